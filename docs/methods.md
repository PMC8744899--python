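# Methods

## Model

`arealsurv` fits a proportional-hazards model for under-five survival with
area-level (county) random effects. Child *i* in area *a(i)* has hazard

    h_i(t) = h0(t) · exp( x_i' β + w_{a(i)} ),   t ∈ (0, 60] months,

with right censoring at interview. The baseline hazard h0 is piecewise
constant on a grid of intervals, so the cumulative baseline H0(t) is
piecewise linear and the log-likelihood of a record (t_i, d_i) is

    d_i · ( log h0(t_i) + x_i'β + w_{a(i)} ) − H0(t_i) · exp( x_i'β + w_{a(i)} ).

The piecewise-exponential form is the canonical implementable Bayesian Cox
surrogate: it keeps H0 closed-form, which the likelihood, the Cox–Snell
residuals and the inverse-transform simulator all share.

The frailties w follow an intrinsic conditional autoregressive (ICAR) prior
on the county contiguity graph:

    p(w | σ²) ∝ (σ²)^(−rank/2) · exp( − Σ_{i~j} (w_i − w_j)² / (2σ²) ),

where the sum runs over neighbouring pairs and rank = n_areas −
n_components. The density is improper (invariant to level shifts), so the
model is identified by a sum-to-zero constraint on w; the normalising
exponent uses the rank so that the posterior of σ² is proper on the
contrast space. The no-frailty comparison model simply drops w.

### Priors (defaults, all overridable via `PriorConfig`)

| block | prior | default | why |
|---|---|---|---|
| β (each) | Normal(0, s²) | s = 10 | weakly informative on the log-hazard scale |
| σ² (frailty variance) | Inverse-Gamma(a, b) | a = 0.5, b = 0.01 | heavy right tail, mass near typical disease-mapping scales |
| log h0k | Normal(μ, 2²) | μ = log crude event rate of the data | centres the baseline on the observed marginal hazard |

The baseline grid defaults to deciles of the observed event times (collapsed
when tied, extended to 60 months), giving each interval a comparable number
of deaths.

## Posterior computation

Metropolis-within-Gibbs, reproducible given a seed:

1. **β** — componentwise Gaussian random-walk Metropolis. Continuous
   covariates are centred at their sample mean when the design matrix is
   built (the offset is recorded); otherwise β_age and the baseline heights
   are nearly collinear on the log scale and a random-walk chain stalls.
   Centring only re-anchors h0 to "a child at mean ages"; hazard ratios are
   unchanged.
2. **log h0k** — componentwise random-walk Metropolis; given the linear
   predictor the interval heights are conditionally independent, so the
   per-interval event counts and exposure sums make each update O(1).
3. **w** — single-site Metropolis against the full conditional (per-area
   event count, per-area cumulative-hazard weight, ICAR pairwise terms).
   After the sweep the field mean is transferred into the baseline log
   heights — an exactly likelihood-invariant shift that enforces Σw = 0.
4. **σ²** — conjugate Gibbs draw from IG(a + rank/2, b + w'Qw/2).
5. **Interweaving rescale** — one Metropolis step in the non-centred
   parameterisation (u = w/σ held fixed, log σ² proposed, w moved with σ).
   This is the package's main departure from a textbook scheme and it is
   load-bearing: with weakly informative per-area data the centered-only
   sampler locks into the σ² ≈ 0, w ≈ 0 corner (small variance ⇒ tiny
   single-site moves ⇒ small quadratic form ⇒ small variance), which
   manifests as an effective sample size of a few dozen for σ². The joint
   rescale restores mixing by an order of magnitude.

Proposal scales adapt by Robbins–Monro toward 0.44 acceptance during
burn-in only, so the retained chain is a fixed kernel. Defaults: 11,000
iterations, 1,000 burn-in, thinning 10. Initialisation: β = 0, w = 0,
σ² = 0.1, baseline heights at the crude event rate — neutral and always
finite.

Diagnostics: per-parameter effective sample size (autocorrelation-based)
and a Geweke z-score comparing the first 10% with the last 50% of the chain,
standardised by ESS-corrected standard errors; constant chains are flagged
rather than scored.

## Model comparison

DIC, WAIC and LPML are all computed from the same retained draws:

* DIC = D̄ + pD with pD = D̄ − D(θ̄); θ̄ plugs in posterior means per block
  (frailties recentred, log-heights averaged on the log scale). If the
  plug-in deviance is non-finite the variance-based pV = var(D)/2 is used
  with a logged warning.
* WAIC uses the variance penalty pWAIC = Σ_i Var(log p(y_i|θ)), evaluated
  with log-sum-exp.
* LPML = Σ_i log CPO_i with log CPO_i = log m − logsumexp(−loglik_i), the
  numerically stable harmonic-mean identity.

## Cox–Snell diagnostics

Residuals r_i = H0(t_i)·exp(x_i'β + w) are evaluated at the posterior-mean
state (matching the single-curve presentation usual for these plots;
per-draw residuals can be computed by applying the same function to any
draw). Censoring status carries over; the cumulative hazard of the
residuals is estimated by Nelson–Aalen and summarised by the least-squares
slope through the origin, which should be ≈ 1 under a correctly specified
model.

## Synthetic data

The generator emulates the structure of a DHS-style birth-history extract:

* **Graph** — a packaged 47-county Kenya-like contiguity list
  (hand-assembled approximate rook adjacency; users supply their own file
  for real analyses). Other area counts get a seeded random-geometric
  surrogate, made connected.
* **Frailties** — exact ICAR draws on the contrast space: independent
  normal scores on the non-null eigenvectors of Q with variances σ²/λ_k.
  Default σ² = 0.2, the scale reported for Kenyan county frailty variance.
* **Covariates** — stylised marginals: female 0.5; rural 0.65;
  female-headed household 0.3; wealth quintiles uniform; education
  (none .13, primary .55, secondary .25, higher .07 — chosen once as
  plausible for Kenyan mothers of young children; no public frequency table
  exists for the microdata); age at first birth ~ round N(19, 3²) clipped
  to [12, 40]; maternal age at birth ~ round N(26, 6²) clipped to [12, 49];
  twin status (single .97, 1st multiple .02, 2nd multiple .01). These are
  deliberately independent across variables — real DHS covariates are
  correlated (wealth with education and residence), so passing recovery
  tests here does not establish robustness to collinearity.
* **Effect sizes** — default true β are the posterior means published for
  the KDHS-2014 spatial Cox analysis, so simulations run at a realistic
  signal-to-noise ratio.
* **Survival** — inverse-transform draws from the piecewise-exponential
  model; two-interval default baseline (0.003/month for infancy,
  0.0006/month for 12–60 months), chosen to give a ~6–7% observed event
  proportion after censoring, the scale of Kenyan under-five mortality.
* **Censoring** — interview age ~ Uniform(0, 60) months mimics the
  birth-history truncation (children born 0–59 months before interview);
  events are deaths occurring before the interview.
* **Size** — ~70 children per county (Poisson), a stand-in for the survey's
  per-county counts, which are published only as a figure.

## Study problem sizes

The replicated studies that exercise the whole pipeline use sizes chosen to
keep repeated fitting cheap while preserving the phenomena of interest:

* model selection: 20 replicates × (20 areas, ~1500 children), 3000
  iterations per fit, unthinned (thinning only trades Monte-Carlo precision
  for memory);
* parameter recovery and residual calibration: the full 47-area,
  ~3300-child default, 4000–6000 iterations.

## Known limitations

* At the default size (~4.7 events per county) the frailty field is weakly
  identified: the posterior for σ² is strongly shrunk toward the
  inverse-gamma prior's mass near zero, its 95% interval fails to cover the
  generating value in roughly a fifth of replicates, and per-replicate
  model-comparison gaps (ΔDIC ~ 0–12) are sometimes inside the ~±0.6
  Monte-Carlo noise of the DIC estimate. These are properties of the data
  regime, not of the sampler — with ~30 events per county the same code
  recovers σ² and the field with correlation > 0.9.
* Single-chain diagnostics only (ESS, Geweke); no multi-chain R-hat.
* No survey design weights, left truncation, time-varying covariates or
  competing risks; records with missing modelled fields are dropped with a
  logged count.
* Published real-data posterior values for KDHS-2014 cannot be reproduced
  here: the microdata are registration-gated, and the packaged adjacency is
  an approximation.
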