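"""Metropolis-within-Gibbs posterior sampling for the areal frailty model.

Update scheme per sweep:

* regression coefficients ``beta`` — componentwise random-walk Metropolis;
* baseline log-heights — componentwise random-walk Metropolis (conditionally
  independent given the linear predictor);
* area frailties ``w`` — single-site Metropolis against the ICAR full
  conditional, then recentred to sum to zero with the mean shifted into the
  baseline log-heights (a likelihood-invariant move that identifies the
  intrinsic prior);
* frailty variance — conjugate inverse-gamma Gibbs draw using the ICAR
  quadratic form ``w' Q w`` and rank, followed by an interweaving move in
  the non-centred parameterisation (``w = sigma * u`` with ``u`` fixed)
  that rescales the whole field and its variance jointly.  Without it the
  chain can lock into the ``variance ~ 0, w ~ 0`` corner: a small variance
  makes single-site moves tiny, which keeps the quadratic form small,
  which keeps the variance small.

Proposal scales adapt by Robbins–Monro toward 0.44 acceptance during burn-in
only, so the post-burn-in chain is a fixed Markov kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import arviz as az

from .graph import AreaGraph, IcarStructure, build_icar_structure
from .model import (
    DesignMatrix,
    ModelState,
    PiecewiseBaseline,
    PriorConfig,
    default_baseline,
    exposure_matrix,
)

__all__ = [
    "McmcConfig",
    "PosteriorChains",
    "sample_posterior",
    "gibbs_variance_draw",
    "trace_summaries",
    "posterior_summary",
    "summary_table",
    "posterior_mean_state",
]

FRAILTY_VARIANCE = "Variance of spatial frailty"


@dataclass(frozen=True)
class McmcConfig:
    n_iterations: int = 11000
    burn_in: int = 1000
    thinning: int = 10
    seed: int = 0
    beta_step: float = 0.1
    height_step: float = 0.3
    frailty_step: float = 0.4
    adapt: bool = True
    adapt_target: float = 0.44
    likelihood_off: bool = False  # prior-only sampling, for validation

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.burn_in < 0 or self.thinning < 1:
            raise ValueError("iteration counts must be positive, thinning >= 1")
        if self.burn_in >= self.n_iterations:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be < n_iterations ({self.n_iterations})"
            )

    @property
    def n_retained(self) -> int:
        return int(np.ceil((self.n_iterations - self.burn_in) / self.thinning))


@dataclass
class PosteriorChains:
    """Retained draws, per-record log-likelihoods and run metadata.

    Parameter series are addressed by name: a design-column label for a
    coefficient, ``"frailty[<area>]"``, ``"log_height[<k>]"``, or the frailty
    variance label.
    """

    beta: np.ndarray  # (m, p)
    beta_names: tuple[str, ...]
    log_heights: np.ndarray  # (m, K)
    cut_points: np.ndarray
    frailties: np.ndarray | None  # (m, A)
    frailty_variance: np.ndarray | None  # (m,)
    area_ids: tuple[str, ...] | None
    per_record_loglik: np.ndarray  # (m, n)
    acceptance_rates: Mapping[str, float]
    config: McmcConfig
    records: pd.DataFrame = field(repr=False)
    design: DesignMatrix = field(repr=False)
    graph: AreaGraph | None = field(repr=False, default=None)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def is_spatial(self) -> bool:
        return self.frailties is not None

    def parameter_names(self) -> list[str]:
        names = list(self.beta_names)
        names += [f"log_height[{k}]" for k in range(self.log_heights.shape[1])]
        if self.is_spatial:
            names += [f"frailty[{a}]" for a in self.area_ids]
            names.append(FRAILTY_VARIANCE)
        return names

    def get_series(self, name: str) -> np.ndarray:
        if name in self.beta_names:
            return self.beta[:, self.beta_names.index(name)]
        if name.startswith("log_height["):
            return self.log_heights[:, int(name[11:-1])]
        if self.is_spatial and name.startswith("frailty["):
            return self.frailties[:, self.area_ids.index(name[8:-1])]
        if self.is_spatial and name == FRAILTY_VARIANCE:
            return self.frailty_variance
        raise KeyError(f"unknown parameter {name!r}")


def gibbs_variance_draw(
    frailties: np.ndarray,
    structure: IcarStructure,
    priors: PriorConfig,
    rng: np.random.Generator,
) -> float:
    """Conjugate draw of the ICAR frailty variance.

    Full conditional: Inverse-Gamma(shape + rank/2, rate + w'Qw/2).
    """
    w = np.asarray(frailties, dtype=float)
    quad = float(w @ structure.precision_unscaled @ w)
    shape = priors.variance_shape + structure.rank / 2.0
    rate = priors.variance_rate + quad / 2.0
    return float(rate / rng.gamma(shape))


class _Workspace:
    """Precomputed data views shared by all update blocks."""

    def __init__(
        self,
        records: pd.DataFrame,
        design: DesignMatrix,
        baseline: PiecewiseBaseline,
        graph: AreaGraph | None,
    ):
        self.t = records["time"].to_numpy(dtype=float)
        self.d = records["event"].to_numpy(dtype=float)
        self.x = np.ascontiguousarray(design.values)
        self.n, self.p = self.x.shape
        self.exposure = exposure_matrix(baseline, self.t)
        self.death_interval = baseline.interval_index(self.t)
        self.k = baseline.n_intervals
        # events falling in each baseline interval
        self.events_per_interval = np.bincount(
            self.death_interval, weights=self.d, minlength=self.k
        )
        self.d_dot_x = self.d @ self.x  # per-coefficient event score
        if graph is not None:
            lookup = {lab: i for i, lab in enumerate(graph.area_ids)}
            try:
                self.area_index = records["area"].map(lookup).to_numpy(dtype=int)
            except (ValueError, TypeError):
                unknown = sorted(set(records["area"]) - set(graph.area_ids))
                raise ValueError(f"record areas not in graph: {unknown}") from None
            self.n_areas = graph.n_areas
            self.events_per_area = np.bincount(
                self.area_index, weights=self.d, minlength=self.n_areas
            )
            self.neighbours = [[] for _ in range(self.n_areas)]
            for i, j in graph.edges:
                self.neighbours[i].append(j)
                self.neighbours[j].append(i)
        else:
            self.area_index = None


class _AdaptiveScale:
    """Robbins–Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, size: int, init: float, target: float):
        self.log_s = np.full(size, np.log(init))
        self.target = target
        self.count = np.zeros(size)

    def scale(self, j: int) -> float:
        return float(np.exp(self.log_s[j]))

    def update(self, j: int, accept_prob: float) -> None:
        self.count[j] += 1
        gamma = self.count[j] ** -0.6
        self.log_s[j] += gamma * (accept_prob - self.target)


def sample_posterior(
    records: pd.DataFrame,
    design: DesignMatrix,
    graph: AreaGraph | None = None,
    priors: PriorConfig | None = None,
    config: McmcConfig | None = None,
    baseline: PiecewiseBaseline | None = None,
) -> PosteriorChains:
    """Draw from the posterior of the (spatial or no-frailty) model.

    Reproducible given ``config.seed``; pass ``graph=None`` for the
    no-frailty proportional-hazards model.
    """
    config = config or McmcConfig()
    priors = priors or PriorConfig()
    rng = np.random.default_rng(config.seed)

    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=float)
    crude = max(d.sum(), 0.5) / t.sum()
    if baseline is None:
        baseline = default_baseline(
            event_times=t[d == 1], log_height=float(np.log(crude))
        )
    if priors.baseline_log_mean is None:
        priors = PriorConfig(
            beta_scale=priors.beta_scale,
            variance_shape=priors.variance_shape,
            variance_rate=priors.variance_rate,
            baseline_log_mean=float(np.log(crude)),
            baseline_log_sd=priors.baseline_log_sd,
        )

    ws = _Workspace(records, design, baseline, graph)
    spatial = graph is not None
    structure = build_icar_structure(graph) if spatial else None

    like_on = not config.likelihood_off

    # --- state ---------------------------------------------------------
    beta = np.zeros(ws.p)
    log_h = baseline.log_heights.copy()
    h = np.exp(log_h)
    w = np.zeros(ws.n_areas) if spatial else None
    variance = 0.1 if spatial else None

    lin = ws.x @ beta  # x'beta
    eta = lin + (w[ws.area_index] if spatial else 0.0)
    hcum = ws.exposure @ h  # H0(t_i)
    if not np.isfinite(eta).all():
        raise FloatingPointError("non-finite linear predictor at initialisation")
    if not np.isfinite(hcum).all():
        raise FloatingPointError("non-finite baseline cumulative hazard at initialisation")

    beta_prec = 1.0 / priors.beta_scale**2
    lh_mu, lh_prec = priors.baseline_log_mean, 1.0 / priors.baseline_log_sd**2

    adapt_beta = _AdaptiveScale(ws.p, config.beta_step, config.adapt_target)
    adapt_h = _AdaptiveScale(ws.k, config.height_step, config.adapt_target)
    adapt_w = _AdaptiveScale(ws.n_areas if spatial else 0, config.frailty_step,
                             config.adapt_target) if spatial else None
    adapt_rescale = _AdaptiveScale(1, 1.0, config.adapt_target) if spatial else None

    m = config.n_retained
    out_beta = np.empty((m, ws.p))
    out_logh = np.empty((m, ws.k))
    out_w = np.empty((m, ws.n_areas)) if spatial else None
    out_var = np.empty(m) if spatial else None
    out_ll = np.empty((m, ws.n))
    acc = {"beta": 0, "heights": 0, "frailties": 0}
    props = {"beta": 0, "heights": 0, "frailties": 0}

    keep = 0
    zeros_n = np.zeros(ws.n)
    for it in range(config.n_iterations):
        adapting = config.adapt and it < config.burn_in
        # prior-only mode skips the likelihood caches (eta may overflow exp)
        expeta = np.exp(eta) if like_on else zeros_n

        # --- beta: componentwise random-walk Metropolis ----------------
        for j in range(ws.p):
            step = adapt_beta.scale(j) * rng.standard_normal()
            xj = ws.x[:, j]
            # likelihood change: d'(step*xj) - sum hcum * (exp(eta+step*xj)-exp(eta))
            ll_delta = (
                step * ws.d_dot_x[j] - hcum @ (expeta * np.expm1(step * xj))
            ) if like_on else 0.0
            bj_new = beta[j] + step
            lp_delta = -0.5 * beta_prec * (bj_new**2 - beta[j] ** 2)
            log_alpha = ll_delta + lp_delta
            accept = np.log(rng.uniform()) < log_alpha
            if accept:
                beta[j] = bj_new
                lin = lin + step * xj
                eta = eta + step * xj
                if like_on:
                    expeta = expeta * np.exp(step * xj)
                acc["beta"] += 1
            props["beta"] += 1
            if adapting:
                adapt_beta.update(j, min(1.0, np.exp(min(log_alpha, 0.0))))

        # --- baseline log-heights: componentwise MH --------------------
        # Given eta, interval heights are conditionally independent.
        colw = ws.exposure.T @ expeta
        for k in range(ws.k):
            step = adapt_h.scale(k) * rng.standard_normal()
            lh_new = log_h[k] + step
            ll_delta = (
                ws.events_per_interval[k] * step
                - (np.exp(lh_new) - h[k]) * colw[k]
            ) if like_on else 0.0
            lp_delta = -0.5 * lh_prec * ((lh_new - lh_mu) ** 2 - (log_h[k] - lh_mu) ** 2)
            log_alpha = ll_delta + lp_delta
            if np.log(rng.uniform()) < log_alpha:
                log_h[k] = lh_new
                h[k] = np.exp(lh_new)
                acc["heights"] += 1
            props["heights"] += 1
            if adapting:
                adapt_h.update(k, min(1.0, np.exp(min(log_alpha, 0.0))))
        hcum = ws.exposure @ h

        if spatial:
            # --- frailties: single-site MH from full conditionals ------
            # For area a the likelihood depends on w_a only through
            #   events_a * w_a - exp(w_a) * R_a,  R_a = sum_i hcum_i exp(lin_i).
            r_area = np.bincount(
                ws.area_index, weights=hcum * np.exp(lin), minlength=ws.n_areas
            ) if like_on else np.zeros(ws.n_areas)
            inv_var = 1.0 / variance
            for a in range(ws.n_areas):
                step = adapt_w.scale(a) * rng.standard_normal()
                wa_new = w[a] + step
                ll_delta = (
                    ws.events_per_area[a] * step
                    - (np.exp(wa_new) - np.exp(w[a])) * r_area[a]
                ) if like_on else 0.0
                nb = ws.neighbours[a]
                lp_delta = 0.0
                for b in nb:
                    lp_delta += (wa_new - w[b]) ** 2 - (w[a] - w[b]) ** 2
                lp_delta *= -0.5 * inv_var
                log_alpha = ll_delta + lp_delta
                if np.log(rng.uniform()) < log_alpha:
                    w[a] = wa_new
                    acc["frailties"] += 1
                props["frailties"] += 1
                if adapting:
                    adapt_w.update(a, min(1.0, np.exp(min(log_alpha, 0.0))))
            # identify the intrinsic prior: recentre w, shift the mean into
            # the baseline (likelihood-invariant)
            shift = w.mean()
            w -= shift
            log_h += shift
            h = np.exp(log_h)
            hcum = ws.exposure @ h
            eta = lin + w[ws.area_index]

            # --- frailty variance: conjugate Gibbs ---------------------
            quad = float(w @ structure.precision_unscaled @ w)
            variance = float(
                (priors.variance_rate + quad / 2.0)
                / rng.gamma(priors.variance_shape + structure.rank / 2.0)
            )

            # --- interweaving rescale (non-centred move) ---------------
            # With u = w / sigma held fixed, propose log-variance and move
            # the whole field along with it; target includes the
            # inverse-gamma prior and the log-scale Jacobian.
            step = adapt_rescale.scale(0) * rng.standard_normal()
            var_new = variance * np.exp(step)
            ratio = np.sqrt(var_new / variance)
            w_new = w * ratio
            eta_new = lin + w_new[ws.area_index]
            ll_delta = (
                ws.d @ (eta_new - eta) - hcum @ (np.exp(eta_new) - np.exp(eta))
            ) if like_on else 0.0
            lp_delta = (
                (-(priors.variance_shape + 1.0))
                * (np.log(var_new) - np.log(variance))
                - priors.variance_rate * (1.0 / var_new - 1.0 / variance)
                + step  # Jacobian of the log-scale proposal
            )
            log_alpha = ll_delta + lp_delta
            if np.log(rng.uniform()) < log_alpha:
                variance = float(var_new)
                w = w_new
                eta = eta_new
            if adapting:
                adapt_rescale.update(0, min(1.0, np.exp(min(log_alpha, 0.0))))

        # --- retain ----------------------------------------------------
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            out_beta[keep] = beta
            out_logh[keep] = log_h
            if spatial:
                out_w[keep] = w
                out_var[keep] = variance
            if like_on:
                expeta = np.exp(eta)
                out_ll[keep] = (
                    ws.d * (log_h[ws.death_interval] + eta) - hcum * expeta
                )
            else:
                out_ll[keep] = 0.0
            keep += 1

    rates = {k: (acc[k] / props[k] if props[k] else np.nan) for k in acc}
    return PosteriorChains(
        beta=out_beta[:keep],
        beta_names=tuple(design.columns),
        log_heights=out_logh[:keep],
        cut_points=baseline.cut_points.copy(),
        frailties=out_w[:keep] if spatial else None,
        frailty_variance=out_var[:keep] if spatial else None,
        area_ids=tuple(graph.area_ids) if spatial else None,
        per_record_loglik=out_ll[:keep],
        acceptance_rates=rates,
        config=config,
        records=records,
        design=design,
        graph=graph,
    )


# ---------------------------------------------------------------------------
# Summaries and diagnostics


def posterior_mean_state(chains: PosteriorChains) -> ModelState:
    """Plug-in state at the posterior mean of each parameter block."""
    baseline = PiecewiseBaseline(chains.cut_points, chains.log_heights.mean(axis=0))
    frail = None
    var = None
    if chains.is_spatial:
        frail = chains.frailties.mean(axis=0)
        frail = frail - frail.mean()  # recentred
        var = float(chains.frailty_variance.mean())
    return ModelState(
        beta=chains.beta.mean(axis=0),
        baseline=baseline,
        frailties=frail,
        frailty_variance=var,
    )


def _ess(series: np.ndarray) -> float:
    return float(az.ess(np.asarray(series)[None, :]))


def trace_summaries(chains: PosteriorChains, min_draws: int = 100) -> pd.DataFrame:
    """Per-parameter effective sample size and Geweke z-score.

    Geweke compares the mean of the first 10% of the chain with the last 50%,
    standardised by ESS-corrected standard errors. Degenerate (constant)
    chains are flagged rather than raising.
    """
    if chains.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws")
    rows = []
    for name in chains.parameter_names():
        s = chains.get_series(name)
        if np.std(s) == 0:
            rows.append({"parameter": name, "ess": np.nan, "geweke_z": np.nan,
                         "degenerate": True})
            continue
        ess = _ess(s)
        n = s.size
        a, b = s[: max(2, n // 10)], s[n // 2:]
        se2 = a.var(ddof=1) / max(_ess(a), 1.0) + b.var(ddof=1) / max(_ess(b), 1.0)
        z = (a.mean() - b.mean()) / np.sqrt(se2) if se2 > 0 else np.nan
        rows.append({"parameter": name, "ess": ess, "geweke_z": z,
                     "degenerate": False})
    return pd.DataFrame(rows).set_index("parameter")


def posterior_summary(chains: PosteriorChains, parameter: str) -> dict[str, float]:
    """Mean, median, sd and the equal-tailed 95% credible interval."""
    s = chains.get_series(parameter)
    lo, hi = np.quantile(s, [0.025, 0.975])
    return {
        "mean": float(s.mean()),
        "median": float(np.median(s)),
        "sd": float(s.std(ddof=1)) if s.size > 1 else 0.0,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def summary_table(chains: PosteriorChains, parameters: list[str] | None = None) -> pd.DataFrame:
    """Posterior summary table over coefficients (and the frailty variance)."""
    if parameters is None:
        parameters = list(chains.beta_names)
        if chains.is_spatial:
            parameters.append(FRAILTY_VARIANCE)
    rows = {p: posterior_summary(chains, p) for p in parameters}
    return pd.DataFrame(rows).T[["mean", "median", "sd", "ci_low", "ci_high"]]
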