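"""Sampler correctness, reproducibility and chain diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arealsurv import (
    FRAILTY_VARIANCE,
    McmcConfig,
    PriorConfig,
    SimulationConfig,
    build_design,
    generate,
    posterior_summary,
    sample_posterior,
    trace_summaries,
    validate_records,
)
from arealsurv.graph import AreaGraph, build_icar_structure
from arealsurv.mcmc import PosteriorChains, gibbs_variance_draw
from arealsurv.synthetic import sample_icar_frailties


def _tiny_fit(seed=5, spatial=True, **cfg_kwargs):
    ds = generate(SimulationConfig(n_areas=5, children_per_area_mean=40, seed=11))
    rec = validate_records(ds.records, ds.graph)
    design = build_design(rec)
    defaults = dict(n_iterations=600, burn_in=200, thinning=2, seed=seed)
    defaults.update(cfg_kwargs)
    cfg = McmcConfig(**defaults)
    return sample_posterior(rec, design, ds.graph if spatial else None, None, cfg)


def _series_chains(series: np.ndarray) -> PosteriorChains:
    """Wrap a 1-d series as a single-coefficient chain for diagnostics."""
    m = series.size
    return PosteriorChains(
        beta=np.asarray(series, dtype=float)[:, None],
        beta_names=("x",),
        log_heights=np.full((m, 1), -5.0),
        cut_points=np.array([60.0]),
        frailties=None,
        frailty_variance=None,
        area_ids=None,
        per_record_loglik=np.zeros((m, 1)),
        acceptance_rates={},
        config=McmcConfig(n_iterations=m + 1, burn_in=0, thinning=1),
        records=pd.DataFrame({"time": [1.0], "event": [0], "area": ["A"]}),
        design=None,
    )


class TestConfig:
    def test_burn_in_must_be_less_than_iterations(self):
        with pytest.raises(ValueError, match="burn_in"):
            McmcConfig(n_iterations=100, burn_in=100)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=0, burn_in=0)

    def test_retained_count(self):
        cfg = McmcConfig(n_iterations=11000, burn_in=1000, thinning=10)
        assert cfg.n_retained == 1000


class TestSampler:
    def test_bit_reproducible(self):
        a = _tiny_fit(seed=3)
        b = _tiny_fit(seed=3)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.frailties, b.frailties)
        np.testing.assert_array_equal(a.frailty_variance, b.frailty_variance)

    def test_different_seed_differs(self):
        a = _tiny_fit(seed=3)
        b = _tiny_fit(seed=4)
        assert not np.array_equal(a.beta, b.beta)

    def test_frailties_sum_to_zero_every_draw(self):
        ch = _tiny_fit()
        np.testing.assert_allclose(ch.frailties.sum(axis=1), 0.0, atol=1e-10)

    def test_acceptance_rates_in_unit_interval(self):
        ch = _tiny_fit()
        for rate in ch.acceptance_rates.values():
            assert 0.0 <= rate <= 1.0

    def test_nonspatial_has_no_frailty_block(self):
        ch = _tiny_fit(spatial=False)
        assert not ch.is_spatial
        assert ch.frailties is None
        assert FRAILTY_VARIANCE not in ch.parameter_names()

    def test_per_record_loglik_shape_and_total(self):
        ch = _tiny_fit()
        assert ch.per_record_loglik.shape == (ch.n_draws, len(ch.records))
        assert np.isfinite(ch.per_record_loglik).all()

    def test_prior_only_recovers_beta_prior_moments(self):
        ch = _tiny_fit(
            seed=9, n_iterations=6000, burn_in=1000, thinning=1, likelihood_off=True
        )
        draws = ch.beta.ravel()  # all coefficients share the N(0, 10^2) prior
        assert abs(draws.mean()) < 2.0
        assert 8.0 < draws.std() < 12.0
        assert (ch.frailty_variance > 0).all()


class TestVarianceConjugacy:
    def test_gibbs_matches_closed_form(self):
        """Variance draws with the field held fixed follow IG(a + rank/2, b + wQw/2)."""
        g = AreaGraph(tuple("ABCDE"), ((0, 1), (1, 2), (2, 3), (3, 4)))
        s = build_icar_structure(g)
        w = sample_icar_frailties(s, 0.25, seed=1)
        priors = PriorConfig()
        rng = np.random.default_rng(123)
        draws = np.array([gibbs_variance_draw(w, s, priors, rng) for _ in range(2000)])
        quad = float(w @ s.precision_unscaled @ w)
        dist = stats.invgamma(priors.variance_shape + s.rank / 2,
                              scale=priors.variance_rate + quad / 2)
        _, p = stats.kstest(draws, dist.cdf)
        assert p > 0.01


class TestTraceSummaries:
    def test_iid_series_ess_near_n(self, rng):
        ch = _series_chains(rng.standard_normal(1000))
        ess = trace_summaries(ch).loc["x", "ess"]
        assert abs(ess - 1000) < 200

    def test_ar1_series_ess_closed_form(self, rng):
        rho, n = 0.9, 8000
        z = np.empty(n)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            z[i] = rho * z[i - 1] + eps[i]
        ess = trace_summaries(_series_chains(z)).loc["x", "ess"]
        want = n * (1 - rho) / (1 + rho)
        assert abs(ess - want) / want < 0.25

    def test_constant_series_flagged_degenerate(self):
        ch = _series_chains(np.full(500, 3.14))
        row = trace_summaries(ch).loc["x"]
        assert row["degenerate"]
        assert np.isnan(row["ess"])

    def test_requires_minimum_draws(self):
        ch = _series_chains(np.arange(50.0))
        with pytest.raises(ValueError, match="retained draws"):
            trace_summaries(ch)

    def test_geweke_near_zero_for_stationary_series(self, rng):
        ch = _series_chains(rng.standard_normal(2000))
        z = trace_summaries(ch).loc["x", "geweke_z"]
        assert abs(z) < 3.0


class TestPosteriorSummary:
    def test_constant_chain(self):
        ch = _series_chains(np.full(200, 2.5))
        s = posterior_summary(ch, "x")
        assert s["mean"] == s["median"] == 2.5
        assert s["sd"] == 0.0
        assert (s["ci_low"], s["ci_high"]) == (2.5, 2.5)

    def test_quantile_rule_on_1_to_100(self):
        ch = _series_chains(np.arange(1.0, 101.0))
        s = posterior_summary(ch, "x")
        assert s["median"] == pytest.approx(50.5)
        assert s["ci_low"] == pytest.approx(3.475)
        assert s["ci_high"] == pytest.approx(97.525)

    def test_symmetry(self, rng):
        draws = rng.standard_normal(500)
        a = posterior_summary(_series_chains(draws), "x")
        b = posterior_summary(_series_chains(-draws), "x")
        assert a["mean"] == pytest.approx(-b["mean"])

    def test_unknown_parameter_errors(self):
        ch = _series_chains(np.arange(100.0))
        with pytest.raises(KeyError):
            posterior_summary(ch, "nope")
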