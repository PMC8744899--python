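"""Likelihood, baseline hazard and design-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from arealsurv import (
    DEFAULT_VARIABLES,
    ModelState,
    PiecewiseBaseline,
    PriorConfig,
    build_design,
    cumulative_baseline,
    log_likelihood,
    log_prior,
)
from arealsurv.graph import AreaGraph, build_icar_structure, icar_log_density
from arealsurv.model import VariableSpec, validate_records


def single_interval(h: float, end: float = 60.0) -> PiecewiseBaseline:
    return PiecewiseBaseline(np.array([end]), np.log([h]))


def brute_force_loglik(records, x, beta, baseline, frailty_by_rec):
    """Independent per-record direct summation with explicit interval overlap."""
    total = []
    for r, (_, row) in enumerate(records.iterrows()):
        t, d = row["time"], row["event"]
        eta = float(np.dot(x[r], beta)) + frailty_by_rec[r]
        h0 = 0.0
        lower = 0.0
        k_at_t = None
        for k, upper in enumerate(baseline.cut_points):
            h0 += np.exp(baseline.log_heights[k]) * max(0.0, min(t, upper) - lower)
            if lower < t <= upper:
                k_at_t = k
            lower = upper
        contrib = -h0 * np.exp(eta)
        if d == 1:
            contrib += baseline.log_heights[k_at_t] + eta
        total.append(contrib)
    return sum(total), np.array(total)


class TestCumulativeBaseline:
    def test_single_interval_is_linear(self):
        assert cumulative_baseline(single_interval(0.01), 10.0) == pytest.approx(0.1)

    def test_zero_time(self):
        assert cumulative_baseline(single_interval(0.01), 0.0) == 0.0

    def test_two_intervals(self):
        b = PiecewiseBaseline(np.array([12.0, 60.0]), np.log([0.01, 0.002]))
        assert cumulative_baseline(b, 24.0) == pytest.approx(0.144)

    def test_beyond_support_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            cumulative_baseline(single_interval(0.01), 61.0)

    def test_nondecreasing(self):
        b = PiecewiseBaseline(np.array([6.0, 24.0, 60.0]), np.log([0.02, 0.005, 0.001]))
        ts = np.linspace(0, 60, 200)
        vals = cumulative_baseline(b, ts)
        assert (np.diff(vals) >= -1e-15).all()


class TestLogLikelihood:
    def test_single_event_closed_form(self):
        rec = pd.DataFrame({"time": [5.0], "event": [1], "area": ["A"]})
        design = _empty_design(1)
        state = ModelState(beta=np.zeros(0), baseline=single_interval(0.01))
        total, per = log_likelihood(rec, design, state)
        assert total == pytest.approx(np.log(0.01) - 0.05)
        assert per.shape == (1,)

    def test_all_censored(self):
        rec = pd.DataFrame(
            {"time": [10.0, 30.0, 59.0], "event": [0, 0, 0], "area": list("AAB")}
        )
        state = ModelState(beta=np.zeros(0), baseline=single_interval(0.02))
        total, _ = log_likelihood(rec, _empty_design(3), state)
        assert total == pytest.approx(-0.02 * (10 + 30 + 59))

    def test_matches_brute_force_oracle(self, rng):
        n = 20
        rec = pd.DataFrame(
            {
                "time": rng.uniform(0.5, 59.5, n),
                "event": rng.integers(0, 2, n),
                "area": rng.choice(["A", "B", "C"], n),
            }
        )
        x = rng.standard_normal((n, 3))
        design = _design_from_matrix(x)
        baseline = PiecewiseBaseline(
            np.array([10.0, 25.0, 60.0]), np.log([0.01, 0.004, 0.001])
        )
        beta = np.array([0.3, -0.2, 0.1])
        graph = AreaGraph(("A", "B", "C"), ((0, 1), (1, 2)))
        w = np.array([0.2, -0.1, -0.1])
        state = ModelState(beta=beta, baseline=baseline, frailties=w, frailty_variance=0.2)
        lookup = {"A": 0, "B": 1, "C": 2}
        total, per = log_likelihood(rec, design, state, graph)
        want_total, want_per = brute_force_loglik(
            rec, x, beta, baseline, w[[lookup[a] for a in rec["area"]]]
        )
        assert total == pytest.approx(want_total, abs=1e-10)
        np.testing.assert_allclose(per, want_per, atol=1e-10)
        assert total == pytest.approx(per.sum(), abs=1e-12)

    def test_proportional_hazards_property(self, rng):
        """Adding c to a coefficient multiplies each hazard by exp(c*x)."""
        n = 10
        x = rng.standard_normal((n, 2))
        rec = pd.DataFrame(
            {"time": rng.uniform(1, 59, n), "event": np.ones(n, dtype=int), "area": ["A"] * n}
        )
        base = single_interval(0.01)
        b0 = np.array([0.5, -0.3])
        c = 0.7
        _, per0 = log_likelihood(rec, _design_from_matrix(x), ModelState(beta=b0, baseline=base))
        b1 = b0 + np.array([c, 0.0])
        _, per1 = log_likelihood(rec, _design_from_matrix(x), ModelState(beta=b1, baseline=base))
        # event part shifts by c*x0; cumulative part scales by exp(c*x0)
        h0 = cumulative_baseline(base, rec["time"].to_numpy())
        want = per0 + c * x[:, 0] - h0 * np.exp(x @ b0) * np.expm1(c * x[:, 0])
        np.testing.assert_allclose(per1, want, rtol=1e-10)

    def test_exponential_mle_recovery(self, rng):
        """Single interval, no frailty: generic optimiser recovers the rate."""
        n, rate = 4000, 0.05
        t = np.minimum(rng.exponential(1 / rate, n), 60.0)
        d = (t < 60.0).astype(int)
        rec = pd.DataFrame({"time": t, "event": d, "area": ["A"] * n})
        design = _empty_design(n)

        def nll(log_h):
            state = ModelState(beta=np.zeros(0), baseline=single_interval(np.exp(log_h[0])))
            return -log_likelihood(rec, design, state)[0]

        res = optimize.minimize(nll, [np.log(0.02)], method="Nelder-Mead")
        mle = np.exp(res.x[0])
        se = rate / np.sqrt(d.sum())
        assert abs(mle - rate) < 3 * se


class TestBuildDesign:
    def test_female_indicator(self):
        rec = _one_child(sex="female")
        d = build_design(rec)
        j = d.columns.index("Sex of the child (Female)")
        assert d.values[0, j] == 1.0

    def test_reference_child_all_zero_dummies(self):
        d = build_design(_one_child())
        dummy_cols = [
            k for k, c in enumerate(d.columns)
            if c not in ("Age of respondent at first birth", "Maternal age at birth")
        ]
        assert np.all(d.values[0, dummy_cols] == 0.0)

    def test_education_yields_three_columns(self):
        d = build_design(_one_child())
        edu = [c for c in d.columns if c.startswith("Highest Level of Education")]
        assert len(edu) == 3

    def test_fourteen_effects_total(self):
        assert build_design(_one_child()).n_effects == 14

    def test_unseen_level_errors(self):
        rec = _one_child(sex="other")
        with pytest.raises(ValueError, match="unseen"):
            build_design(rec)

    def test_continuous_centering_recorded(self):
        rec = pd.concat([_one_child(), _one_child()], ignore_index=True)
        rec.loc[1, "age_first_birth"] = 25
        d = build_design(rec)
        j = d.columns.index("Age of respondent at first birth")
        assert d.centering["Age of respondent at first birth"] == pytest.approx(22.0)
        np.testing.assert_allclose(d.values[:, j], [-3.0, 3.0])

    def test_missing_rows_dropped(self):
        rec = pd.concat([_one_child(), _one_child()], ignore_index=True)
        rec.loc[1, "education"] = np.nan
        out = validate_records(rec)
        assert len(out) == 1


class TestLogPrior:
    def test_zero_beta_normal_form(self):
        state = ModelState(beta=np.zeros(3), baseline=single_interval(0.01))
        priors = PriorConfig(beta_scale=10.0, baseline_log_mean=np.log(0.01))
        got = log_prior(state, None, priors)
        want_beta = 3 * stats.norm.logpdf(0.0, scale=10.0)
        want_h = stats.norm.logpdf(np.log(0.01), loc=np.log(0.01), scale=2.0)
        assert got == pytest.approx(want_beta + want_h)

    def test_componentwise_oracle(self, rng):
        g = AreaGraph(tuple("ABCD"), ((0, 1), (1, 2), (2, 3)))
        s = build_icar_structure(g)
        w = rng.standard_normal(4)
        w -= w.mean()
        state = ModelState(
            beta=rng.standard_normal(2),
            baseline=PiecewiseBaseline(np.array([12.0, 60.0]), np.array([-5.0, -6.0])),
            frailties=w,
            frailty_variance=0.3,
        )
        priors = PriorConfig(baseline_log_mean=-5.5)
        got = log_prior(state, s, priors)
        want = (
            stats.norm.logpdf(state.beta, scale=10.0).sum()
            + stats.norm.logpdf(state.baseline.log_heights, loc=-5.5, scale=2.0).sum()
            + icar_log_density(w, 0.3, s)
            + stats.invgamma.logpdf(0.3, 0.5, scale=0.01)
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_bad_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(beta_scale=-1.0)


# --- helpers ---------------------------------------------------------------


def _one_child(**overrides) -> pd.DataFrame:
    base = {
        "time": 60.0,
        "event": 0,
        "area": "A",
        "sex": "male",
        "residence": "urban",
        "household_head": "male",
        "wealth_index": "poorest",
        "education": "none",
        "age_first_birth": 19,
        "maternal_age": 26,
        "twin": "single",
    }
    base.update(overrides)
    return pd.DataFrame([base])


def _empty_design(n):
    from arealsurv.model import DesignMatrix

    return DesignMatrix(columns=(), values=np.empty((n, 0)), reference_levels={})


def _design_from_matrix(x):
    from arealsurv.model import DesignMatrix

    return DesignMatrix(
        columns=tuple(f"x{j}" for j in range(x.shape[1])),
        values=x,
        reference_levels={},
    )
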