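"""Cox–Snell residual diagnostics.

Under a correctly specified proportional-hazards model the residual
``r_i = H(t_i | x_i) = H0(t_i) * exp(x_i' beta + w_{a(i)})`` of an uncensored
record is unit-exponentially distributed, and censored records stay censored
at their residual value.  The cumulative hazard of the residuals, estimated
by Nelson–Aalen, should therefore be approximately a straight line through
the origin with slope one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import NelsonAalenFitter

from .graph import AreaGraph
from .mcmc import PosteriorChains, posterior_mean_state
from .model import DesignMatrix, ModelState, cumulative_baseline

__all__ = ["ResidualSet", "cox_snell_residuals", "residual_gof"]


@dataclass(frozen=True)
class ResidualSet:
    residuals: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residual": self.residuals, "event": self.events})


def cox_snell_residuals(
    records: pd.DataFrame,
    design: DesignMatrix,
    state: ModelState,
    graph: AreaGraph | None = None,
) -> ResidualSet:
    """Residuals at a plug-in state (typically the posterior mean)."""
    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    eta = design.values @ state.beta
    if state.frailties is not None:
        if graph is None:
            raise ValueError("spatial state needs the area graph")
        lookup = {lab: k for k, lab in enumerate(graph.area_ids)}
        eta = eta + state.frailties[records["area"].map(lookup).to_numpy(dtype=int)]
    r = cumulative_baseline(state.baseline, t) * np.exp(eta)
    return ResidualSet(residuals=np.asarray(r, dtype=float), events=d)


def residuals_from_chains(chains: PosteriorChains) -> ResidualSet:
    """Convenience: residuals at the posterior-mean state of a fitted chain."""
    return cox_snell_residuals(
        chains.records, chains.design, posterior_mean_state(chains), chains.graph
    )


def residual_gof(
    residual_set: ResidualSet, min_records: int = 20, min_events: int = 5
) -> tuple[float, pd.DataFrame]:
    """Nelson–Aalen cumulative hazard of the residuals and its slope.

    Returns the least-squares slope through the origin of ``H_hat(r)`` vs
    ``r`` (weighting each step point equally) together with the step curve
    as a ``(r, cumhaz)`` frame for plotting; slope near 1 indicates fit.
    """
    r, d = residual_set.residuals, residual_set.events
    if r.size < min_records:
        raise ValueError(f"need at least {min_records} records, got {r.size}")
    if d.sum() < min_events:
        raise ValueError(f"need at least {min_events} events, got {int(d.sum())}")
    naf = NelsonAalenFitter()
    naf.fit(r, event_observed=d)
    curve = naf.cumulative_hazard_
    x = curve.index.to_numpy(dtype=float)
    y = curve.iloc[:, 0].to_numpy(dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    slope = float((x @ y) / (x @ x))
    return slope, pd.DataFrame({"residual": x, "cumulative_hazard": y})
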