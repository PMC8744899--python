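"""Posterior predictive model comparison: DIC, WAIC and LPML.

All three criteria are computed from the same retained draws of a
:class:`~arealsurv.mcmc.PosteriorChains`; nothing is re-fitted.

* DIC  = D-bar + pD with D-bar the posterior mean deviance and
  pD = D-bar - D(theta-bar), the deviance at the posterior-mean state
  (classical plug-in definition; a variance-based pV fallback is used when
  the plug-in deviance is non-finite).
* WAIC = -2 (lppd - pWAIC) with the variance-form penalty
  pWAIC = sum_i Var_draws(log p(y_i | theta)).
* LPML = sum_i log CPO_i, CPO_i the harmonic mean of the per-draw
  likelihoods of record i, evaluated stably in log space.

Lower DIC/WAIC and higher LPML indicate the preferred model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mcmc import PosteriorChains, posterior_mean_state
from .model import log_likelihood

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonReport",
    "compute_dic",
    "compute_waic",
    "compute_lpml",
    "comparison_report",
    "comparison_table",
]


@dataclass(frozen=True)
class ComparisonReport:
    dic: float
    p_d: float
    waic: float
    p_waic: float
    lpml: float
    per_record_cpo: np.ndarray

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_record_cpo"] = self.per_record_cpo.tolist()
        return d


def compute_dic(chains: PosteriorChains, plugin_loglik=None) -> tuple[float, float]:
    """Deviance information criterion and its effective-parameter count pD.

    ``plugin_loglik`` — optional zero-argument callable returning the total
    log-likelihood at the posterior-mean state; defaults to evaluating the
    piecewise-exponential model at the plug-in state.
    """
    total_ll = chains.per_record_loglik.sum(axis=1)
    d_bar = float(np.mean(-2.0 * total_ll))
    if plugin_loglik is not None:
        ll_plug = float(plugin_loglik())
    else:
        state = posterior_mean_state(chains)
        ll_plug, _ = log_likelihood(chains.records, chains.design, state, chains.graph)
    if np.isfinite(ll_plug):
        p_d = d_bar - (-2.0 * ll_plug)
    else:
        logger.warning("non-finite plug-in deviance; falling back to pV = var(D)/2")
        p_d = float(np.var(-2.0 * total_ll, ddof=1) / 2.0)
    return d_bar + p_d, p_d


def compute_waic(chains: PosteriorChains) -> tuple[float, float]:
    """Watanabe–Akaike information criterion with the variance penalty."""
    ll = chains.per_record_loglik  # (m, n)
    m = ll.shape[0]
    if not np.isfinite(ll).any(axis=0).all():
        bad = np.flatnonzero(~np.isfinite(ll).any(axis=0))
        raise ValueError(f"record(s) {bad.tolist()} have no finite log-likelihood draw")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(m)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=0))) if m > 1 else 0.0
    return -2.0 * (lppd - p_waic), p_waic


def compute_lpml(chains: PosteriorChains) -> tuple[float, np.ndarray]:
    """Log pseudo marginal likelihood and per-record CPO values.

    log CPO_i = log(m) - logsumexp(-loglik_i) (harmonic-mean identity).
    """
    ll = chains.per_record_loglik
    m = ll.shape[0]
    log_cpo = np.log(m) - logsumexp(-ll, axis=0)
    if not np.isfinite(log_cpo).all():
        logger.warning("degenerate CPO value(s) detected")
    return float(log_cpo.sum()), np.exp(log_cpo)


def comparison_report(chains: PosteriorChains) -> ComparisonReport:
    dic, p_d = compute_dic(chains)
    waic, p_waic = compute_waic(chains)
    lpml, cpo = compute_lpml(chains)
    return ComparisonReport(dic=dic, p_d=p_d, waic=waic, p_waic=p_waic,
                            lpml=lpml, per_record_cpo=cpo)


def comparison_table(reports: dict[str, ComparisonReport]) -> pd.DataFrame:
    """Two-model (or more) comparison table: DIC, LPML, WAIC per model row."""
    rows = {
        name: {"DIC": r.dic, "pD": r.p_d, "LPML": r.lpml, "WAIC": r.waic,
               "pWAIC": r.p_waic}
        for name, r in reports.items()
    }
    return pd.DataFrame(rows).T[["DIC", "pD", "LPML", "WAIC", "pWAIC"]]
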