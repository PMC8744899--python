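"""Posterior effect reporting, frailty map export and the end-to-end pipeline.

Hazard ratios are the exponentiated posterior mean coefficients with
equal-tailed credible intervals exponentiated endpoint-wise.  The percent
change in hazard is ``(HR - 1) * 100``; following common epidemiological
phrasing, protective effects (HR < 1) are additionally quoted as a
``(1 - HR) * 100`` percent increase in survival.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import AreaGraph, read_adjacency
from .mcmc import (
    FRAILTY_VARIANCE,
    McmcConfig,
    PosteriorChains,
    sample_posterior,
    summary_table,
    trace_summaries,
)
from .model import DEFAULT_VARIABLES, PriorConfig, build_design, validate_records
from .compare import comparison_report, comparison_table
from .residuals import residual_gof, residuals_from_chains

logger = logging.getLogger(__name__)

__all__ = [
    "round_sig",
    "hazard_ratio_report",
    "format_effect_table",
    "frailty_map_export",
    "run_pipeline",
]


def round_sig(x: float, sig: int = 4) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


def hazard_ratio_report(summaries: pd.DataFrame) -> pd.DataFrame:
    """Effect table from a coefficient summary frame.

    ``summaries`` is indexed by effect name with columns
    ``mean, median, sd, ci_low, ci_high`` on the coefficient scale (the
    output of :func:`arealsurv.mcmc.summary_table`); the frailty-variance row,
    if present, is passed through without exponentiation.
    """
    rows = []
    for name, s in summaries.iterrows():
        if name == FRAILTY_VARIANCE:
            continue
        hr = float(np.exp(s["mean"]))
        pct = (hr - 1.0) * 100.0
        rows.append(
            {
                "effect": name,
                "mean": s["mean"],
                "median": s["median"],
                "sd": s["sd"],
                "ci_low": s["ci_low"],
                "ci_high": s["ci_high"],
                "hazard_ratio": hr,
                "hr_ci_low": float(np.exp(s["ci_low"])),
                "hr_ci_high": float(np.exp(s["ci_high"])),
                "percent_change": pct,
                "percent_reported": (1.0 - hr) * 100.0 if hr < 1 else pct,
                "direction": "decrease" if hr < 1 else ("none" if hr == 1 else "increase"),
            }
        )
    return pd.DataFrame(rows).set_index("effect")


def format_effect_table(report: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: coefficients to 4 decimals, ratios to 4 significant
    figures, percents to 2 decimals."""
    out = report.copy()
    for c in ("mean", "median", "sd", "ci_low", "ci_high"):
        out[c] = out[c].round(4)
    for c in ("hazard_ratio", "hr_ci_low", "hr_ci_high"):
        out[c] = out[c].map(lambda v: round_sig(v, 4))
    for c in ("percent_change", "percent_reported"):
        out[c] = out[c].round(2)
    return out


def frailty_map_export(
    chains: PosteriorChains,
    graph: AreaGraph,
    geometry: dict | str | Path | None = None,
    statistic: str = "median",
) -> tuple[pd.DataFrame, dict | None]:
    """Per-area posterior frailty summary, optionally merged into GeoJSON.

    The mapped statistic defaults to the posterior median per area; the mean
    is exported alongside.  When ``geometry`` (a GeoJSON FeatureCollection
    with a ``name`` property per feature) is given, a copy is returned with
    ``frailty_median``/``frailty_mean`` properties added per feature.
    """
    if not chains.is_spatial:
        raise ValueError("frailty map requires chains from the spatial model")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    med = np.median(chains.frailties, axis=0)
    mean = chains.frailties.mean(axis=0)
    table = pd.DataFrame(
        {"area": chains.area_ids, "frailty_median": med, "frailty_mean": mean}
    ).set_index("area")
    geo = None
    if geometry is not None:
        if not isinstance(geometry, dict):
            geometry = json.loads(Path(geometry).read_text())
        geo = json.loads(json.dumps(geometry))  # deep copy
        names = [f.get("properties", {}).get("name") for f in geo.get("features", [])]
        missing = sorted(set(graph.area_ids) - set(names))
        extra = sorted(set(n for n in names if n is not None) - set(graph.area_ids))
        if missing or extra:
            raise ValueError(
                f"geometry/graph label mismatch: missing={missing}, unmatched={extra}"
            )
        for feat in geo["features"]:
            name = feat["properties"]["name"]
            feat["properties"]["frailty_median"] = float(table.loc[name, "frailty_median"])
            feat["properties"]["frailty_mean"] = float(table.loc[name, "frailty_mean"])
    return table, geo


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Fit, compare, diagnose and report in one run.

    ``config`` keys:

    * ``data``: ``{"records": csv path, "adjacency": path}`` — or
      ``synthetic``: kwargs for :class:`~arealsurv.synthetic.SimulationConfig`;
    * ``models``: subset of ``["spatial", "nonspatial"]`` (default both);
    * ``mcmc``: kwargs for :class:`~arealsurv.mcmc.McmcConfig`;
    * ``priors``: kwargs for :class:`~arealsurv.model.PriorConfig`.

    Artifacts (CSV/JSON) land in ``out_dir``; partial artifacts are kept when
    a stage fails, and the failing stage is named in the raised error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    models = config.get("models", ["nonspatial", "spatial"])
    mcmc_cfg = McmcConfig(**config.get("mcmc", {}))
    priors = PriorConfig(**config.get("priors", {}))

    @_stage("load-data")
    def load():
        if "synthetic" in config:
            from .synthetic import SimulationConfig, generate, write_dataset

            ds = generate(SimulationConfig(**config["synthetic"]))
            write_dataset(ds, out_dir / "dataset")
            artifacts["dataset"] = out_dir / "dataset"
            return ds.records, ds.graph
        spec = config["data"]
        records = pd.read_csv(spec["records"])
        graph = read_adjacency(spec["adjacency"])
        return records, graph

    records, graph = load()
    records = validate_records(records, graph)
    design = build_design(records, DEFAULT_VARIABLES)

    chains: dict[str, PosteriorChains] = {}

    @_stage("fit")
    def fit():
        for name in models:
            g = graph if name == "spatial" else None
            chains[name] = sample_posterior(records, design, g, priors, mcmc_cfg)
            tbl = summary_table(chains[name])
            path = out_dir / f"posterior_{name}.csv"
            tbl.to_csv(path)
            artifacts[f"posterior_{name}"] = path

    fit()

    @_stage("compare")
    def compare():
        reports = {name: comparison_report(c) for name, c in chains.items()}
        tbl = comparison_table(reports)
        path = out_dir / "comparison.csv"
        tbl.to_csv(path)
        artifacts["comparison"] = path

    if len(chains) > 1:
        compare()

    @_stage("diagnose")
    def diagnose():
        for name, c in chains.items():
            ts = trace_summaries(c, min_draws=min(100, c.n_draws))
            path = out_dir / f"trace_summary_{name}.csv"
            ts.to_csv(path)
            artifacts[f"trace_summary_{name}"] = path
            slope, curve = residual_gof(residuals_from_chains(c))
            cpath = out_dir / f"residual_curve_{name}.csv"
            curve.to_csv(cpath, index=False)
            artifacts[f"residual_curve_{name}"] = cpath
            (out_dir / f"residual_slope_{name}.json").write_text(
                json.dumps({"slope": slope})
            )
            artifacts[f"residual_slope_{name}"] = out_dir / f"residual_slope_{name}.json"

    diagnose()

    @_stage("report")
    def report():
        name = "spatial" if "spatial" in chains else models[0]
        effects = hazard_ratio_report(summary_table(chains[name]))
        path = out_dir / "effects.csv"
        format_effect_table(effects).to_csv(path)
        artifacts["effects"] = path
        if "spatial" in chains:
            table, _ = frailty_map_export(chains["spatial"], graph)
            fpath = out_dir / "frailty_map.csv"
            table.to_csv(fpath)
            artifacts["frailty_map"] = fpath

    report()

    manifest = {
        "seed": mcmc_cfg.seed,
        "mcmc": {
            "n_iterations": mcmc_cfg.n_iterations,
            "burn_in": mcmc_cfg.burn_in,
            "thinning": mcmc_cfg.thinning,
        },
        "models": list(chains),
        "n_records": int(len(records)),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "acceptance_rates": {k: dict(c.acceptance_rates) for k, c in chains.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = out_dir / "manifest.json"
    return artifacts
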