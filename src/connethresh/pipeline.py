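"""End-to-end orchestration: consistency sweep + sensitivity sweep.

``run_full_analysis`` takes a cohort and a :class:`RunConfig` and writes
a report bundle of delimited tables plus a run-metadata file recording
every convention choice, the seed, and a config hash.  Two runs with the
same config hash produce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consistency import consistency_sweep
from .core import Cohort
from .metrics import MEAN_INVERSE, SUBJECT_METRICS
from .sweep_analysis import (baseline_followup_correlation,
                             cohort_metric_table, cross_threshold_correlation,
                             longitudinal_zscores, sensitivity_sweep)
from .threshold import (ABSOLUTE, DEFAULT_ABSOLUTE_GRID, DEFAULT_DENSITY_GRID,
                        FIXED_DENSITY)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis-wide conventions and grids for one pipeline run."""

    methods: tuple[str, ...] = (FIXED_DENSITY, ABSOLUTE)
    density_grid: tuple[float, ...] = DEFAULT_DENSITY_GRID
    absolute_grid: tuple[float, ...] = DEFAULT_ABSOLUTE_GRID
    metrics: tuple[str, ...] = SUBJECT_METRICS
    efficiency_convention: str = MEAN_INVERSE
    efficiency_channel: str | None = None   # None = binary topology
    test_family: str = "t"
    alpha: float = 0.05
    band_sd_tolerance: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def grid(self, method: str) -> tuple[float, ...]:
        return self.density_grid if method == FIXED_DENSITY else self.absolute_grid

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for k, v in raw.items():
            if k not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def recommended_band(summary: pd.DataFrame, n_nodes: int,
                     sd_tolerance: float = 1.0) -> tuple[float, float] | None:
    """Recommended fixed-density band from a consistency summary.

    Levels whose mean dice is within ``sd_tolerance`` SDs (SD at the
    maximising level) of the maximum mean dice AND where every network
    kept all ``n_nodes`` nodes connected.  Returns the (low, high) bounds
    of the contiguous run containing the argmax, or None when undefined.
    A pure function of the summary table, unit-testable separately.
    """
    dice = summary[summary["statistic"] == "dice"].dropna(subset=["mean"])
    nodes = summary[summary["statistic"] == "connected_node_count"]
    if dice.empty:
        return None
    best = dice.loc[dice["mean"].idxmax()]
    cutoff = best["mean"] - sd_tolerance * best["sd"]
    full_nodes = set(
        nodes[(nodes["mean"] >= n_nodes) & (nodes["sd"].fillna(0) == 0)]
        ["level"]) if not nodes.empty else set()
    ok_levels = sorted(lvl for lvl in dice[dice["mean"] >= cutoff]["level"]
                       if lvl in full_nodes)
    if not ok_levels:
        return None
    levels = sorted(dice["level"])
    # contiguous run (in grid order) containing the argmax level
    idx = {lvl: k for k, lvl in enumerate(levels)}
    ok_idx = sorted(idx[lvl] for lvl in ok_levels)
    best_i = idx[float(best["level"])]
    if best_i not in ok_idx:
        return None
    lo = hi = best_i
    ok_set = set(ok_idx)
    while lo - 1 in ok_set:
        lo -= 1
    while hi + 1 in ok_set:
        hi += 1
    return (levels[lo], levels[hi])


def run_full_analysis(cohort: Cohort, config: RunConfig,
                      out_dir: str | Path) -> dict:
    """Run the full analysis and write the report bundle.

    Emits, per method: the per-level consistency summary (with argmax
    levels), per-subject consistency rows, node-count curves; and per
    method x metric: cross-threshold correlation matrices for baseline
    and change scores, per-level baseline-follow-up r, and the per-level
    mixed-ANOVA table.  ``run_metadata.yaml`` records conventions, seed,
    config hash, and subject exclusions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    n_nodes = len(cohort.node_labels)
    report: dict = {"config_hash": cfg_hash, "methods": {}}
    logger.info("running full analysis on %d subjects (%d nodes), hash %s",
                len(cohort), n_nodes, cfg_hash)

    def _write(df: pd.DataFrame, name: str) -> None:
        df = df.copy()
        df.insert(0, "config_hash", cfg_hash)
        df.to_csv(out_dir / name, index=False)

    for method in config.methods:
        levels = config.grid(method)
        rows, summary = consistency_sweep(cohort, method, levels,
                                          test=config.test_family)
        _write(rows, f"consistency_rows_{method}.csv")
        _write(summary, f"consistency_summary_{method}.csv")
        node_counts = summary[summary["statistic"] == "connected_node_count"]
        _write(node_counts, f"node_counts_{method}.csv")
        band = (recommended_band(summary, n_nodes, config.band_sd_tolerance)
                if method == FIXED_DENSITY else None)
        mreport = {"argmax": summary.attrs["argmax"],
                   "recommended_band": band, "metrics": {}}

        for metric in config.metrics:
            pre = cohort_metric_table(
                cohort, metric, method, levels,
                efficiency_convention=config.efficiency_convention,
                efficiency_channel=config.efficiency_channel)
            lv, xb, xf, ids = pre
            z = longitudinal_zscores(xb, xf, lv, metric)
            corr_base = cross_threshold_correlation(xb, lv)
            corr_change = cross_threshold_correlation(z.change, lv)
            names = [f"{lvl:g}" for lvl in lv]
            pd.DataFrame(corr_base.r_matrix, index=names, columns=names) \
                .to_csv(out_dir / f"corr_baseline_{method}_{metric}.csv")
            pd.DataFrame(corr_change.r_matrix, index=names, columns=names) \
                .to_csv(out_dir / f"corr_change_{method}_{metric}.csv")
            bf_r = baseline_followup_correlation(z)
            _write(pd.DataFrame({"level": lv, "r_baseline_followup": bf_r}),
                   f"baseline_followup_r_{method}_{metric}.csv")
            try:
                anova = sensitivity_sweep(
                    cohort, metric, method, levels, alpha=config.alpha,
                    efficiency_convention=config.efficiency_convention,
                    efficiency_channel=config.efficiency_channel,
                    precomputed=pre)
                _write(anova, f"anova_{method}_{metric}.csv")
                mreport["metrics"][metric] = {
                    "anova_table": f"anova_{method}_{metric}.csv"}
            except Exception as exc:  # e.g. no group covariate
                logger.warning("ANOVA skipped for %s/%s: %s", method, metric,
                               exc)
                mreport["metrics"][metric] = {"anova_table": None,
                                              "anova_skipped": str(exc)}
        report["methods"][method] = mreport

    meta = {
        "config": asdict(config),
        "config_hash": cfg_hash,
        "n_subjects": len(cohort),
        "n_nodes": n_nodes,
        "excluded_partial": cohort.metadata.get("excluded_partial", []),
        "conventions": {
            "efficiency": config.efficiency_convention,
            "efficiency_channel": config.efficiency_channel or "binary",
            "test_vs_unthresholded": config.test_family,
            "zscore_sd": "sample (ddof=1)",
            "median_split_ties": "median element -> low",
            "icc": "one-way random, single measurement, per-subject items",
        },
        "report": report,
    }
    with open(out_dir / "run_metadata.yaml", "w") as fh:
        yaml.safe_dump(_clean(meta), fh, sort_keys=True)
    return report


def _clean(obj):
    """Make numpy scalars/tuples YAML-serializable."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
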