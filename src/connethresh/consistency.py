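"""Scan-rescan consistency statistics per subject and threshold level.

Four statistics per subject x level: dice overlap of kept edge sets,
one-way ICC of NOS over the common kept edges, and one-way ICCs of node
degree and betweenness centrality.  The ICC's "items" are edges or nodes
within one participant, with the two sessions as the k = 2 repeated
measurements; cohort curves average the per-participant ICCs.

Undefined values (empty edge sets, degenerate variance, too few common
edges) are reported as NaN and excluded from summaries with counts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryEdgeSet, Cohort, WeightedConnectome, edge_set
from .metrics import NodeMetricVector, betweenness_centrality, degree
from .threshold import run_sweep

CONSISTENCY_STATS = ("dice", "icc_edge_weight", "icc_degree", "icc_betweenness")


def dice_similarity(a: BinaryEdgeSet, b: BinaryEdgeSet) -> float:
    """``2 |a & b| / (|a| + |b|)``; NaN when both sets are empty."""
    if a.node_count != b.node_count:
        raise ValueError("edge sets have different node counts")
    na, nb = len(a), len(b)
    if na == 0 and nb == 0:
        return float("nan")
    return 2.0 * len(a.edges & b.edges) / (na + nb)


def icc_oneway(measurements: np.ndarray) -> float:
    """One-way random-effects, single-measurement ICC.

    ``measurements`` is an ``items x k`` matrix of repeated measurements.
    With MSb the between-item and MSw the within-item mean square,

        ICC = (MSb - MSw) / (MSb + (k - 1) MSw).

    Negative values are reported as computed (no clamping).  Returns NaN
    when the total variance is zero.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an items x k matrix with >= 2 items, k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("measurements contain missing values")
    n, k = x.shape
    row_means = x.mean(axis=1)
    grand = x.mean()
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((x - row_means[:, None]) ** 2)
    if ssb + ssw <= 0:
        return float("nan")
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


def edge_weight_icc(scan: WeightedConnectome, rescan: WeightedConnectome,
                    kept_scan: BinaryEdgeSet,
                    kept_rescan: BinaryEdgeSet) -> float:
    """ICC of NOS over edges kept in both sessions; NaN if < 2 common edges."""
    common = sorted(kept_scan.edges & kept_rescan.edges)
    if len(common) < 2:
        return float("nan")
    idx = np.array(common)
    x = np.column_stack([scan.nos[idx[:, 0], idx[:, 1]],
                         rescan.nos[idx[:, 0], idx[:, 1]]])
    return icc_oneway(x)


def hub_score_icc(scan_vec: NodeMetricVector,
                  rescan_vec: NodeMetricVector) -> float:
    """ICC of a node metric across sessions, items = all N nodes."""
    if scan_vec.metric_name != rescan_vec.metric_name:
        raise ValueError("metric names differ")
    a, b = scan_vec.values, rescan_vec.values
    if a.shape != b.shape:
        raise ValueError("vectors have different lengths")
    return icc_oneway(np.column_stack([a, b]))


def compare_to_unthresholded(at_level: Sequence[float],
                             unthresholded: Sequence[float],
                             test: str = "t") -> float:
    """Paired two-sided p-value for level-vs-unthresholded mean difference.

    ``test`` is ``"t"`` (paired t, default) or ``"wilcoxon"``.  Pairs with
    a missing value on either side are dropped; fewer than 3 remaining
    pairs, or all-zero differences, yield NaN / 1.0 respectively.
    """
    a = np.asarray(at_level, dtype=float)
    b = np.asarray(unthresholded, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        return float("nan")
    diffs = a - b
    if np.allclose(diffs, 0):
        return 1.0  # identical vectors: no effect by convention
    if test == "t":
        return float(stats.ttest_rel(a, b).pvalue)
    if test == "wilcoxon":
        return float(stats.wilcoxon(a, b).pvalue)
    raise ValueError(f"unknown test family {test!r}")


# ---------------------------------------------------------------------------
# cohort sweep
# ---------------------------------------------------------------------------


def _session_stats(scan: WeightedConnectome, rescan: WeightedConnectome,
                   kept_b: BinaryEdgeSet, kept_f: BinaryEdgeSet,
                   stats_wanted: Sequence[str]) -> dict:
    common = kept_b.edges & kept_f.edges
    nan = float("nan")
    return {
        "dice": dice_similarity(kept_b, kept_f)
        if "dice" in stats_wanted else nan,
        "icc_edge_weight": edge_weight_icc(scan, rescan, kept_b, kept_f)
        if "icc_edge_weight" in stats_wanted else nan,
        "icc_degree": hub_score_icc(degree(kept_b), degree(kept_f))
        if "icc_degree" in stats_wanted else nan,
        "icc_betweenness": hub_score_icc(betweenness_centrality(kept_b),
                                         betweenness_centrality(kept_f))
        if "icc_betweenness" in stats_wanted else nan,
        "n_common_edges": len(common),
    }


def consistency_sweep(cohort: Cohort, method: str,
                      levels: Sequence[float] | None = None,
                      include_unthresholded: bool = True,
                      test: str = "t",
                      stats_wanted: Sequence[str] = CONSISTENCY_STATS
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject consistency statistics across a threshold sweep.

    Returns ``(rows, summary)``.  ``rows`` has one record per subject and
    level (plus, optionally, an unthresholded record per subject with
    ``level = NaN``).  ``summary`` aggregates per level and statistic:
    mean, SD, n, and the paired p-value against unthresholded; its
    ``attrs["argmax"]`` maps each statistic to the level maximising its
    mean.  ``stats_wanted`` restricts which statistics are computed
    (the betweenness ICC dominates run time); the rest are NaN.
    """
    records = []
    for s in cohort.subjects:
        sweep_b = run_sweep(s.baseline, method, levels)
        sweep_f = run_sweep(s.followup, method, levels)
        if include_unthresholded:
            eb, ef = edge_set(s.baseline), edge_set(s.followup)
            rec = _session_stats(s.baseline, s.followup, eb, ef, stats_wanted)
            rec.update(subject_id=s.subject_id, method=method,
                       level=float("nan"),
                       nodes_baseline=int(np.count_nonzero(eb.degrees())),
                       nodes_followup=int(np.count_nonzero(ef.degrees())))
            records.append(rec)
        for tb, tf in zip(sweep_b, sweep_f):
            rec = _session_stats(s.baseline, s.followup, tb.kept, tf.kept,
                                 stats_wanted)
            rec.update(subject_id=s.subject_id, method=method,
                       level=tb.spec.level,
                       nodes_baseline=tb.connected_node_count,
                       nodes_followup=tf.connected_node_count)
            records.append(rec)
    cols = ["subject_id", "method", "level", *CONSISTENCY_STATS,
            "n_common_edges", "nodes_baseline", "nodes_followup"]
    rows = pd.DataFrame.from_records(records, columns=cols)
    summary = summarize_consistency(rows, test=test)
    return rows, summary


def summarize_consistency(rows: pd.DataFrame, test: str = "t") -> pd.DataFrame:
    """Per-level mean/SD/n (+ p vs unthresholded) for each statistic."""
    unthresh = rows[rows["level"].isna()]
    levelled = rows[rows["level"].notna()]
    out = []
    for level, grp in levelled.groupby("level", sort=True):
        for stat in CONSISTENCY_STATS:
            vals = grp[stat]
            p = float("nan")
            if not unthresh.empty:
                merged = grp.set_index("subject_id")[stat].to_frame("lvl").join(
                    unthresh.set_index("subject_id")[stat].to_frame("raw"))
                p = compare_to_unthresholded(merged["lvl"], merged["raw"],
                                             test=test)
            out.append({
                "level": level, "statistic": stat,
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                "n": int(vals.notna().sum()), "p_vs_unthresholded": p,
            })
        out.append({
            "level": level, "statistic": "connected_node_count",
            "mean": float(grp[["nodes_baseline", "nodes_followup"]]
                          .to_numpy().mean()),
            "sd": float(grp[["nodes_baseline", "nodes_followup"]]
                        .to_numpy().std(ddof=1)),
            "n": 2 * len(grp), "p_vs_unthresholded": float("nan"),
        })
    summary = pd.DataFrame(out)
    argmax = {}
    for stat in CONSISTENCY_STATS:
        sub = summary[summary["statistic"] == stat].dropna(subset=["mean"])
        if not sub.empty:
            argmax[stat] = float(sub.loc[sub["mean"].idxmax(), "level"])
    summary.attrs["argmax"] = argmax
    return summary
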