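"""Sensitivity-to-disease-effects analysis across threshold sweeps.

Covers: longitudinal z-scoring of subject-level metrics (follow-up
standardized with the baseline mean/SD), cross-threshold Pearson
correlation matrices of those z-scores, per-level baseline-vs-follow-up
correlations, median-split group assignment, and a 2 x 2 mixed-design
ANOVA (time within, group between) with Cohen's d per effect.

The mixed ANOVA is computed from an explicit decomposition rather than a
stats-package call: for two sessions the design decouples exactly into a
between-subject analysis of subject means and a within-subject analysis
of change scores, giving Type III F statistics with df (1, n - 2) for
each effect, valid for unbalanced groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cohort
from .metrics import MEAN_INVERSE, subject_metric
from .threshold import run_sweep

ANOVA_EFFECTS = ("time", "group", "interaction")


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# z-scores and correlation structure
# ---------------------------------------------------------------------------


@dataclass
class LongitudinalZScores:
    """Baseline-standardized z-scores per subject and threshold level.

    ``z_baseline`` has mean 0 / SD 1 per level by construction (sample
    SD, ddof = 1); ``z_followup`` uses the *baseline* mean and SD so that
    longitudinal change stays on the baseline scale; ``change`` is
    baseline minus follow-up.  Levels with zero baseline SD are NaN and
    listed in ``degenerate_levels``.
    """

    metric_name: str
    levels: np.ndarray
    z_baseline: np.ndarray
    z_followup: np.ndarray
    change: np.ndarray
    degenerate_levels: tuple[float, ...] = ()


def longitudinal_zscores(values_baseline: np.ndarray,
                         values_followup: np.ndarray,
                         levels: Sequence[float] | None = None,
                         metric_name: str = "metric") -> LongitudinalZScores:
    """Standardize a subjects x levels metric table against baseline."""
    xb = np.asarray(values_baseline, dtype=float)
    xf = np.asarray(values_followup, dtype=float)
    if xb.shape != xf.shape or xb.ndim != 2:
        raise AnalysisError("baseline/follow-up must be equal subjects x levels")
    if xb.shape[0] < 3:
        raise AnalysisError("need at least 3 subjects")
    lv = (np.arange(xb.shape[1], dtype=float) if levels is None
          else np.asarray(levels, dtype=float))
    mu = xb.mean(axis=0)
    sd = xb.std(axis=0, ddof=1)
    degen = sd <= 0
    sd_safe = np.where(degen, np.nan, sd)
    zb = (xb - mu) / sd_safe
    zf = (xf - mu) / sd_safe
    return LongitudinalZScores(metric_name, lv, zb, zf, zb - zf,
                               tuple(lv[degen].tolist()))


@dataclass
class CrossThresholdCorrelation:
    """Symmetric unit-diagonal Pearson correlation matrix across levels."""

    levels: np.ndarray
    r_matrix: np.ndarray


def cross_threshold_correlation(values: np.ndarray,
                                levels: Sequence[float] | None = None
                                ) -> CrossThresholdCorrelation:
    """Correlate a subjects x levels matrix between every level pair.

    NaN cells are handled pairwise; degenerate-variance pairs are NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise AnalysisError("need a subjects x levels matrix, >= 3 subjects")
    lv = (np.arange(x.shape[1], dtype=float) if levels is None
          else np.asarray(levels, dtype=float))
    r = pd.DataFrame(x).corr(min_periods=3).to_numpy()
    np.fill_diagonal(r, 1.0)
    return CrossThresholdCorrelation(lv, r)


def baseline_followup_correlation(z: LongitudinalZScores) -> np.ndarray:
    """Per-level Pearson r between baseline and follow-up across subjects."""
    out = np.full(len(z.levels), np.nan)
    for t in range(len(z.levels)):
        a, b = z.z_baseline[:, t], z.z_followup[:, t]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3 and a[ok].std() > 0 and b[ok].std() > 0:
            out[t] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return out


# ---------------------------------------------------------------------------
# groups and ANOVA
# ---------------------------------------------------------------------------


def median_split(wmh_volumes: Mapping[str, float]) -> dict[str, str]:
    """Assign "low"/"high" by median split; ties and the odd-n median
    element go to "low"; missing (NaN) volumes are excluded."""
    present = {k: v for k, v in wmh_volumes.items() if np.isfinite(v)}
    if len(present) < 2:
        raise AnalysisError("need >= 2 subjects with WMH volume")
    vals = np.array(list(present.values()))
    med = float(np.median(vals))
    if np.all(vals == vals[0]):
        raise AnalysisError("all WMH volumes equal; split undefined")
    return {k: ("high" if v > med else "low") for k, v in present.items()}


@dataclass(frozen=True)
class EffectResult:
    F: float
    df: tuple[int, int]
    p: float
    cohens_d: float


@dataclass(frozen=True)
class MixedAnovaResult:
    """F, df, p and Cohen's d for time, group, and interaction effects."""

    effects: dict[str, EffectResult]
    n_per_group: tuple[int, int]

    def __getitem__(self, effect: str) -> EffectResult:
        return self.effects[effect]


def mixed_anova(baseline: Sequence[float], followup: Sequence[float],
                groups: Sequence[str]) -> MixedAnovaResult:
    """2 x 2 mixed ANOVA: time (within) x group (between).

    For k = 2 sessions the split-plot decomposition reduces exactly to
    two independent analyses: subject means ``m = (b + f) / 2`` carry the
    group effect, change scores ``d = b - f`` carry the time and
    interaction effects.  Type III tests (unweighted group means) with
    df (1, n - 2) each.

    Cohen's d conventions (recorded in outputs): time = mean change /
    pooled SD of the two sessions; group = difference of group means of
    subject means / pooled between-subject SD; interaction = difference
    of group mean changes / pooled SD of changes.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    g = np.asarray(groups)
    if not (b.shape == f.shape == g.shape) or b.ndim != 1:
        raise AnalysisError("baseline, followup, groups must be equal 1-D")
    ok = np.isfinite(b) & np.isfinite(f)
    b, f, g = b[ok], f[ok], g[ok]
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise AnalysisError(f"need exactly 2 groups, got {labels}")
    masks = [g == lab for lab in labels]
    n1, n2 = int(masks[0].sum()), int(masks[1].sum())
    if min(n1, n2) < 3:
        raise AnalysisError("each group needs >= 3 subjects")
    n = n1 + n2
    df = (1, n - 2)

    m = (b + f) / 2.0
    d = b - f

    def _pooled_mse(x: np.ndarray) -> tuple[float, float, float]:
        m1, m2 = float(x[masks[0]].mean()), float(x[masks[1]].mean())
        sse = float(((x[masks[0]] - m1) ** 2).sum()
                    + ((x[masks[1]] - m2) ** 2).sum())
        return m1, m2, sse / (n - 2)

    inv = 1.0 / n1 + 1.0 / n2

    def _f_to_p(F: float) -> float:
        return float(stats.f.sf(F, *df))

    # group: two-sample comparison of subject means
    gm1, gm2, mse_m = _pooled_mse(m)
    F_group = ((gm1 - gm2) ** 2 / (mse_m * inv)) if mse_m > 0 else 0.0
    d_group = (gm1 - gm2) / np.sqrt(mse_m) if mse_m > 0 else 0.0

    # time: unweighted mean change against pooled within-group change var
    dm1, dm2, mse_d = _pooled_mse(d)
    theta = (dm1 + dm2) / 2.0
    F_time = (theta ** 2 / (mse_d * inv / 4.0)) if mse_d > 0 else 0.0
    pooled_session_sd = np.sqrt((b.var(ddof=1) + f.var(ddof=1)) / 2.0)
    d_time = (float(d.mean()) / pooled_session_sd
              if pooled_session_sd > 0 else 0.0)

    # interaction: group difference of mean changes
    F_int = ((dm1 - dm2) ** 2 / (mse_d * inv)) if mse_d > 0 else 0.0
    d_int = (dm1 - dm2) / np.sqrt(mse_d) if mse_d > 0 else 0.0

    effects = {
        "time": EffectResult(float(F_time), df, _f_to_p(F_time), float(d_time)),
        "group": EffectResult(float(F_group), df, _f_to_p(F_group),
                              float(d_group)),
        "interaction": EffectResult(float(F_int), df, _f_to_p(F_int),
                                    float(d_int)),
    }
    return MixedAnovaResult(effects, (n1, n2))


# ---------------------------------------------------------------------------
# cohort-level sweeps
# ---------------------------------------------------------------------------


def cohort_metric_table(cohort: Cohort, metric: str, method: str,
                        levels: Sequence[float] | None = None,
                        efficiency_convention: str = MEAN_INVERSE,
                        efficiency_channel: str | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Subject x level metric matrices for both sessions.

    Returns ``(levels, baseline, followup, subject_ids)``.
    """
    xb, xf, ids = [], [], []
    lv: np.ndarray | None = None
    for s in cohort.subjects:
        row_b, row_f = [], []
        sweeps = []
        for conn in (s.baseline, s.followup):
            sweeps.append(run_sweep(conn, method, levels))
        if lv is None:
            lv = np.array([t.spec.level for t in sweeps[0]])
        for tc in sweeps[0]:
            row_b.append(subject_metric(tc, metric, efficiency_convention,
                                        efficiency_channel))
        for tc in sweeps[1]:
            row_f.append(subject_metric(tc, metric, efficiency_convention,
                                        efficiency_channel))
        xb.append(row_b)
        xf.append(row_f)
        ids.append(s.subject_id)
    return lv, np.array(xb), np.array(xf), ids


def cohort_groups(cohort: Cohort, use_median_split: bool = True
                  ) -> dict[str, str]:
    """Group labels per subject: stored labels, else a WMH median split.

    Subjects without a usable label/volume are absent from the result
    (they are excluded from the ANOVA stage only).
    """
    stored = {s.subject_id: s.group for s in cohort.subjects
              if s.group is not None}
    if stored and not use_median_split:
        return stored
    volumes = {s.subject_id: s.wmh_volume for s in cohort.subjects}
    try:
        return median_split(volumes)
    except AnalysisError:
        if stored:
            return stored
        raise


def sensitivity_sweep(cohort: Cohort, metric: str, method: str,
                      levels: Sequence[float] | None = None,
                      alpha: float = 0.05,
                      efficiency_convention: str = MEAN_INVERSE,
                      efficiency_channel: str | None = None,
                      precomputed: tuple | None = None) -> pd.DataFrame:
    """Per-level mixed-ANOVA table for one metric across the sweep.

    Columns: level, per-effect F / p / Cohen's d, df, n per group, and
    the critical F at ``alpha`` for reference.  ``precomputed`` may carry
    the output of :func:`cohort_metric_table` to avoid recomputation.
    """
    lv, xb, xf, ids = (precomputed if precomputed is not None else
                       cohort_metric_table(cohort, metric, method, levels,
                                           efficiency_convention,
                                           efficiency_channel))
    glabels = cohort_groups(cohort)
    keep = [i for i, sid in enumerate(ids) if sid in glabels]
    if len(keep) < 6:
        raise AnalysisError("too few subjects with group labels")
    groups = [glabels[ids[i]] for i in keep]
    rows = []
    for t in range(len(lv)):
        res = mixed_anova(xb[keep, t], xf[keep, t], groups)
        dfd = res["time"].df[1]
        row = {"level": float(lv[t]), "metric": metric, "method": method,
               "df_num": 1, "df_den": dfd,
               "critical_F": float(stats.f.isf(alpha, 1, dfd)),
               "n_low": res.n_per_group[0], "n_high": res.n_per_group[1]}
        for eff in ANOVA_EFFECTS:
            e = res[eff]
            row[f"F_{eff}"] = e.F
            row[f"p_{eff}"] = e.p
            row[f"d_{eff}"] = e.cohens_d
        rows.append(row)
    return pd.DataFrame(rows)
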