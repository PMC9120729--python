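"""Synthetic scan-rescan cohort generator with recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at the matrix level only (no tractography or geometry):

* a fixed connected "true" edge backbone shared by both sessions, with
  log-normal streamline counts and normal FA / MD edge weights;
* low-weight false-positive edges drawn independently per session — the
  mechanism that makes thresholding improve scan-rescan overlap;
* weight-dependent false negatives (a logistic dropout in log NOS, so
  weak connections vanish most often);
* multiplicative subject- and session-level NOS noise;
* a two-group burden effect (lower FA / NOS, higher MD in the high
  group) tied to WMH volume, and a longitudinal decline at follow-up.

Standardized effect sizes (``group_effect_*``, ``decline_per_followup``)
are expressed in units of the cross-sectional subject+session SD of the
corresponding weight channel; the distribution defaults are
order-of-magnitude choices, not fitted to any real cohort.

A single integer seed drives a hierarchical RNG (cohort -> subject ->
session) so subsets are reproducible independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from .core import (BinaryEdgeSet, Cohort, SubjectRecord, WeightedConnectome)

logger = logging.getLogger(__name__)


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (see module docstring)."""

    n_nodes: int = 90
    n_subjects: int = 86
    true_density: float = 0.15
    nos_lognormal_params: tuple[float, float] = (3.0, 1.0)
    fp_rate: float = 0.05
    fp_nos_range: tuple[int, int] = (1, 5)
    fn_logistic_params: tuple[float, float] = (-1.0, -0.6)  # intercept, slope
    session_noise_cv: float = 0.35       # per-edge multiplicative NOS noise
    subject_scale_sd: float = 0.15       # log-scale subject NOS factor
    fa_mean: float = 0.45
    fa_sd: float = 0.08                  # across template edges
    fa_subject_sd: float = 0.006
    fa_session_sd: float = 0.03
    fa_noise_sd: float = 0.02            # per edge per session
    md_mean: float = 8.0e-4              # mm^2/s
    md_sd: float = 5.0e-5
    md_subject_sd: float = 8.0e-6
    md_session_sd: float = 2.5e-5
    md_noise_sd: float = 1.0e-5
    group_effect_fa: float = 0.5         # standardized; high group FA down
    group_effect_md: float = 0.5         # high group MD up
    group_effect_ge_proxy: float = 0.5   # high group NOS scale down
    decline_per_followup: float = 0.3    # FA/NOS down, MD up at follow-up
    wmh_lognormal_params: tuple[float, float] = (1.5, 0.8)
    followup_months_range: tuple[float, float] = (22.0, 35.0)
    redraw_disconnected: bool = True
    max_redraws: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("fp_rate", "true_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise GeneratorError(f"{name} must be in [0, 1]")
        for name in ("nos_lognormal_params",):
            if getattr(self, name)[1] <= 0:
                raise GeneratorError(f"{name} sigma must be > 0")
        if self.n_nodes < 3:
            raise GeneratorError("need at least 3 nodes")
        if self.fp_nos_range[0] < 1 or self.fp_nos_range[1] < self.fp_nos_range[0]:
            raise GeneratorError("invalid fp_nos_range")
        median_nos = math.exp(self.nos_lognormal_params[0])
        if self.fp_nos_range[1] >= median_nos:
            logger.warning(
                "false-positive NOS range %s overlaps the bulk of true-edge "
                "weights (median %.1f); low-weight false positives are the "
                "premise of weight-based thresholding", self.fp_nos_range,
                median_nos)

    # -- convenience presets -------------------------------------------------
    def null(self) -> "GeneratorConfig":
        """Same noise structure but no group or time effects."""
        return replace(self, group_effect_fa=0.0, group_effect_md=0.0,
                       group_effect_ge_proxy=0.0, decline_per_followup=0.0)

    def noise_free(self) -> "GeneratorConfig":
        """No session-level randomness at all: rescan is a byte-identical
        copy of scan (subject-level variation is retained)."""
        return replace(self.null(), fp_rate=0.0,
                       fn_logistic_params=(-1e9, 0.0), session_noise_cv=0.0,
                       fa_session_sd=0.0, fa_noise_sd=0.0,
                       md_session_sd=0.0, md_noise_sd=0.0)

    @property
    def combined_fa_sd(self) -> float:
        return math.hypot(self.fa_subject_sd, self.fa_session_sd)

    @property
    def combined_md_sd(self) -> float:
        return math.hypot(self.md_subject_sd, self.md_session_sd)


@dataclass
class Template:
    """The true backbone shared by every subject and session."""

    n_nodes: int
    pairs: np.ndarray          # (E, 2) true edges, canonical order
    nos: np.ndarray            # (E,) template streamline counts, >= 1
    fa: np.ndarray             # (E,)
    md: np.ndarray             # (E,)
    absent_pairs: np.ndarray   # (P - E, 2) candidate false-positive slots

    @property
    def edge_set(self) -> BinaryEdgeSet:
        return BinaryEdgeSet(self.n_nodes, self.pairs)


@dataclass
class SubjectParams:
    subject_id: str
    group: str                  # "low" / "high"
    log_scale: float            # subject NOS log-scale factor
    fa_offset: float
    md_offset: float
    wmh_volume: float
    followup_months: float


@dataclass
class SessionTruth:
    fp_pairs: np.ndarray
    fn_pairs: np.ndarray
    connected: bool
    redraws: int


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of the injected structure."""

    config: GeneratorConfig
    seed: int
    true_edge_set: BinaryEdgeSet
    subjects: dict[str, SubjectParams] = field(default_factory=dict)
    sessions: dict[tuple[str, str], SessionTruth] = field(default_factory=dict)

    @property
    def groups(self) -> dict[str, str]:
        return {sid: p.group for sid, p in self.subjects.items()}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _all_pairs(n: int) -> np.ndarray:
    iu, ju = np.triu_indices(n, 1)
    return np.column_stack([iu, ju])


def _is_connected(n: int, pairs: np.ndarray) -> bool:
    if len(pairs) < n - 1:
        return False
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = n
    for i, j in pairs:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri
            comps -= 1
            if comps == 1:
                return True
    return comps == 1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_template(cfg: GeneratorConfig,
                      rng: np.random.Generator | None = None) -> Template:
    """Sample the connected true backbone and its template edge weights."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_nodes
    pairs = _all_pairs(n)
    possible = len(pairs)
    n_edges = int(math.floor(cfg.true_density * possible + 0.5))
    if n_edges < n - 1:
        raise GeneratorError(
            f"true_density {cfg.true_density} gives {n_edges} edges, fewer "
            f"than the {n - 1} needed for connectivity")
    pair_index = {(int(i), int(j)): k for k, (i, j) in enumerate(pairs)}
    mask = None
    for _ in range(200):
        chosen = rng.choice(possible, size=n_edges, replace=False)
        chosen.sort()
        if _is_connected(n, pairs[chosen]):
            mask = np.zeros(possible, dtype=bool)
            mask[chosen] = True
            break
    if mask is None:
        # near-tree densities: rejection sampling is hopeless, so build a
        # random spanning tree first and fill the remainder uniformly
        mask = np.zeros(possible, dtype=bool)
        for v in range(1, n):
            u = int(rng.integers(0, v))
            mask[pair_index[(u, v)]] = True
        free = np.nonzero(~mask)[0]
        extra = rng.choice(free, size=n_edges - (n - 1), replace=False)
        mask[extra] = True
    edge_pairs = pairs[mask]
    mu, sigma = cfg.nos_lognormal_params
    nos = np.maximum(np.round(rng.lognormal(mu, sigma, n_edges)), 1.0)
    fa = np.clip(rng.normal(cfg.fa_mean, cfg.fa_sd, n_edges), 0.05, 0.95)
    md = np.maximum(rng.normal(cfg.md_mean, cfg.md_sd, n_edges),
                    cfg.md_mean / 10)
    return Template(n, edge_pairs, nos, fa, md, pairs[~mask])


def _session_once(template: Template, subj: SubjectParams, session_index: int,
                  cfg: GeneratorConfig, rng: np.random.Generator
                  ) -> tuple[WeightedConnectome, np.ndarray, np.ndarray]:
    n = template.n_nodes
    is_followup = session_index == 1
    high = subj.group == "high"

    # ---- which edges survive / appear -------------------------------------
    a, b = cfg.fn_logistic_params
    p_drop = _sigmoid(a + b * np.log(template.nos))
    dropped = rng.random(len(template.nos)) < p_drop
    fp_mask = rng.random(len(template.absent_pairs)) < cfg.fp_rate
    fp_pairs = template.absent_pairs[fp_mask]
    fn_pairs = template.pairs[dropped]

    # ---- NOS --------------------------------------------------------------
    log_scale = subj.log_scale
    if high:
        log_scale -= cfg.group_effect_ge_proxy * cfg.subject_scale_sd
    if is_followup:
        log_scale -= cfg.decline_per_followup * cfg.subject_scale_sd
    noise = (rng.lognormal(0.0, cfg.session_noise_cv, len(template.nos))
             if cfg.session_noise_cv > 0 else 1.0)
    nos_true = np.maximum(
        np.round(template.nos * math.exp(log_scale) * noise), 1.0)
    nos_true[dropped] = 0.0
    lo, hi = cfg.fp_nos_range
    nos_fp = rng.integers(lo, hi + 1, len(fp_pairs)).astype(float)

    # ---- FA / MD ----------------------------------------------------------
    fa_shift = subj.fa_offset + (rng.normal(0.0, cfg.fa_session_sd)
                                 if cfg.fa_session_sd > 0 else 0.0)
    md_shift = subj.md_offset + (rng.normal(0.0, cfg.md_session_sd)
                                 if cfg.md_session_sd > 0 else 0.0)
    if high:
        fa_shift -= cfg.group_effect_fa * cfg.combined_fa_sd
        md_shift += cfg.group_effect_md * cfg.combined_md_sd
    if is_followup:
        fa_shift -= cfg.decline_per_followup * cfg.combined_fa_sd
        md_shift += cfg.decline_per_followup * cfg.combined_md_sd

    def _edge_fa(base: np.ndarray) -> np.ndarray:
        jitter = (rng.normal(0.0, cfg.fa_noise_sd, len(base))
                  if cfg.fa_noise_sd > 0 else 0.0)
        return np.clip(base + fa_shift + jitter, 0.01, 0.99)

    def _edge_md(base: np.ndarray) -> np.ndarray:
        jitter = (rng.normal(0.0, cfg.md_noise_sd, len(base))
                  if cfg.md_noise_sd > 0 else 0.0)
        return np.maximum(base + md_shift + jitter, cfg.md_mean / 20)

    fa_true = _edge_fa(template.fa)
    md_true = _edge_md(template.md)
    fa_fp = _edge_fa(np.clip(rng.normal(cfg.fa_mean, cfg.fa_sd, len(fp_pairs)),
                             0.05, 0.95))
    md_fp = _edge_md(np.maximum(rng.normal(cfg.md_mean, cfg.md_sd,
                                           len(fp_pairs)), cfg.md_mean / 10))

    # ---- assemble matrices ------------------------------------------------
    nos_m = np.zeros((n, n))
    fa_m = np.zeros((n, n))
    md_m = np.zeros((n, n))
    present = ~dropped
    ti, tj = template.pairs[present, 0], template.pairs[present, 1]
    nos_m[ti, tj] = nos_true[present]
    fa_m[ti, tj] = fa_true[present]
    md_m[ti, tj] = md_true[present]
    if len(fp_pairs):
        fi, fj = fp_pairs[:, 0], fp_pairs[:, 1]
        nos_m[fi, fj] = nos_fp
        fa_m[fi, fj] = fa_fp
        md_m[fi, fj] = md_fp
    for m in (nos_m, fa_m, md_m):
        m += m.T
    labels = tuple(f"region_{k:03d}" for k in range(n))
    conn = WeightedConnectome(labels, {"NOS": nos_m, "FA": fa_m, "MD": md_m})
    return conn, fp_pairs, fn_pairs


def generate_session(template: Template, subj: SubjectParams,
                     session_index: int, cfg: GeneratorConfig,
                     rng: np.random.Generator | np.random.SeedSequence
                     ) -> tuple[WeightedConnectome, SessionTruth]:
    """One session for one subject; optionally redraw disconnected graphs.

    ``rng`` should be a :class:`numpy.random.SeedSequence` when redraws
    are enabled so each attempt gets an independent stream.
    """
    if isinstance(rng, np.random.SeedSequence):
        streams = rng.spawn(max(cfg.max_redraws, 1))
    else:
        streams = None
        gen = rng
    attempts = max(cfg.max_redraws, 1) if cfg.redraw_disconnected else 1
    conn = fp = fn = None
    connected = False
    for attempt in range(attempts):
        gen_a = (np.random.default_rng(streams[attempt])
                 if streams is not None else gen)
        conn, fp, fn = _session_once(template, subj, session_index, cfg, gen_a)
        pairs = np.column_stack(np.nonzero(np.triu(conn.nos, 1) > 0))
        connected = _is_connected(template.n_nodes, pairs)
        if connected or not cfg.redraw_disconnected:
            break
    if not connected:
        logger.warning("%s session %d remained disconnected after %d draws",
                       subj.subject_id, session_index, attempts)
    return conn, SessionTruth(fp, fn, connected, attempt)


def generate_cohort(cfg: GeneratorConfig
                    ) -> tuple[Cohort, SyntheticGroundTruth]:
    """Full scan-rescan cohort plus its ground truth, from one seed."""
    root = np.random.SeedSequence(cfg.seed)
    template_ss, assign_ss, *subject_ss = root.spawn(cfg.n_subjects + 2)
    template = generate_template(cfg, np.random.default_rng(template_ss))
    truth = SyntheticGroundTruth(cfg, cfg.seed, template.edge_set)

    arng = np.random.default_rng(assign_ss)
    order = arng.permutation(cfg.n_subjects)
    n_high = cfg.n_subjects // 2
    groups = np.array(["low"] * cfg.n_subjects, dtype=object)
    groups[order[:n_high]] = "high"
    wmu, wsd = cfg.wmh_lognormal_params
    # high group from the upper half of the volume distribution, low from
    # the lower half, so a median split recovers the assignment
    z = np.abs(arng.normal(size=cfg.n_subjects))
    wmh = np.where(groups == "high", np.exp(wmu + wsd * z),
                   np.exp(wmu - wsd * z))
    months = arng.uniform(*cfg.followup_months_range, cfg.n_subjects)

    subjects = []
    for s in range(cfg.n_subjects):
        sid = f"sub-{s + 1:03d}"
        s_ss = subject_ss[s]
        param_ss, base_ss, follow_ss = s_ss.spawn(3)
        prng = np.random.default_rng(param_ss)
        params = SubjectParams(
            subject_id=sid,
            group=str(groups[s]),
            log_scale=prng.normal(0.0, cfg.subject_scale_sd),
            fa_offset=prng.normal(0.0, cfg.fa_subject_sd),
            md_offset=prng.normal(0.0, cfg.md_subject_sd),
            wmh_volume=float(wmh[s]),
            followup_months=float(months[s]),
        )
        baseline, t0 = generate_session(template, params, 0, cfg, base_ss)
        followup, t1 = generate_session(template, params, 1, cfg, follow_ss)
        truth.subjects[sid] = params
        truth.sessions[(sid, "baseline")] = t0
        truth.sessions[(sid, "followup")] = t1
        subjects.append(SubjectRecord(
            sid, baseline, followup, group=params.group,
            wmh_volume=params.wmh_volume,
            followup_months=params.followup_months))
    meta = {"generator": "connethresh.synth", "seed": cfg.seed,
            "config": asdict(cfg)}
    return Cohort(subjects, metadata=meta), truth
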