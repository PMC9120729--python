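"""Data model, validation, and delimited-text I/O for weighted connectomes.

A connectome is an undirected weighted graph over ``N`` labelled brain
regions, carried as dense symmetric matrices for up to three weight
channels:

``NOS``
    streamline count (non-negative; the thresholding weight),
``FA``
    fractional anisotropy (unitless, in ``[0, 1]``),
``MD``
    mean diffusivity (positive, mm^2/s).

FA and MD may only be non-zero where NOS is non-zero: microstructural
weights are attributes of detected connections.

Matrices travel as dense delimited text (comma or tab, autodetected) with
a plain-text sidecar listing region labels, one per line.  A cohort is a
set of subjects with paired baseline / follow-up connectomes plus group
covariates, described by a delimited manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised weight channels, in canonical order.
CHANNELS = ("NOS", "FA", "MD")

#: Tolerance for symmetry checks on loaded matrices.
SYMMETRY_ATOL = 1e-8


class ConnectomeError(ValueError):
    """Raised when a connectome or cohort violates its invariants."""


# ---------------------------------------------------------------------------
# edge sets
# ---------------------------------------------------------------------------


class BinaryEdgeSet:
    """Set of unordered node pairs on ``node_count`` nodes.

    Pairs are stored canonically with ``i < j``, deduplicated, and sorted
    lexicographically.  The class is immutable and hashable on its content.

    Parameters
    ----------
    node_count : int
        Number of nodes ``N`` (>= 2).
    pairs : iterable of (int, int) or (E, 2) array
        Edges; order and orientation are irrelevant.
    """

    __slots__ = ("node_count", "_pairs", "_frozen")

    def __init__(self, node_count: int, pairs: Iterable[tuple[int, int]] | np.ndarray):
        if node_count < 2:
            raise ConnectomeError(f"need at least 2 nodes, got {node_count}")
        arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                         dtype=np.int64)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ConnectomeError("pairs must be an (E, 2) collection")
        if arr.size and (arr.min() < 0 or arr.max() >= node_count):
            raise ConnectomeError("edge endpoint out of range")
        if arr.size and np.any(arr[:, 0] == arr[:, 1]):
            raise ConnectomeError("self-pairs are not allowed")
        lo = np.minimum(arr[:, 0], arr[:, 1])
        hi = np.maximum(arr[:, 0], arr[:, 1])
        canon = np.unique(np.column_stack([lo, hi]), axis=0)
        object.__setattr__(self, "node_count", node_count)
        object.__setattr__(self, "_pairs", canon)
        object.__setattr__(self, "_frozen", None)

    def __setattr__(self, name, value):  # immutability
        raise AttributeError("BinaryEdgeSet is immutable")

    # -- container protocol -------------------------------------------------
    @property
    def pairs(self) -> np.ndarray:
        """Canonical ``(E, 2)`` integer array, read-only view."""
        v = self._pairs.view()
        v.flags.writeable = False
        return v

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        """Edges as a frozenset of ``(i, j)`` tuples with ``i < j``."""
        if self._frozen is None:
            object.__setattr__(self, "_frozen",
                               frozenset(map(tuple, self._pairs.tolist())))
        return self._frozen

    def __len__(self) -> int:
        return self._pairs.shape[0]

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.edges

    def __iter__(self):
        return iter(self.edges)

    def __eq__(self, other) -> bool:
        return (isinstance(other, BinaryEdgeSet)
                and self.node_count == other.node_count
                and self._pairs.shape == other._pairs.shape
                and bool(np.array_equal(self._pairs, other._pairs)))

    def __hash__(self) -> int:
        return hash((self.node_count, self.edges))

    def __repr__(self) -> str:
        return f"BinaryEdgeSet(N={self.node_count}, |E|={len(self)})"

    # -- set algebra ---------------------------------------------------------
    def intersection(self, other: "BinaryEdgeSet") -> "BinaryEdgeSet":
        if self.node_count != other.node_count:
            raise ConnectomeError("node counts differ")
        return BinaryEdgeSet(self.node_count, list(self.edges & other.edges))

    def issubset(self, other: "BinaryEdgeSet") -> bool:
        return self.edges <= other.edges

    # -- conversions ---------------------------------------------------------
    def to_adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix."""
        a = np.zeros((self.node_count, self.node_count), dtype=bool)
        if len(self):
            i, j = self._pairs[:, 0], self._pairs[:, 1]
            a[i, j] = True
            a[j, i] = True
        return a

    def degrees(self) -> np.ndarray:
        """Integer degree per node."""
        d = np.zeros(self.node_count, dtype=np.int64)
        if len(self):
            np.add.at(d, self._pairs[:, 0], 1)
            np.add.at(d, self._pairs[:, 1], 1)
        return d


# ---------------------------------------------------------------------------
# connectome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightedConnectome:
    """Multi-channel weighted undirected network over labelled nodes.

    Attributes
    ----------
    node_labels : tuple of str
        Region names; their order fixes node indices.
    weights : dict
        Maps channel name (subset of :data:`CHANNELS`) to a dense
        symmetric ``N x N`` float matrix with zero diagonal.
    """

    node_labels: tuple[str, ...]
    weights: Mapping[str, np.ndarray]

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.weights[name]
        except KeyError:
            raise ConnectomeError(f"channel {name!r} not present") from None

    @property
    def nos(self) -> np.ndarray:
        return self.channel("NOS")

    def validate(self, atol: float = SYMMETRY_ATOL) -> "WeightedConnectome":
        """Check all invariants, returning ``self``; raise on violation."""
        n = self.n_nodes
        if n < 3:
            raise ConnectomeError(f"need N >= 3 nodes, got {n}")
        if "NOS" not in self.weights:
            raise ConnectomeError("NOS channel is required")
        for ch, m in self.weights.items():
            if ch not in CHANNELS:
                raise ConnectomeError(f"unknown channel {ch!r}")
            if m.shape != (n, n):
                raise ConnectomeError(
                    f"{ch}: shape {m.shape} does not match {n} labels")
            delta = np.abs(m - m.T)
            if delta.max(initial=0.0) > atol:
                i, j = np.unravel_index(np.argmax(delta), delta.shape)
                raise ConnectomeError(
                    f"{ch}: asymmetric at cell ({i}, {j}): "
                    f"{m[i, j]!r} vs {m[j, i]!r}")
            if np.any(np.abs(np.diag(m)) > atol):
                k = int(np.argmax(np.abs(np.diag(m))))
                raise ConnectomeError(f"{ch}: nonzero diagonal at node {k}")
            if not np.all(np.isfinite(m)):
                raise ConnectomeError(f"{ch}: non-finite entries")
        nos = self.weights["NOS"]
        if nos.min(initial=0.0) < 0:
            raise ConnectomeError("NOS has negative entries")
        if not np.allclose(nos, np.round(nos)):
            logger.warning("NOS contains fractional values; treating them as "
                           "streamline densities")
        support = nos > 0
        for ch in ("FA", "MD"):
            if ch in self.weights:
                bad = (self.weights[ch] != 0) & ~support
                if bad.any():
                    ii, jj = np.nonzero(np.triu(bad, 1))
                    cells = list(zip(ii.tolist(), jj.tolist()))[:10]
                    raise ConnectomeError(
                        f"{ch} nonzero where NOS = 0 at edges {cells}")
        if "FA" in self.weights:
            fa = self.weights["FA"]
            if fa.min(initial=0.0) < 0 or fa.max(initial=0.0) > 1:
                raise ConnectomeError("FA outside [0, 1]")
        if "MD" in self.weights and self.weights["MD"].min(initial=0.0) < 0:
            raise ConnectomeError("MD has negative entries")
        return self


def edge_set(c: WeightedConnectome) -> BinaryEdgeSet:
    """Binary topology: pair ``(i, j)`` is an edge iff ``NOS[i, j] > 0``."""
    iu, ju = np.nonzero(np.triu(c.nos, 1) > 0)
    return BinaryEdgeSet(c.n_nodes, np.column_stack([iu, ju]))


def network_density(e: BinaryEdgeSet) -> float:
    """Proportion of present edges among all ``N (N - 1) / 2`` possible."""
    possible = e.node_count * (e.node_count - 1) / 2
    return len(e) / possible


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """One participant with paired baseline and follow-up connectomes."""

    subject_id: str
    baseline: WeightedConnectome
    followup: WeightedConnectome
    group: str | None = None          # "low" / "high" burden label, if assigned
    wmh_volume: float = float("nan")  # ml; NaN = missing
    followup_months: float = float("nan")

    def __post_init__(self):
        if self.baseline.node_labels != self.followup.node_labels:
            raise ConnectomeError(
                f"{self.subject_id}: sessions have different node labels")
        if self.group is not None and self.group not in ("low", "high"):
            raise ConnectomeError(f"invalid group label {self.group!r}")

    @property
    def has_wmh(self) -> bool:
        return not np.isnan(self.wmh_volume)


@dataclass
class Cohort:
    """Subjects sharing one parcellation, plus free-form provenance."""

    subjects: list[SubjectRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ConnectomeError("duplicate subject ids in cohort")
        labels = {s.baseline.node_labels for s in self.subjects}
        if len(labels) > 1:
            raise ConnectomeError("subjects do not share node labels")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.subjects[0].baseline.node_labels


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if "," in line:
                    return ","
                if "\t" in line:
                    return "\t"
                return None  # whitespace
    raise ConnectomeError(f"{path}: empty file")


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a dense numeric matrix from delimited text (autodetected)."""
    path = Path(path)
    m = np.loadtxt(path, delimiter=_sniff_delimiter(path), ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ConnectomeError(f"{path}: matrix is {m.shape}, not square")
    return m


def write_matrix(path: str | Path, m: np.ndarray) -> None:
    np.savetxt(path, m, delimiter=",", fmt="%.17g")


def read_labels(path: str | Path) -> tuple[str, ...]:
    with open(path) as fh:
        labels = tuple(line.strip() for line in fh if line.strip())
    if not labels:
        raise ConnectomeError(f"{path}: no labels")
    return labels


def load_connectome(matrix_paths: Mapping[str, str | Path],
                    labels_path: str | Path) -> WeightedConnectome:
    """Load and validate a connectome from per-channel matrix files.

    Parameters
    ----------
    matrix_paths : mapping
        Channel name (``NOS`` required; ``FA`` / ``MD`` optional) to the
        path of its dense delimited matrix.
    labels_path : path
        Text file with one region name per line; the line count must
        match the matrix dimension.
    """
    labels = read_labels(labels_path)
    weights = {}
    for ch, p in matrix_paths.items():
        m = read_matrix(p)
        if m.shape[0] != len(labels):
            raise ConnectomeError(
                f"{p}: matrix is {m.shape[0]}x{m.shape[0]} but labels file "
                f"has {len(labels)} lines")
        weights[ch] = m
    return WeightedConnectome(labels, weights).validate()


def write_connectome(c: WeightedConnectome, out_dir: str | Path,
                     stem: str = "connectome") -> dict[str, Path]:
    """Write one file per channel plus the labels sidecar; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ch, m in c.weights.items():
        p = out_dir / f"{stem}_{ch}.csv"
        write_matrix(p, m)
        paths[ch] = p
    lp = out_dir / f"{stem}_labels.txt"
    lp.write_text("\n".join(c.node_labels) + "\n")
    paths["labels"] = lp
    return paths


MANIFEST_COLUMNS = ("subject_id", "session", "group", "wmh_volume",
                    "followup_months", "nos_path", "fa_path", "md_path",
                    "labels_path")

_SESSIONS = ("baseline", "followup")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write all matrices plus a ``manifest.csv``; return the manifest path."""
    out_dir = Path(out_dir)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        for session in _SESSIONS:
            conn = getattr(s, session)
            paths = write_connectome(conn, mat_dir, f"{s.subject_id}_{session}")
            rows.append({
                "subject_id": s.subject_id,
                "session": session,
                "group": s.group if s.group is not None else "",
                "wmh_volume": s.wmh_volume,
                "followup_months": s.followup_months,
                "nos_path": paths["NOS"].relative_to(out_dir).as_posix(),
                "fa_path": paths["FA"].relative_to(out_dir).as_posix()
                if "FA" in paths else "",
                "md_path": paths["MD"].relative_to(out_dir).as_posix()
                if "MD" in paths else "",
                "labels_path": paths["labels"].relative_to(out_dir).as_posix(),
            })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest,
                                                              index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a manifest table.

    Subjects missing either session are excluded with a warning; their
    ids are recorded under ``metadata["excluded_partial"]``.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype={"subject_id": str, "session": str})
    for col in ("subject_id", "session", "nos_path", "labels_path"):
        if col not in df.columns:
            raise ConnectomeError(f"manifest missing column {col!r}")
    subjects: list[SubjectRecord] = []
    excluded: list[str] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        sessions = dict(zip(grp["session"], grp.index))
        if not all(s in sessions for s in _SESSIONS):
            excluded.append(str(sid))
            continue
        conns = {}
        row0 = grp.loc[sessions["baseline"]]
        for session in _SESSIONS:
            row = grp.loc[sessions[session]]
            mpaths = {"NOS": base / row["nos_path"]}
            for ch, col in (("FA", "fa_path"), ("MD", "md_path")):
                if col in row and isinstance(row[col], str) and row[col]:
                    mpaths[ch] = base / row[col]
            conns[session] = load_connectome(mpaths, base / row["labels_path"])
        group = row0.get("group")
        group = group if isinstance(group, str) and group else None
        wmh = float(row0["wmh_volume"]) if "wmh_volume" in row0 and \
            pd.notna(row0["wmh_volume"]) else float("nan")
        months = float(row0["followup_months"]) if "followup_months" in row0 \
            and pd.notna(row0["followup_months"]) else float("nan")
        subjects.append(SubjectRecord(str(sid), conns["baseline"],
                                      conns["followup"], group=group,
                                      wmh_volume=wmh, followup_months=months))
    if excluded:
        logger.info("excluded %d subjects with a missing session: %s",
                    len(excluded), excluded)
    return Cohort(subjects, metadata={"manifest": str(manifest_path),
                                      "excluded_partial": excluded})
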