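"""MST-anchored fixed-density and absolute thresholding of connectomes.

Both strategies filter the NOS channel and mask FA/MD to the surviving
edges.  Fixed-density thresholding first takes the maximum spanning tree
of the NOS graph (so the network can never fragment) and then adds the
remaining edges from strongest to weakest NOS until the target density is
reached.  Absolute thresholding simply drops every edge with fewer than
``min_streamlines`` streamlines and offers no connectivity guarantee.

Ties in NOS are broken deterministically by ``(NOS desc, i asc, j asc)``
so that sweeps are reproducible and density-nested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (BinaryEdgeSet, WeightedConnectome, edge_set,
                   network_density)

FIXED_DENSITY = "fixed_density"
ABSOLUTE = "absolute"

#: Default sweep grids: densities .02 to .40 in steps of .01, and
#: absolute cut-offs 1 to 40 streamlines in steps of 1.
DEFAULT_DENSITY_GRID = tuple(np.round(np.arange(2, 41) / 100, 2).tolist())
DEFAULT_ABSOLUTE_GRID = tuple(range(1, 41))


class ThresholdError(ValueError):
    """Raised for invalid threshold specs or unthresholdable inputs."""


class DisconnectedGraphError(ThresholdError):
    """NOS graph does not span all nodes; MST is undefined."""

    def __init__(self, component_sizes: Sequence[int]):
        self.component_sizes = sorted(component_sizes, reverse=True)
        super().__init__(
            "NOS graph is disconnected; component sizes: "
            f"{self.component_sizes}")


@dataclass(frozen=True)
class ThresholdSpec:
    """Which thresholding method at which level."""

    method: str
    level: float

    def __post_init__(self):
        if self.method not in (FIXED_DENSITY, ABSOLUTE):
            raise ThresholdError(f"unknown method {self.method!r}")
        if self.method == ABSOLUTE:
            if self.level < 1:
                raise ThresholdError("absolute level must be >= 1")
        elif not 0 < self.level <= 1:
            raise ThresholdError("density level must be in (0, 1]")


@dataclass
class ThresholdedConnectome:
    """Result of applying one :class:`ThresholdSpec` to one connectome."""

    source: WeightedConnectome
    spec: ThresholdSpec
    kept: BinaryEdgeSet
    achieved_density: float
    connected_node_count: int
    shortfall: bool = False  # source had fewer edges than the target

    @property
    def n_nodes(self) -> int:
        return self.source.n_nodes

    def masked(self, channel: str) -> np.ndarray:
        """Channel matrix with non-kept cells zeroed."""
        m = np.where(self.kept.to_adjacency(), self.source.channel(channel), 0.0)
        return m

    def to_connectome(self) -> WeightedConnectome:
        """A standalone connectome carrying only the kept edges."""
        weights = {ch: self.masked(ch) for ch in self.source.weights}
        return WeightedConnectome(self.source.node_labels, weights)


# ---------------------------------------------------------------------------
# edge ordering and MST
# ---------------------------------------------------------------------------


def _ordered_edges(c: WeightedConnectome) -> tuple[np.ndarray, np.ndarray]:
    """Present edges ordered by (NOS desc, i asc, j asc).

    Returns ``(pairs, weights)`` where ``pairs`` is ``(E, 2)``.
    """
    nos = np.triu(c.nos, 1)
    i, j = np.nonzero(nos > 0)
    w = nos[i, j]
    order = np.lexsort((j, i, -w))
    return np.column_stack([i, j])[order], w[order]


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def _mst_order(c: WeightedConnectome) -> tuple[np.ndarray, np.ndarray]:
    """Split the ordered edges into (MST edges, remaining edges).

    Kruskal-style greedy pass over edges sorted strongest-first, skipping
    any edge that would close a cycle.  Raises
    :class:`DisconnectedGraphError` when the NOS graph does not span all
    nodes, reporting component sizes.
    """
    n = c.n_nodes
    pairs, _ = _ordered_edges(c)
    uf = _UnionFind(n)
    in_tree = np.zeros(len(pairs), dtype=bool)
    taken = 0
    for k in range(len(pairs)):
        if uf.union(int(pairs[k, 0]), int(pairs[k, 1])):
            in_tree[k] = True
            taken += 1
            if taken == n - 1:
                break
    if taken < n - 1:
        from collections import Counter
        sizes = Counter(uf.find(v) for v in range(n))
        raise DisconnectedGraphError(list(sizes.values()))
    return pairs[in_tree], pairs[~in_tree]


def maximum_spanning_tree(c: WeightedConnectome) -> BinaryEdgeSet:
    """Maximum-NOS spanning tree of a connected connectome.

    Exactly ``N - 1`` edges forming an acyclic subgraph that spans all
    nodes with maximal total NOS weight.
    """
    tree, _ = _mst_order(c)
    return BinaryEdgeSet(c.n_nodes, tree)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def apply_fixed_density(c: WeightedConnectome, target_density: float,
                        *, clamp_to_mst: bool = True) -> ThresholdedConnectome:
    """Threshold to a fixed density, anchored on the maximum spanning tree.

    The kept set is the MST plus the strongest remaining edges until the
    edge count reaches ``round(target_density * N(N-1)/2)``.  Targets
    below the MST density ``2/N`` are clamped to the MST when
    ``clamp_to_mst`` is true (the sweep grid's nominal .02 level sits
    marginally below ``2/N`` for N = 90); otherwise they raise.
    Sources with fewer edges than the target keep everything and are
    flagged with ``shortfall``.
    """
    n = c.n_nodes
    possible = n * (n - 1) // 2
    target_count = _round_half_away(target_density * possible)
    if target_count < n - 1:
        if not clamp_to_mst:
            raise ThresholdError(
                f"target density {target_density} is below the MST density "
                f"2/N = {2 / n:.4f}")
        target_count = n - 1
    tree, rest = _mst_order(c)
    n_fill = min(target_count - (n - 1), len(rest))
    kept_pairs = np.vstack([tree, rest[:n_fill]])
    kept = BinaryEdgeSet(n, kept_pairs)
    shortfall = len(kept) < target_count
    return ThresholdedConnectome(
        source=c,
        spec=ThresholdSpec(FIXED_DENSITY, float(target_density)),
        kept=kept,
        achieved_density=network_density(kept),
        connected_node_count=n,
        shortfall=shortfall,
    )


def apply_absolute(c: WeightedConnectome,
                   min_streamlines: float) -> ThresholdedConnectome:
    """Keep edges with ``NOS >= min_streamlines`` (weaker ones removed)."""
    if min_streamlines < 1:
        raise ThresholdError("min_streamlines must be >= 1")
    n = c.n_nodes
    i, j = np.nonzero(np.triu(c.nos, 1) >= min_streamlines)
    kept = BinaryEdgeSet(n, np.column_stack([i, j]))
    return ThresholdedConnectome(
        source=c,
        spec=ThresholdSpec(ABSOLUTE, float(min_streamlines)),
        kept=kept,
        achieved_density=network_density(kept),
        connected_node_count=int(np.count_nonzero(kept.degrees())),
    )


def apply_threshold(c: WeightedConnectome,
                    spec: ThresholdSpec) -> ThresholdedConnectome:
    if spec.method == FIXED_DENSITY:
        return apply_fixed_density(c, spec.level)
    return apply_absolute(c, spec.level)


def run_sweep(c: WeightedConnectome, method: str,
              levels: Sequence[float] | None = None
              ) -> list[ThresholdedConnectome]:
    """Apply one method across a level grid, ordered by level.

    Defaults to densities ``.02 .. .40`` (step .01) or absolute cut-offs
    ``1 .. 40``.  Fixed-density results are computed from one shared MST
    and edge ordering, so kept sets are nested across levels.
    """
    if method == FIXED_DENSITY:
        levels = DEFAULT_DENSITY_GRID if levels is None else sorted(levels)
        n = c.n_nodes
        possible = n * (n - 1) // 2
        tree, rest = _mst_order(c)
        out = []
        for lvl in levels:
            target_count = max(_round_half_away(lvl * possible), n - 1)
            n_fill = min(target_count - (n - 1), len(rest))
            kept = BinaryEdgeSet(n, np.vstack([tree, rest[:n_fill]]))
            out.append(ThresholdedConnectome(
                source=c, spec=ThresholdSpec(FIXED_DENSITY, float(lvl)),
                kept=kept, achieved_density=network_density(kept),
                connected_node_count=n, shortfall=len(kept) < target_count))
        return out
    if method == ABSOLUTE:
        levels = DEFAULT_ABSOLUTE_GRID if levels is None else sorted(levels)
        return [apply_absolute(c, lvl) for lvl in levels]
    raise ThresholdError(f"unknown method {method!r}")
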