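"""Graph metrics on (thresholded) connectomes.

Node-level: degree, normalized shortest-path betweenness centrality, and
FA- or MD-weighted node strength (mean incident edge weight).  Subject
level: global efficiency and mean node strength.

Conventions that the source description leaves open are explicit keyword
arguments here and are recorded in pipeline outputs:

* global efficiency defaults to the mean of inverse shortest-path
  distances over all ordered node pairs (disconnected pairs contribute
  zero); the literal "inverse of the average shortest path length" form
  is selectable via ``convention="inverse_mean"``;
* betweenness and default efficiency operate on the binary kept
  topology; weighted efficiency (edge length ``1 / weight``) is
  available by passing a channel matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .core import BinaryEdgeSet
from .threshold import ThresholdedConnectome

MEAN_INVERSE = "mean_inverse"      # mean over pairs of 1/d; robust default
INVERSE_MEAN = "inverse_mean"      # 1 / (mean finite d)


@dataclass(frozen=True)
class NodeMetricVector:
    """Per-node metric values plus the nodes on which it is undefined."""

    metric_name: str
    values: np.ndarray
    undefined_nodes: frozenset[int] = frozenset()


@dataclass(frozen=True)
class SubjectMetricValue:
    """One scalar per subject/session, with the node count it used."""

    metric_name: str
    value: float
    node_count_used: int


def degree(e: BinaryEdgeSet) -> NodeMetricVector:
    """Number of edges incident to each node."""
    return NodeMetricVector("degree", e.degrees().astype(float))


def betweenness_centrality(e: BinaryEdgeSet) -> NodeMetricVector:
    """Normalized unweighted shortest-path betweenness.

    Fraction of all shortest paths passing through each node, with
    fractional counting of tied shortest paths, normalized by
    ``(N - 1)(N - 2) / 2``; disconnected pairs contribute nothing.
    """
    g = nx.Graph()
    g.add_nodes_from(range(e.node_count))
    g.add_edges_from(e.pairs.tolist())
    bc = nx.betweenness_centrality(g, normalized=True)
    values = np.array([bc[i] for i in range(e.node_count)])
    return NodeMetricVector("betweenness", values)


def _pairwise_distances(e: BinaryEdgeSet,
                        lengths: np.ndarray | None) -> np.ndarray:
    adj = e.to_adjacency().astype(float)
    if lengths is not None:
        with np.errstate(divide="ignore"):
            adj = np.where(adj > 0, 1.0 / np.where(lengths > 0, lengths, np.inf),
                           0.0)
        return shortest_path(adj, method="D", directed=False)
    return shortest_path(adj, method="D", directed=False, unweighted=True)


def global_efficiency(e: BinaryEdgeSet,
                      weights: np.ndarray | None = None,
                      convention: str = MEAN_INVERSE) -> SubjectMetricValue:
    """Efficiency of information exchange from shortest-path lengths.

    Parameters
    ----------
    e : BinaryEdgeSet
        Topology to evaluate.
    weights : ndarray, optional
        Channel matrix; when given, edge length is ``1 / weight`` and
        path lengths are weighted.  Default is binary (unit lengths).
    convention : {"mean_inverse", "inverse_mean"}
        ``mean_inverse`` averages ``1 / d(i, j)`` over all ordered pairs
        with disconnected pairs contributing 0.  ``inverse_mean`` is the
        reciprocal of the mean finite distance (0 if no pair is
        connected).
    """
    n = e.node_count
    if len(e) == 0:
        return SubjectMetricValue("global_efficiency", 0.0, 0)
    d = _pairwise_distances(e, weights)
    off = ~np.eye(n, dtype=bool)
    dv = d[off]
    if convention == MEAN_INVERSE:
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(dv) & (dv > 0), 1.0 / dv, 0.0)
        value = float(inv.mean())
    elif convention == INVERSE_MEAN:
        finite = dv[np.isfinite(dv)]
        value = float(1.0 / finite.mean()) if finite.size else 0.0
    else:
        raise ValueError(f"unknown efficiency convention {convention!r}")
    return SubjectMetricValue("global_efficiency", value,
                              int(np.count_nonzero(e.degrees())))


def node_strength(tc: ThresholdedConnectome, channel: str) -> NodeMetricVector:
    """Mean FA or MD over kept edges incident to each node.

    Degree-zero nodes are undefined (recorded, never imputed as 0):
    a zero would conflate disconnection with low anisotropy.
    """
    if channel not in ("FA", "MD"):
        raise ValueError("strength channel must be FA or MD")
    mask = tc.kept.to_adjacency()
    vals = np.where(mask, tc.source.channel(channel), 0.0)
    deg = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(deg > 0, vals.sum(axis=1) / np.maximum(deg, 1), np.nan)
    undefined = frozenset(np.nonzero(deg == 0)[0].tolist())
    return NodeMetricVector(f"strength_{channel}", means, undefined)


def mean_strength(tc: ThresholdedConnectome, channel: str) -> SubjectMetricValue:
    """Mean node strength over nodes where strength is defined."""
    v = node_strength(tc, channel)
    defined = ~np.isnan(v.values)
    n_used = int(defined.sum())
    value = float(v.values[defined].mean()) if n_used else float("nan")
    return SubjectMetricValue(f"mean_strength_{channel}", value, n_used)


def subject_summary(tc: ThresholdedConnectome,
                    efficiency_convention: str = MEAN_INVERSE,
                    efficiency_channel: str | None = None
                    ) -> list[SubjectMetricValue]:
    """Global efficiency and mean FA/MD strength for one thresholded network."""
    weights = (tc.masked(efficiency_channel)
               if efficiency_channel is not None else None)
    out = [global_efficiency(tc.kept, weights=weights,
                             convention=efficiency_convention)]
    for ch in ("FA", "MD"):
        if ch in tc.source.weights:
            out.append(mean_strength(tc, ch))
    return out


#: Subject-level metric extractors used by the sensitivity analysis.
SUBJECT_METRICS = ("global_efficiency", "mean_strength_FA", "mean_strength_MD")


def subject_metric(tc: ThresholdedConnectome, metric: str,
                   efficiency_convention: str = MEAN_INVERSE,
                   efficiency_channel: str | None = None) -> float:
    """Evaluate one named subject-level metric on a thresholded network."""
    if metric == "global_efficiency":
        weights = (tc.masked(efficiency_channel)
                   if efficiency_channel is not None else None)
        return global_efficiency(tc.kept, weights=weights,
                                 convention=efficiency_convention).value
    if metric == "mean_strength_FA":
        return mean_strength(tc, "FA").value
    if metric == "mean_strength_MD":
        return mean_strength(tc, "MD").value
    raise ValueError(f"unknown subject metric {metric!r}")
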