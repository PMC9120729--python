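import numpy as np
import pytest

from connethresh.core import WeightedConnectome


def make_connectome(nos, fa=None, md=None, labels=None):
    """Build a validated connectome from an upper-triangular NOS spec.

    ``nos`` may be a full symmetric matrix or a dict {(i, j): w} plus a
    node count via ``labels``.
    """
    nos = np.asarray(nos, dtype=float)
    n = nos.shape[0]
    if labels is None:
        labels = tuple(f"r{i}" for i in range(n))
    weights = {"NOS": nos}
    if fa is not None:
        weights["FA"] = np.asarray(fa, dtype=float)
    if md is not None:
        weights["MD"] = np.asarray(md, dtype=float)
    return WeightedConnectome(tuple(labels), weights).validate()


def from_edges(n, edge_weights, fa_value=0.5, md_value=8e-4):
    """Connectome on n nodes from {(i, j): nos} with constant FA/MD."""
    nos = np.zeros((n, n))
    fa = np.zeros((n, n))
    md = np.zeros((n, n))
    for (i, j), w in edge_weights.items():
        nos[i, j] = nos[j, i] = w
        fa[i, j] = fa[j, i] = fa_value
        md[i, j] = md[j, i] = md_value
    return make_connectome(nos, fa, md)


def random_connected_connectome(rng, n, p=0.6, max_weight=50,
                                distinct=False):
    """Random connected graph with positive integer NOS weights."""
    while True:
        nos = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        mask = rng.random(len(iu)) < p
        if distinct:
            w = rng.permutation(len(iu))[mask] + 1
        else:
            w = rng.integers(1, max_weight + 1, size=int(mask.sum()))
        nos[iu[mask], ju[mask]] = w
        nos += nos.T
        # connectivity via BFS
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for u in np.nonzero(nos[v])[0]:
                if u not in seen:
                    seen.add(int(u))
                    stack.append(int(u))
        if len(seen) == n and mask.sum() >= n - 1:
            return make_connectome(nos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    """Triangle with NOS weights (0,1)=3, (1,2)=2, (0,2)=1."""
    return from_edges(3, {(0, 1): 3, (1, 2): 2, (0, 2): 1})
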