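"""Correlation-distance hierarchical clustering with bootstrap support.

Used to check that positively and negatively seed-correlated genes form
exclusive clusters: gene rows of the list under test are clustered with
average linkage on the correlation distance d(i,j) = 1 - pearson(i,j), and
cluster stability is quantified by the plain bootstrap proportion (BP) —
samples (columns) are resampled with replacement ``nboot`` times, each
resample is reclustered, and a cluster's support is the fraction of
resamples whose dendrogram contains an identical leaf set. (This is the BP
column of pvclust-style output; the multiscale-bootstrap AU probability is
deliberately not computed.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = [
    "ClusterSupport",
    "correlation_distance",
    "bootstrap_support",
    "sign_separation",
    "to_newick",
]


@dataclass
class ClusterSupport:
    leaves: tuple[str, ...]  # gene order of the linkage input
    linkage_matrix: np.ndarray
    support: dict[frozenset, float]  # observed cluster leaf set -> BP
    nboot: int


def _pairwise_corr_dist(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0.0):
        raise ValueError("constant gene row in correlation-distance input")
    corr = np.corrcoef(values)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    # numerical symmetry for squareform
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def correlation_distance(matrix: ExpressionMatrix) -> np.ndarray:
    """Pairwise 1 - Pearson distance over the matrix's rows (genes)."""
    if len(matrix.probe_ids) < 2:
        raise ValueError("need >= 2 genes for a distance matrix")
    return _pairwise_corr_dist(matrix.data.to_numpy())


def _clusters_of(linkage_matrix: np.ndarray, leaves: tuple[str, ...]) -> set[frozenset]:
    """Leaf sets of all internal (non-root, non-singleton) dendrogram nodes."""
    n = len(leaves)
    sets: dict[int, frozenset] = {i: frozenset([leaves[i]]) for i in range(n)}
    out: set[frozenset] = set()
    for i, (a, b, _, _) in enumerate(linkage_matrix):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + i] = merged
        if len(merged) < n:  # root cluster is trivially supported
            out.add(merged)
    return out


def bootstrap_support(
    matrix: ExpressionMatrix,
    genes,
    nboot: int = 1000,
    linkage: str = "average",
    rng_seed: int = 0,
) -> ClusterSupport:
    """Cluster the given gene rows and estimate BP support for each cluster."""
    if nboot < 1:
        raise ValueError("nboot must be >= 1")
    sub = matrix.subset(genes)
    if sub.n_samples < 3:
        raise ValueError("need >= 3 samples for bootstrap clustering")
    values = sub.data.to_numpy()
    leaves = tuple(sub.probe_ids)

    Z = hierarchy.linkage(squareform(_pairwise_corr_dist(values)), method=linkage)
    observed = _clusters_of(Z, leaves)
    counts = {c: 0 for c in observed}

    rng = np.random.default_rng(rng_seed)
    n_samples = values.shape[1]
    for _ in range(nboot):
        idx = rng.integers(0, n_samples, size=n_samples)
        boot = values[:, idx]
        sd = boot.std(axis=1)
        if np.any(sd == 0.0):  # degenerate resample; counts as non-support
            continue
        Zb = hierarchy.linkage(squareform(_pairwise_corr_dist(boot)), method=linkage)
        for c in _clusters_of(Zb, leaves):
            if c in counts:
                counts[c] += 1

    support = {c: k / nboot for c, k in counts.items()}
    return ClusterSupport(leaves, Z, support, nboot)


def sign_separation(
    support: ClusterSupport, rho_by_gene: dict[str, float]
) -> tuple[bool, dict]:
    """Does a 2-cut of the dendrogram reproduce the sign partition exactly?

    Returns (separated, report); a single-sign gene list separates vacuously.
    The report carries the two cut clusters, the sign partition, and the BP
    support of the cut clusters (1.0 for the vacuous case).
    """
    missing = [g for g in support.leaves if g not in rho_by_gene]
    if missing:
        raise ValueError(f"genes without a signed rho: {missing[:5]}")
    pos = frozenset(g for g in support.leaves if rho_by_gene[g] > 0)
    neg = frozenset(g for g in support.leaves if rho_by_gene[g] < 0)
    report: dict = {"positive": pos, "negative": neg}

    if not pos or not neg:
        report["cut"] = [frozenset(support.leaves)]
        report["cut_support"] = {frozenset(support.leaves): 1.0}
        return True, report

    assign = hierarchy.fcluster(support.linkage_matrix, t=2, criterion="maxclust")
    cut: dict[int, set[str]] = {}
    for leaf, a in zip(support.leaves, assign):
        cut.setdefault(int(a), set()).add(leaf)
    cut_sets = [frozenset(c) for c in cut.values()]
    report["cut"] = cut_sets
    report["cut_support"] = {
        c: support.support.get(c, 1.0 if len(c) == len(support.leaves) else 0.0)
        for c in cut_sets
    }
    separated = set(cut_sets) == {pos, neg}
    return separated, report


def to_newick(support: ClusterSupport) -> str:
    """Newick serialization of the dendrogram with BP support annotations."""
    n = len(support.leaves)
    Z = support.linkage_matrix

    def node(i: int) -> tuple[str, float, frozenset]:
        if i < n:
            leaf = support.leaves[i]
            return leaf, 0.0, frozenset([leaf])
        a, b, height, _ = Z[i - n]
        sa, ha, la = node(int(a))
        sb, hb, lb = node(int(b))
        leafset = la | lb
        bp = support.support.get(leafset, 1.0 if len(leafset) == n else 0.0)
        text = f"({sa}:{height - ha:.6g},{sb}:{height - hb:.6g}){bp:.3f}"
        return text, float(height), leafset

    text, _, _ = node(n + len(Z) - 1)
    return text + ";"
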