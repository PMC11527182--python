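"""Over-representation analysis of a gene list against a GMT library.

For a query list of n genes drawn from a background universe of N genes, a
library term covering K genes, and an observed overlap of k genes, the
enrichment p-value is the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

(equivalently the one-sided Fisher exact test on the 2x2 overlap table).
Per query and library, p-values over all terms with non-empty overlap are
Benjamini-Hochberg adjusted ("q"). This mirrors the convention of web
enrichment engines whose "adjusted p-value" column gates downstream calls.

The background universe is configurable: by default the union of the tested
library's genes; alternatively a fixed integer size (to mimic engines with a
precomputed genome-wide background) or an explicit gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import GeneSetLibrary

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_name: str
    library_name: str
    overlap_genes: frozenset[str]
    k: int
    n_list: int
    K_term: int
    N_bg: int
    p_value: float
    q_value: float
    odds_ratio: float
    #: carried for reporting when the query came from a threshold list
    list_label: str = ""
    threshold: float = float("nan")


def hypergeom_upper_tail(k: int, n_list: int, K_term: int, N_bg: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N_bg, K_term, n_list)."""
    if not (0 <= k <= min(n_list, K_term)) or n_list > N_bg or K_term > N_bg:
        raise ValueError(
            f"inconsistent counts: k={k}, n_list={n_list}, K_term={K_term}, N_bg={N_bg}"
        )
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N_bg, K_term, n_list))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if b == 0 or c == 0:
        return float("inf") if a * d > 0 else 0.0
    return (a * d) / (b * c)


def enrich(
    query,
    library: GeneSetLibrary,
    background=None,
    list_label: str = "",
    threshold: float = float("nan"),
) -> list[EnrichmentResult]:
    """Test a query gene set against every term of a library.

    ``background`` is ``None`` (universe = union of the library's genes), an
    ``int`` (fixed universe size; the query is assumed drawn from it), or an
    explicit gene set. Only terms overlapping the query (k >= 1) are tested;
    q-values are BH-adjusted across those terms. Results are sorted by
    (q, p, term name).
    """
    query = frozenset(g.upper() for g in query)
    if not query:
        raise ValueError("empty query gene set")

    if background is None:
        universe = library.all_genes
        N_bg = len(universe)
        n_list = len(query & universe)
    elif isinstance(background, int):
        universe = None
        N_bg = background
        n_list = len(query)
    else:
        universe = frozenset(g.upper() for g in background)
        N_bg = len(universe)
        n_list = len(query & universe)
    if n_list == 0:
        raise ValueError("query is disjoint from the background universe")

    tested: list[tuple[str, frozenset[str], int, float]] = []
    for term, genes in library.terms.items():
        genes_in_bg = genes & universe if universe is not None else genes
        overlap = query & genes_in_bg
        if not overlap:
            continue
        K_term = len(genes_in_bg)
        p = hypergeom_upper_tail(len(overlap), n_list, K_term, N_bg)
        tested.append((term, overlap, K_term, p))

    if not tested:
        return []
    qvals = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(
            term_name=term,
            library_name=library.library_name,
            overlap_genes=overlap,
            k=len(overlap),
            n_list=n_list,
            K_term=K_term,
            N_bg=N_bg,
            p_value=p,
            q_value=float(q),
            odds_ratio=_odds_ratio(len(overlap), n_list, K_term, N_bg),
            list_label=list_label,
            threshold=threshold,
        )
        for (term, overlap, K_term, p), q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_name))
    return results
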