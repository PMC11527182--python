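"""Disorder selection from threshold-list enrichment results.

A disorder qualifies ("meets inclusion") on a signed list when its term's
overlap with that list is significant at the adjusted threshold (q < 0.05)
and large enough: on a positively correlated list the overlap must contain
the seed gene plus at least two other list genes; on a negatively correlated
list (which cannot contain the seed) at least three list genes. Unsigned
lists are not considered at this stage — signed lists achieve the same
overlap with fewer genes and hence greater significance.

Scanning the signed ladders in ascending gene-count order, each disorder is
attached to the smallest list on which it first meets inclusion. Disorders
that cannot be uniquely discriminated — identical overlap gene set on their
smallest viable list AND identical causal gene set — are excluded, unless a
synonym merge table declares them the same disorder (e.g. hereditary and
non-hereditary forms sharing one OMIM identifier), in which case they are
merged into a single call. Finally, among all same-sign lists where the
disorder meets inclusion, the optimal list — maximal overlap count, ties
broken by smaller q, then smaller list size — is attached for the
downstream ontology stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .correlation import ThresholdList
from .enrichment import EnrichmentResult, enrich
from .io import GeneSetLibrary

__all__ = [
    "DisorderCall",
    "meets_inclusion",
    "smallest_viable",
    "discriminate",
    "select_optimal",
    "discover_disorders",
]


@dataclass
class DisorderCall:
    disorder_name: str
    causal_genes: frozenset[str]
    sign: str  # "positive" or "negative"
    smallest_viable_list: str
    smallest_result: EnrichmentResult
    optimal_list: str = ""
    optimal_result: EnrichmentResult | None = None
    #: disorder names merged into this call via the synonym table
    merged_from: tuple[str, ...] = ()
    discriminated: bool = True


def meets_inclusion(
    result: EnrichmentResult,
    list_sign: str,
    seed_gene: str,
    q_threshold: float = 0.05,
    min_overlap: int = 3,
) -> bool:
    """Inclusion rule for one (disorder term, signed list) enrichment result."""
    if list_sign == "full":
        raise ValueError("unsigned lists are not eligible for disorder inclusion")
    if list_sign not in ("positive", "negative"):
        raise ValueError(f"bad list sign {list_sign!r}")
    if not result.q_value < q_threshold:
        return False
    if len(result.overlap_genes) < min_overlap:
        return False
    if list_sign == "positive" and seed_gene.upper() not in result.overlap_genes:
        return False
    return True


def _signed_lists(lists) -> list[ThresholdList]:
    """Signed lists in ascending gene-count order (positives then negatives)."""
    signed = [l for l in lists if l.sign in ("positive", "negative")]
    return sorted(signed, key=lambda l: (l.sign != "positive", len(l), -l.threshold))


def smallest_viable(
    lists,
    disease_library: GeneSetLibrary,
    causal_map: dict[str, frozenset[str]],
    background=None,
    seed_gene: str = "SOD3",
    q_threshold: float = 0.05,
    min_overlap: int = 3,
) -> dict[str, tuple[ThresholdList, EnrichmentResult]]:
    """Map each disorder to the smallest signed list where it meets inclusion.

    Positive and negative ladders are scanned independently, each in
    ascending gene-count order; a disorder absent from the result never met
    inclusion on any list. Disorders missing from ``causal_map`` are still
    scanned (causal genes only matter for discrimination and augmentation).
    """
    out: dict[str, tuple[ThresholdList, EnrichmentResult]] = {}
    for lst in _signed_lists(lists):
        if len(lst) == 0:
            continue
        for res in enrich(
            lst.genes, disease_library, background, list_label=lst.label, threshold=lst.threshold
        ):
            if res.term_name in out:
                continue
            if meets_inclusion(res, lst.sign, seed_gene, q_threshold, min_overlap):
                out[res.term_name] = (lst, res)
    return out


def discriminate(
    calls: list[DisorderCall],
    merge_table: dict[str, str] | None = None,
) -> list[DisorderCall]:
    """Drop (or merge) disorders indistinguishable by overlap and causal genes.

    Two disorders are indistinguishable iff their smallest-viable-list
    overlap gene sets and their causal gene sets are both identical. Groups
    of size >= 2 are excluded wholesale unless the merge table maps every
    member of the group to one canonical name, in which case the group
    collapses to a single call under that name.
    """
    merge_table = merge_table or {}
    groups: dict[tuple[frozenset[str], frozenset[str]], list[DisorderCall]] = {}
    for call in calls:
        key = (call.smallest_result.overlap_genes, call.causal_genes)
        groups.setdefault(key, []).append(call)

    survivors: list[DisorderCall] = []
    for group in groups.values():
        if len(group) == 1:
            survivors.append(group[0])
            continue
        canon = {merge_table.get(c.disorder_name) for c in group}
        if len(canon) == 1 and None not in canon:
            rep = min(group, key=lambda c: c.disorder_name)
            rep.merged_from = tuple(sorted(c.disorder_name for c in group))
            rep.disorder_name = canon.pop()
            survivors.append(rep)
        # otherwise: the whole indistinguishable group is excluded
    survivors.sort(key=lambda c: c.disorder_name)
    return survivors


def select_optimal(
    call: DisorderCall,
    lists,
    disease_library: GeneSetLibrary,
    background=None,
    seed_gene: str = "SOD3",
    q_threshold: float = 0.05,
    min_overlap: int = 3,
) -> DisorderCall:
    """Attach the optimal same-sign parent list to a qualifying disorder.

    Optimality is lexicographic: overlap count descending, then q ascending,
    then list size ascending.
    """
    candidates: list[tuple[int, float, int, ThresholdList, EnrichmentResult]] = []
    term_names = {call.disorder_name, *call.merged_from}
    for lst in _signed_lists(lists):
        if lst.sign != call.sign or len(lst) == 0:
            continue
        for res in enrich(
            lst.genes, disease_library, background, list_label=lst.label, threshold=lst.threshold
        ):
            if res.term_name not in term_names:
                continue
            if meets_inclusion(res, lst.sign, seed_gene, q_threshold, min_overlap):
                candidates.append((-res.k, res.q_value, len(lst), lst, res))
    if not candidates:
        raise ValueError(f"disorder {call.disorder_name!r} meets inclusion on no list")
    _, _, _, best_list, best_res = min(candidates, key=lambda c: c[:3])
    call.optimal_list = best_list.label
    call.optimal_result = best_res
    return call


def discover_disorders(
    lists,
    disease_library: GeneSetLibrary,
    causal_map: dict[str, frozenset[str]],
    background=None,
    seed_gene: str = "SOD3",
    q_threshold: float = 0.05,
    min_overlap: int = 3,
    merge_table: dict[str, str] | None = None,
) -> list[DisorderCall]:
    """Full disorder-selection stage: smallest viable -> discriminate -> optimal."""
    viable = smallest_viable(
        lists, disease_library, causal_map, background, seed_gene, q_threshold, min_overlap
    )
    calls = [
        DisorderCall(
            disorder_name=name,
            causal_genes=causal_map.get(name, frozenset()),
            sign=lst.sign,
            smallest_viable_list=lst.label,
            smallest_result=res,
        )
        for name, (lst, res) in viable.items()
    ]
    calls = discriminate(calls, merge_table)
    return [
        select_optimal(
            c, lists, disease_library, background, seed_gene, q_threshold, min_overlap
        )
        for c in calls
    ]
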