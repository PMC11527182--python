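"""Causal-gene augmentation and the ontology co-membership novel-gene caller.

For each discriminated disorder, its optimal threshold list is augmented
with the disorder's accepted causal genes and tested for enrichment against
ontology libraries (GO-style, phenotype, pathway collections). A significant
term (q < 0.05) whose overlap with the augmented list contains at least one
causal gene AND at least one list gene that is neither causal nor part of
the disorder's disease-term overlap yields a novel-gene call: those
non-overlapping list genes are the candidates — genes co-annotated with a
causal gene and co-expressed with the seed, yet not currently linked to the
disorder.

Counting convention for the headline tallies: the per-disorder candidate
lists may repeat genes across disorders ("total"), while "unique" collapses
across disorders.
"""

from __future__ import annotations

from dataclasses import dataclass

from .correlation import ThresholdList
from .disorders import DisorderCall
from .enrichment import enrich

__all__ = ["NovelGeneCall", "augment_list", "call_novel", "summarize_novel"]


@dataclass(frozen=True)
class NovelGeneCall:
    disorder_name: str
    ontology_term: str
    library_name: str
    q_value: float
    causal_in_term: frozenset[str]
    candidates: frozenset[str]
    provenance: str  # the augmented list label


def augment_list(lst: ThresholdList, causal_genes) -> frozenset[str]:
    """Union of list genes and causal genes (already-present causal genes
    leave the size unchanged)."""
    return lst.genes | frozenset(g.upper() for g in causal_genes)


def call_novel(
    disorder: DisorderCall,
    optimal_list: ThresholdList,
    ontology_libraries,
    background=None,
    q_threshold: float = 0.05,
    co_membership: str = "causal",
) -> list[NovelGeneCall]:
    """Emit novel-gene calls for one disorder across ontology libraries.

    ``co_membership`` controls what a candidate must share a term with:
    ``"causal"`` (default) requires a causal gene in the term's overlap;
    ``"causal_or_overlap"`` relaxes this to a causal OR disease-overlap gene.
    """
    if not disorder.causal_genes:
        raise ValueError(f"disorder {disorder.disorder_name!r} has no causal genes")
    if co_membership not in ("causal", "causal_or_overlap"):
        raise ValueError(f"bad co_membership {co_membership!r}")
    if disorder.optimal_result is None:
        raise ValueError(f"disorder {disorder.disorder_name!r} has no optimal list attached")

    augmented = augment_list(optimal_list, disorder.causal_genes)
    disease_overlap = disorder.optimal_result.overlap_genes
    anchor = disorder.causal_genes
    if co_membership == "causal_or_overlap":
        anchor = anchor | disease_overlap

    calls: list[NovelGeneCall] = []
    for library in ontology_libraries:
        for res in enrich(augmented, library, background, list_label=disorder.optimal_list):
            if not res.q_value < q_threshold:
                continue
            causal_in_term = res.overlap_genes & disorder.causal_genes
            if co_membership == "causal" and not causal_in_term:
                continue
            if not (res.overlap_genes & anchor):
                continue
            candidates = (
                res.overlap_genes & optimal_list.genes
            ) - disorder.causal_genes - disease_overlap
            if not candidates:
                continue
            calls.append(
                NovelGeneCall(
                    disorder_name=disorder.disorder_name,
                    ontology_term=res.term_name,
                    library_name=library.library_name,
                    q_value=res.q_value,
                    causal_in_term=causal_in_term,
                    candidates=candidates,
                    provenance=disorder.optimal_list,
                )
            )
    calls.sort(key=lambda c: (c.q_value, c.library_name, c.ontology_term))
    return calls


def summarize_novel(calls: list[NovelGeneCall]) -> tuple[dict[str, frozenset[str]], int, int]:
    """Per-disorder deduplicated candidates plus (total, unique) tallies.

    ``total`` sums per-disorder unique candidate counts (a gene implicated in
    two disorders counts twice); ``unique`` counts distinct genes overall.
    """
    per_disorder: dict[str, set[str]] = {}
    for call in calls:
        per_disorder.setdefault(call.disorder_name, set()).update(call.candidates)
    frozen = {d: frozenset(g) for d, g in sorted(per_disorder.items())}
    total = sum(len(g) for g in frozen.values())
    unique = len(set().union(*frozen.values())) if frozen else 0
    return frozen, total, unique
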