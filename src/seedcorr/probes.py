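"""Probe -> gene symbol resolution and duplicate-probe collapse.

Surviving probes are mapped to gene symbols through the platform annotation
table, then pruned in four audited steps (the order of the exclusion-flow
table): probes with no symbol, non-specific probes, probes for non-coding
genes, and sub-optimal duplicate probes of the same gene.

Duplicate resolution prefers an externally supplied best-probe map (a
jetset-style gene -> probe choice); without one, the probe with the largest
interquartile range of expression across samples is kept (ties broken
lexicographically by probe ID). Chip-internal probe scoring is deliberately
not reimplemented here — the map input carries such choices when available.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .correlation import CorrelationRecord
from .io import ExpressionMatrix, ProbeAnnotation

__all__ = [
    "resolve_probes",
    "NO_SYMBOL_CRITERION",
    "NON_SPECIFIC_CRITERION",
    "NON_CODING_CRITERION",
    "DUPLICATE_CRITERION",
]

NO_SYMBOL_CRITERION = "No Gene Symbol for Probe ID"
NON_SPECIFIC_CRITERION = "Non-specific Probe IDs"
NON_CODING_CRITERION = "Non-coding Genes"
DUPLICATE_CRITERION = "Duplicated Genes"


def _iqr(values: np.ndarray) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def resolve_probes(
    records: list[CorrelationRecord],
    annotation: dict[str, ProbeAnnotation],
    best_probe_map: dict[str, str] | None = None,
    ledger=None,
    matrix: ExpressionMatrix | None = None,
) -> list[CorrelationRecord]:
    """Attach gene symbols and collapse to one probe per gene.

    Applies four ledger steps in exclusion-flow order; afterwards
    (gene -> probe) is a bijection over the surviving records. ``matrix`` is
    required for the IQR fallback whenever duplicates exist and no (usable)
    best-probe map entry covers them.
    """
    for r in records:
        if r.probe_id not in annotation:
            raise KeyError(f"probe {r.probe_id!r} missing from annotation")

    def step(criterion, survivors, dropped_count):
        if ledger is not None:
            ledger.append(criterion, len(survivors) + dropped_count, dropped_count)

    # 1. unmappable probes
    n0 = len(records)
    records = [
        replace(r, gene_symbol=annotation[r.probe_id].gene_symbol)
        for r in records
    ]
    survivors = [r for r in records if r.gene_symbol is not None]
    step(NO_SYMBOL_CRITERION, survivors, n0 - len(survivors))

    # 2. non-specific probes
    n0 = len(survivors)
    survivors = [r for r in survivors if annotation[r.probe_id].is_specific]
    step(NON_SPECIFIC_CRITERION, survivors, n0 - len(survivors))

    # 3. non-coding genes
    n0 = len(survivors)
    survivors = [r for r in survivors if annotation[r.probe_id].is_coding]
    step(NON_CODING_CRITERION, survivors, n0 - len(survivors))

    # 4. duplicate probes per gene
    by_gene: dict[str, list[CorrelationRecord]] = {}
    for r in survivors:
        by_gene.setdefault(r.gene_symbol, []).append(r)

    kept: list[CorrelationRecord] = []
    n_dropped = 0
    for gene, group in by_gene.items():
        if len(group) == 1:
            kept.append(group[0])
            continue
        chosen = None
        if best_probe_map and gene in best_probe_map:
            wanted = best_probe_map[gene]
            matches = [r for r in group if r.probe_id == wanted]
            if matches:
                chosen = matches[0]
            else:
                warnings.warn(
                    f"best-probe map names {wanted!r} for gene {gene}, but that probe "
                    "was excluded upstream; falling back to the IQR heuristic",
                    stacklevel=2,
                )
        if chosen is None:
            if matrix is None:
                raise ValueError(
                    f"gene {gene} has duplicate probes and no usable best-probe map "
                    "entry; an expression matrix is required for the IQR fallback"
                )
            chosen = max(
                group,
                key=lambda r: (_iqr(matrix.data.loc[r.probe_id].to_numpy()), r.probe_id),
            )
            # ties on IQR break lexicographically by probe ID via max on the tuple;
            # max picks the lexicographically largest — invert to smallest:
            best_iqr = _iqr(matrix.data.loc[chosen.probe_id].to_numpy())
            tied = [
                r for r in group
                if _iqr(matrix.data.loc[r.probe_id].to_numpy()) == best_iqr
            ]
            chosen = min(tied, key=lambda r: r.probe_id)
        kept.append(chosen)
        n_dropped += len(group) - 1
    step(DUPLICATE_CRITERION, kept, n_dropped)

    # deterministic order: by descending |rho|, then gene
    kept.sort(key=lambda r: (-abs(r.rho), r.gene_symbol))
    return kept
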