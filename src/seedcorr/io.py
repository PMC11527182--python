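"""Readers and writers for every external artifact the pipeline touches.

External formats
----------------
Expression matrix
    Tab-delimited; header row of sample IDs, first column probe IDs, one row
    per probe of log-scale normalized intensities. No missing cells.
Gene-set libraries
    GMT: ``term<TAB>description<TAB>gene1<TAB>gene2...``. One dialect serves
    both disease and ontology libraries (the format Enrichr libraries ship in).
Probe annotation
    TSV with header ``probe_id  gene_symbol  is_specific  is_coding``; an
    empty symbol field marks an unmappable probe; flags are ``0``/``1``.
Causal-gene map
    TSV with header ``disorder  causal_genes``; causal genes are
    semicolon-separated symbols.
Best-probe map
    TSV with header ``gene_symbol  probe_id``.
Reports (written by :func:`write_reports`, UTF-8 TSV, fixed column order)
    ``exclusion_ledger.tsv``: criterion, count, excluded.
    ``disorders.tsv``: disorder, list_label, rho_threshold, list_size,
    overlap_count, overlap_genes, p_value, q_value, row_type, optimal.
    ``novel_genes.tsv``: disorder, term, library, q_value, causal_in_term,
    candidates.
    ``novel_summary.tsv``: disorder, candidate_genes.

Gene symbols are uppercased at every ingestion point so that membership
tests are case-insensitive by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "GeneSetLibrary",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "read_causal_map",
    "write_causal_map",
    "read_best_probe_map",
    "read_merge_table",
    "write_reports",
]


@dataclass
class ExpressionMatrix:
    """Probes x samples table of normalized log-scale intensities.

    Invariants: unique probe and sample IDs, no missing cells, >= 3 samples.
    """

    data: pd.DataFrame  # index = probe IDs, columns = sample IDs

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        if df.shape[1] < 3:
            raise ValueError(f"need >= 3 samples, got {df.shape[1]}")
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)]
            raise ValueError(f"missing expression values in probe(s) {list(rows[:5])}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.data.index

    def subset(self, probe_ids) -> "ExpressionMatrix":
        """Row subset preserving the given order."""
        return ExpressionMatrix(self.data.loc[list(probe_ids)])


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    gene_symbol: str | None  # None == unmappable probe
    is_specific: bool
    is_coding: bool


@dataclass
class GeneSetLibrary:
    """Named collection of gene sets (disease or ontology library)."""

    library_name: str
    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"empty gene set for term {term!r}")
            bad = [g for g in genes if g != g.upper()]
            if bad:
                raise ValueError(f"non-uppercase symbols in term {term!r}: {bad[:3]}")

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (samples in header row)."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        ncol = len(sample_ids)
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol + 1:
                raise ValueError(
                    f"ragged row at line {lineno}: expected {ncol + 1} fields, got {len(fields)}"
                )
            probe = fields[0]
            if probe in seen:
                raise ValueError(f"duplicate probe ID {probe!r} at line {lineno}")
            seen.add(probe)
            vals = []
            for j, cell in enumerate(fields[1:]):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell at line {lineno}, column {sample_ids[j]!r}: {cell!r}"
                    ) from None
            probe_ids.append(probe)
            rows.append(vals)
    df = pd.DataFrame(rows, index=probe_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_gmt(path, library_name: str | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set library (term, description, then gene symbols)."""
    name = library_name or os.path.splitext(os.path.basename(str(path)))[0]
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            # drop blank trailing fields (Enrichr GMTs pad with empty columns)
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            term, desc = fields[0], fields[1]
            if term in terms:
                raise ValueError(f"GMT line {lineno}: duplicate term {term!r}")
            terms[term] = frozenset(g.upper() for g in fields[2:] if g)
            descriptions[term] = desc
    return GeneSetLibrary(name, terms, descriptions)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for term, genes in library.terms.items():
            desc = library.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_annotation(path) -> dict[str, ProbeAnnotation]:
    """Read the probe annotation table, keyed by probe ID."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "gene_symbol", "is_specific", "is_coding"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing column(s): {sorted(missing)}")
    out: dict[str, ProbeAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.probe_id in out:
            raise ValueError(f"duplicate probe row {row.probe_id!r}")
        symbol = row.gene_symbol.upper() or None
        out[row.probe_id] = ProbeAnnotation(
            probe_id=row.probe_id,
            gene_symbol=symbol,
            is_specific=row.is_specific.strip() in ("1", "true", "True"),
            is_coding=row.is_coding.strip() in ("1", "true", "True"),
        )
    return out


def write_annotation(annotation: dict[str, ProbeAnnotation], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("probe_id\tgene_symbol\tis_specific\tis_coding\n")
        for ann in annotation.values():
            fh.write(
                f"{ann.probe_id}\t{ann.gene_symbol or ''}\t"
                f"{int(ann.is_specific)}\t{int(ann.is_coding)}\n"
            )


def read_causal_map(path) -> dict[str, frozenset[str]]:
    """Read the disorder -> causal genes map (semicolon-separated symbols)."""
    out: dict[str, frozenset[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()  # "disorder\tcausal_genes"
        if not header.lower().startswith("disorder"):
            raise ValueError("causal map must start with a 'disorder' header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"causal map line {lineno}: expected 2 fields")
            disorder, genes_field = fields
            if disorder in out:
                raise ValueError(f"causal map line {lineno}: duplicate disorder {disorder!r}")
            genes = frozenset(g.strip().upper() for g in genes_field.split(";") if g.strip())
            if not genes:
                raise ValueError(f"causal map line {lineno}: empty causal set for {disorder!r}")
            out[disorder] = genes
    return out


def write_causal_map(causal_map: dict[str, frozenset[str]], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("disorder\tcausal_genes\n")
        for disorder, genes in causal_map.items():
            fh.write(f"{disorder}\t{';'.join(sorted(genes))}\n")


def read_best_probe_map(path) -> dict[str, str]:
    """Two-column gene -> preferred probe table (jetset-style choices)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene_symbol", "probe_id"} <= set(df.columns):
        raise ValueError("best-probe map needs columns gene_symbol, probe_id")
    out: dict[str, str] = {}
    for row in df.itertuples(index=False):
        sym = row.gene_symbol.upper()
        if sym in out:
            raise ValueError(f"duplicate gene {sym!r} in best-probe map")
        out[sym] = row.probe_id
    return out


def read_merge_table(path) -> dict[str, str]:
    """Disorder synonym table: disorder -> canonical name."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"disorder", "canonical"} <= set(df.columns):
        raise ValueError("merge table needs columns disorder, canonical")
    return dict(zip(df["disorder"], df["canonical"]))


def write_reports(results, out_dir) -> dict[str, str]:
    """Write the pipeline's TSV reports; returns {report name: path}.

    ``results`` is a :class:`seedcorr.pipeline.PipelineResult` (duck-typed:
    only the attributes present are written, so partial runs report what they
    have). Files with no data rows still carry their header.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}

    ledger = getattr(results, "ledger", None)
    if ledger is not None:
        path = os.path.join(out_dir, "exclusion_ledger.tsv")
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("criterion\tcount\texcluded\n")
            for step in ledger.steps:
                fh.write(f"{step.criterion}\t{step.count_before}\t{step.count_excluded}\n")
        written["exclusion_ledger"] = path

    lists = getattr(results, "lists", None)
    if lists is not None:
        path = os.path.join(out_dir, "gene_lists.tsv")
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("list_label\trho_threshold\tsign\tn_genes\tgene\trho\n")
            for lst in lists:
                for gene, rho in lst.members:
                    fh.write(
                        f"{lst.label}\t{lst.threshold:.2f}\t{lst.sign}\t"
                        f"{len(lst.members)}\t{gene}\t{rho:.10f}\n"
                    )
        written["gene_lists"] = path

    calls = getattr(results, "disorder_calls", None)
    if calls is not None:
        path = os.path.join(out_dir, "disorders.tsv")
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(
                "disorder\tlist_label\trho_threshold\tlist_size\toverlap_count\t"
                "overlap_genes\tp_value\tq_value\trow_type\toptimal\n"
            )
            for call in calls:
                rows = [("smallest_viable", call.smallest_viable_list, call.smallest_result)]
                if call.optimal_list != call.smallest_viable_list:
                    rows.append(("optimal", call.optimal_list, call.optimal_result))
                for row_type, label, res in rows:
                    is_opt = int(label == call.optimal_list)
                    fh.write(
                        f"{call.disorder_name}\t{label}\t{res.threshold:.2f}\t"
                        f"{res.n_list}\t{res.k}\t{';'.join(sorted(res.overlap_genes))}\t"
                        f"{res.p_value:.6g}\t{res.q_value:.6g}\t{row_type}\t{is_opt}\n"
                    )
        written["disorders"] = path

    novel = getattr(results, "novel_calls", None)
    if novel is not None:
        path = os.path.join(out_dir, "novel_genes.tsv")
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("disorder\tterm\tlibrary\tq_value\tcausal_in_term\tcandidates\n")
            for call in novel:
                fh.write(
                    f"{call.disorder_name}\t{call.ontology_term}\t{call.library_name}\t"
                    f"{call.q_value:.6g}\t{';'.join(sorted(call.causal_in_term))}\t"
                    f"{';'.join(sorted(call.candidates))}\n"
                )
        written["novel_genes"] = path

        summary = getattr(results, "novel_summary", None)
        if summary is not None:
            path = os.path.join(out_dir, "novel_summary.tsv")
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write("disorder\tcandidate_genes\n")
                for disorder, genes in summary.items():
                    fh.write(f"{disorder}\t{';'.join(sorted(genes))}\n")
            written["novel_summary"] = path

    return written
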