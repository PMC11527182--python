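"""End-to-end orchestration of the seed-correlation screen.

Stage order mirrors the analysis workflow: normality QC -> seed correlation
-> significance filter -> |rho| threshold -> probe resolution -> threshold
ladder -> disease enrichment -> disorder discovery -> causal-gene
augmentation / novel-gene calling -> bootstrap robustness. Each run records
an exclusion ledger, a manifest (config snapshot, input digests, stage
timings, output paths, seeds) and the TSV reports of ``io.write_reports``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as sio
from .correlation import (
    PipelineConfig,
    ThresholdList,
    bonferroni_threshold,
    build_ladder,
    filter_rho_threshold,
    filter_significant,
    pearson_vs_seed,
)
from .disorders import DisorderCall, discover_disorders
from .enrichment import EnrichmentResult, enrich
from .novel import NovelGeneCall, call_novel, summarize_novel
from .qc import ExclusionLedger, filter_normality
from .probes import resolve_probes
from .robustness import ClusterSupport, bootstrap_support, sign_separation, to_newick

logger = logging.getLogger("seedcorr")

STAGES = ("qc", "correlate", "lists", "enrich", "discover", "novel", "robustness")

__all__ = ["PipelineResult", "RunManifest", "run_pipeline", "run_from_files",
           "load_config", "dump_config", "parse_background", "STAGES"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    alpha_cor: float = float("nan")
    ledger: ExclusionLedger | None = None
    normality_records: list = field(default_factory=list)
    correlation_records: list = field(default_factory=list)
    resolved_records: list = field(default_factory=list)
    lists: list[ThresholdList] | None = None
    enrichment_results: list[EnrichmentResult] | None = None
    disorder_calls: list[DisorderCall] | None = None
    novel_calls: list[NovelGeneCall] | None = None
    novel_summary: dict[str, frozenset[str]] | None = None
    novel_total: int = 0
    novel_unique: int = 0
    cluster_support: ClusterSupport | None = None
    sign_separated: bool | None = None
    sign_report: dict | None = None


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    stage_seconds: dict[str, float]
    output_paths: dict[str, str]
    rng_seed: int
    ledger: list[tuple[str, int, int]]

    def write(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def run_pipeline(
    matrix: sio.ExpressionMatrix,
    annotation: dict[str, sio.ProbeAnnotation],
    disease_library: sio.GeneSetLibrary,
    ontology_libraries,
    causal_map: dict[str, frozenset[str]],
    config: PipelineConfig | None = None,
    best_probe_map: dict[str, str] | None = None,
    merge_table: dict[str, str] | None = None,
    rng_seed: int = 0,
    until: str = "robustness",
    stage_seconds: dict[str, float] | None = None,
) -> PipelineResult:
    """Run the screen from in-memory inputs up to (and including) ``until``."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    config = config or PipelineConfig()
    cutoff = STAGES.index(until)
    result = PipelineResult(config=config)
    timings = stage_seconds if stage_seconds is not None else {}

    def stage(name):
        return _StageTimer(name, timings)

    seed_probe = config.seed_probe_id
    if seed_probe not in matrix:
        raise ValueError(f"seed probe {seed_probe!r} not present in the expression matrix")

    # --- QC -------------------------------------------------------------
    with stage("qc"):
        ledger = ExclusionLedger(initial_count=len(matrix.probe_ids) - 1)
        result.ledger = ledger
        qc_matrix, result.normality_records = filter_normality(
            matrix, config.alpha_norm, ledger, exempt={seed_probe}
        )
        logger.info("qc: %d probes retained of %d", ledger.current_count,
                    ledger.initial_count)
    if cutoff < 1:
        return result

    # --- seed correlation + filters ------------------------------------
    with stage("correlate"):
        records = pearson_vs_seed(qc_matrix, seed_probe)
        divisor = config.bonferroni_divisor or matrix.n_samples
        result.alpha_cor = bonferroni_threshold(config.alpha, divisor)
        records = filter_significant(records, result.alpha_cor, ledger)
        records = filter_rho_threshold(records, config.tau_min, ledger)
        result.correlation_records = records
        logger.info("correlate: %d probes significant at alpha_cor=%.3g, |rho|>=%g",
                    len(records), result.alpha_cor, config.tau_min)
    if cutoff < 2:
        return result

    # --- probe resolution + ladder -------------------------------------
    with stage("lists"):
        resolved = resolve_probes(records, annotation, best_probe_map, ledger, qc_matrix)
        result.resolved_records = resolved
        result.lists = build_ladder(resolved, config)
        logger.info("lists: %d genes -> %d lists", len(resolved) + 1, len(result.lists))
    if cutoff < 3:
        return result

    # --- per-list disease enrichment ------------------------------------
    with stage("enrich"):
        enr: list[EnrichmentResult] = []
        for lst in result.lists:
            if lst.sign == "full" or len(lst) == 0:
                continue
            enr.extend(
                enrich(lst.genes, disease_library, config.background,
                       list_label=lst.label, threshold=lst.threshold)
            )
        result.enrichment_results = enr
    if cutoff < 4:
        return result

    # --- disorder discovery ---------------------------------------------
    with stage("discover"):
        result.disorder_calls = discover_disorders(
            result.lists,
            disease_library,
            causal_map,
            background=config.background,
            seed_gene=config.seed_gene_symbol,
            q_threshold=config.q_threshold,
            min_overlap=config.min_overlap,
            merge_table=merge_table,
        )
        logger.info("discover: %d uniquely discriminated disorder(s)",
                    len(result.disorder_calls))
    if cutoff < 5:
        return result

    # --- novel-gene calling ---------------------------------------------
    with stage("novel"):
        by_label = {l.label: l for l in result.lists}
        novel_calls: list[NovelGeneCall] = []
        for call in result.disorder_calls:
            if not call.causal_genes:
                logger.warning("novel: %s has no causal genes; skipped", call.disorder_name)
                continue
            novel_calls.extend(
                call_novel(call, by_label[call.optimal_list], ontology_libraries,
                           background=config.background, q_threshold=config.q_threshold)
            )
        result.novel_calls = novel_calls
        result.novel_summary, result.novel_total, result.novel_unique = (
            summarize_novel(novel_calls)
        )
        logger.info("novel: %d candidate gene(s) (%d unique) across %d disorder(s)",
                    result.novel_total, result.novel_unique,
                    len(result.novel_summary))
    if cutoff < 6:
        return result

    # --- bootstrap robustness --------------------------------------------
    with stage("robustness"):
        full = [l for l in result.lists if l.sign == "full"]
        widest = max(full, key=len)
        gene_matrix = _gene_level_matrix(qc_matrix, result.resolved_records,
                                         config, widest.genes)
        result.cluster_support = bootstrap_support(
            gene_matrix, gene_matrix.probe_ids, nboot=config.nboot,
            linkage=config.linkage, rng_seed=rng_seed,
        )
        rho_by_gene = {g: r for g, r in widest.members}
        result.sign_separated, result.sign_report = sign_separation(
            result.cluster_support, rho_by_gene
        )
        logger.info("robustness: sign separation = %s", result.sign_separated)
    return result


def _gene_level_matrix(matrix, resolved_records, config, genes) -> sio.ExpressionMatrix:
    """Gene-symbol-indexed expression rows for the resolved probes (plus seed)."""
    rows = {config.seed_gene_symbol: matrix.data.loc[config.seed_probe_id]}
    for rec in resolved_records:
        if rec.gene_symbol in genes:
            rows[rec.gene_symbol] = matrix.data.loc[rec.probe_id]
    df = pd.DataFrame({g: rows[g] for g in sorted(rows)}).T
    return sio.ExpressionMatrix(df)


class _StageTimer:
    def __init__(self, name: str, timings: dict[str, float]):
        self.name, self.timings = name, timings

    def __enter__(self):
        self.t0 = time.perf_counter()

    def __exit__(self, exc_type, exc, tb):
        self.timings[self.name] = round(time.perf_counter() - self.t0, 4)
        if exc_type is not None:
            logger.error("stage %r failed: %s", self.name, exc)
        return False


def parse_background(spec: str | None):
    """Parse a CLI background policy: library-union | fixed:<int> | file:<path>."""
    if spec is None or spec == "library-union":
        return None
    if spec.startswith("fixed:"):
        return int(spec.split(":", 1)[1])
    if spec.startswith("file:"):
        path = spec.split(":", 1)[1]
        with open(path, "rt", encoding="utf-8") as fh:
            return frozenset(line.strip().upper() for line in fh if line.strip())
    raise ValueError(f"bad background spec {spec!r}")


def load_config(path) -> PipelineConfig:
    with open(path, "rt", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path) -> None:
    data = dataclasses.asdict(config)
    if isinstance(data.get("background"), frozenset):
        data["background"] = sorted(data["background"])
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_from_files(
    expression: str,
    annotation: str,
    disease_gmt: str,
    ontology_gmts: list[str],
    causal_map_path: str,
    out_dir: str,
    config: PipelineConfig | None = None,
    best_probe_map_path: str | None = None,
    merge_table_path: str | None = None,
    rng_seed: int = 0,
    until: str = "robustness",
) -> tuple[PipelineResult, RunManifest]:
    """File-based entry point: read inputs, run, write reports and manifest."""
    config = config or PipelineConfig()
    inputs = {
        "expression": expression,
        "annotation": annotation,
        "disease_gmt": disease_gmt,
        "causal_map": causal_map_path,
    }
    for i, p in enumerate(ontology_gmts):
        inputs[f"ontology_gmt_{i}"] = p
    if best_probe_map_path:
        inputs["best_probe_map"] = best_probe_map_path
    if merge_table_path:
        inputs["merge_table"] = merge_table_path

    matrix = sio.read_expression(expression)
    ann = sio.read_annotation(annotation)
    disease = sio.read_gmt(disease_gmt)
    ontologies = [sio.read_gmt(p) for p in ontology_gmts]
    causal = sio.read_causal_map(causal_map_path)
    bpm = sio.read_best_probe_map(best_probe_map_path) if best_probe_map_path else None
    merge = sio.read_merge_table(merge_table_path) if merge_table_path else None

    timings: dict[str, float] = {}
    result = run_pipeline(
        matrix, ann, disease, ontologies, causal,
        config=config, best_probe_map=bpm, merge_table=merge,
        rng_seed=rng_seed, until=until, stage_seconds=timings,
    )

    os.makedirs(out_dir, exist_ok=True)
    outputs = sio.write_reports(result, out_dir)
    if result.cluster_support is not None:
        newick_path = os.path.join(out_dir, "dendrogram.nwk")
        with open(newick_path, "wt", encoding="utf-8") as fh:
            fh.write(to_newick(result.cluster_support) + "\n")
        outputs["dendrogram"] = newick_path

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_digests={k: _digest(v) for k, v in inputs.items()},
        stage_seconds=timings,
        output_paths=outputs,
        rng_seed=rng_seed,
        ledger=[(s.criterion, s.count_before, s.count_excluded)
                for s in result.ledger.steps] if result.ledger else [],
    )
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return result, manifest
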