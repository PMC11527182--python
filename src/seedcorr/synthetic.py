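"""Synthetic expression matrices and gene-set libraries with known ground truth.

The generator emulates the structure of a large one-channel microarray
compendium screened against a single seed gene: a seed probe with i.i.d.
normal log-intensities; genes planted at chosen population correlations with
the seed (both signs) via the linear-mixture construction

    x = rho * z_seed + sqrt(1 - rho^2) * eps,   eps ~ N(0, 1) i.i.d.,

rescaled into a positive log-intensity range (so the population correlation
equals rho exactly, while the sample correlation carries the estimation
noise of a real study, sd ~ (1 - rho^2)/sqrt(n)); independent background
genes; contaminant probes from an exponentiated-normal (log-normal)
distribution that fail normality screening; duplicate probes per gene as
attenuated noisy copies with distinct dispersions; and annotation rows for
unmappable, non-specific and non-coding probes planted at screenable
correlations so every exclusion step of the ledger is exercised.

Disease and ontology libraries are generated against the same truth: each
planted disorder's disease term contains its causal genes, the seed gene and
planted correlated member genes (plus background padding); decoy terms
contain only background genes. Ontology terms co-annotate causal genes with
planted "novel" genes — list genes deliberately left out of the disorder's
disease term — so the downstream caller has an exactly recoverable answer.

Default parameters are the study conditions of the motivating screen:
n_samples = 2158, an 8-step |rho| ladder spanned by 20 planted genes,
3 planted disorders with causal and novel genes, 20 decoy disease terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, GeneSetLibrary, ProbeAnnotation

__all__ = [
    "PlantedDisorder",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_disease_library",
    "generate_ontology_library",
]


@dataclass(frozen=True)
class PlantedDisorder:
    """Ground-truth disorder: members come from the planted correlated genes;
    novel genes are planted genes deliberately excluded from the disease term."""

    name: str
    members: tuple[str, ...]
    causal_genes: tuple[str, ...]
    novel_genes: tuple[str, ...]


_DEFAULT_PLANTED: tuple[tuple[str, float], ...] = (
    ("PCG01", 0.62), ("PCG02", 0.59), ("PCG03", 0.56), ("PCG04", 0.53),
    ("PCG05", 0.51), ("PCG06", 0.49), ("PCG07", 0.48), ("PCG08", 0.44),
    ("PCG09", 0.42), ("PCG10", 0.39), ("PCG11", 0.37), ("PCG12", 0.35),
    ("NCG01", -0.60), ("NCG02", -0.56), ("NCG03", -0.52), ("NCG04", -0.50),
    ("NCG05", -0.48), ("NCG06", -0.42), ("NCG07", -0.38), ("NCG08", -0.35),
)

_DEFAULT_DISORDERS: tuple[PlantedDisorder, ...] = (
    PlantedDisorder(
        name="Planted Arteriopathy Syndrome",
        members=("PCG01", "PCG02", "PCG03"),
        causal_genes=("CGA1",),
        novel_genes=("PCG04", "PCG05"),
    ),
    PlantedDisorder(
        name="Planted Myopathy Disorder",
        members=("PCG04", "PCG05", "PCG06"),
        causal_genes=("CGB1", "CGB2"),
        novel_genes=("PCG01", "PCG07"),
    ),
    PlantedDisorder(
        name="Planted Neoplastic Disorder",
        members=("NCG01", "NCG02", "NCG03"),
        causal_genes=("CGC1",),
        novel_genes=("NCG04", "NCG05"),
    ),
)


@dataclass
class SyntheticConfig:
    n_samples: int = 2158
    seed_mean: float = 7.0
    seed_sd: float = 1.0
    planted: tuple[tuple[str, float], ...] = _DEFAULT_PLANTED
    n_background: int = 300
    n_nonnormal: int = 10
    n_duplicates: int = 3
    n_unmappable: int = 2
    n_nonspecific: int = 3
    n_noncoding: int = 2
    planted_disorders: tuple[PlantedDisorder, ...] = _DEFAULT_DISORDERS
    n_decoy_terms: int = 20
    n_decoy_ontology_terms: int = 15
    seed_probe_id: str = "205236_x_at"
    seed_gene_symbol: str = "SOD3"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError(f"n_samples must be >= 10, got {self.n_samples}")
        if self.seed_sd <= 0:
            raise ValueError("seed_sd must be > 0")
        symbols = [g for g, _ in self.planted]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate planted gene symbols")
        for gene, rho in self.planted:
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"planted rho for {gene} must be in (-1, 1), got {rho}")
        for name in (
            "n_background", "n_nonnormal", "n_duplicates",
            "n_unmappable", "n_nonspecific", "n_noncoding",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_duplicates > len(self.planted):
            raise ValueError("n_duplicates exceeds the number of planted genes")
        planted_set = set(symbols)
        for dis in self.planted_disorders:
            missing = (set(dis.members) | set(dis.novel_genes)) - planted_set
            if missing:
                raise ValueError(
                    f"disorder {dis.name!r} references unplanted genes {sorted(missing)}"
                )
            if set(dis.novel_genes) & set(dis.members):
                raise ValueError(f"disorder {dis.name!r}: novel genes overlap members")
            signs = {np.sign(dict(self.planted)[g]) for g in dis.members}
            if len(signs) > 1:
                raise ValueError(f"disorder {dis.name!r}: members mix correlation signs")


@dataclass
class SyntheticTruth:
    seed_probe_id: str
    seed_gene_symbol: str
    planted_rho: dict[str, float]
    contaminant_probes: frozenset[str]
    duplicate_groups: dict[str, frozenset[str]]
    #: disorder -> (member genes, causal genes, expected overlap with a list)
    planted_disorders: dict[str, tuple[frozenset[str], frozenset[str], frozenset[str]]]
    planted_novel: dict[str, frozenset[str]]
    background_genes: tuple[str, ...]
    probe_of_gene: dict[str, str] = field(default_factory=dict)


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, dict[str, ProbeAnnotation], SyntheticTruth]:
    """Emit the expression matrix, its probe annotation, and the ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    probe_ids: list[str] = []
    rows: list[np.ndarray] = []
    ann: dict[str, ProbeAnnotation] = {}

    def emit(probe: str, values: np.ndarray, symbol: str | None,
             specific: bool = True, coding: bool = True) -> None:
        probe_ids.append(probe)
        rows.append(values)
        ann[probe] = ProbeAnnotation(probe, symbol, specific, coding)

    # seed probe: i.i.d. normal log-intensity
    seed_raw = rng.normal(config.seed_mean, config.seed_sd, size=n)
    z_seed = (seed_raw - seed_raw.mean()) / seed_raw.std()
    emit(config.seed_probe_id, seed_raw, config.seed_gene_symbol)

    # Signal rows are rank-inverse-normal transformed (normal scores): the
    # mixture construction fixes the population correlation, and replacing
    # the row by its normal scores afterwards preserves the rank-borne
    # estimation noise of that correlation while making the row's sample
    # moments exact, so signal rows conform to normality by construction —
    # emulating the real screen, where retained probes pass the JB gate
    # near-wholesale.
    scores = sps.norm.ppf(np.arange(1, n + 1) / (n + 1.0))
    scores = (scores - scores.mean()) / scores.std()

    def normal_scores(x: np.ndarray) -> np.ndarray:
        return scores[np.argsort(np.argsort(x))]

    def planted_row(rho: float) -> np.ndarray:
        """Standardized latent signal with population correlation rho to the seed."""
        eps = rng.standard_normal(n)
        return normal_scores(rho * z_seed + np.sqrt(1.0 - rho * rho) * eps)

    def to_intensity(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
        return mean + sd * x

    # planted correlated genes (+ duplicates for the first n_duplicates)
    planted_rho: dict[str, float] = {}
    duplicate_groups: dict[str, frozenset[str]] = {}
    probe_of_gene: dict[str, str] = {config.seed_gene_symbol: config.seed_probe_id}
    for i, (gene, rho) in enumerate(config.planted):
        signal = planted_row(rho)
        mean = float(rng.uniform(5.0, 9.0))
        sd = float(rng.uniform(0.7, 1.3))
        probe = f"{1000 + i:05d}_at"
        emit(probe, to_intensity(signal, mean, sd), gene)
        planted_rho[gene] = rho
        probe_of_gene[gene] = probe
        if i < config.n_duplicates:
            # attenuated noisy copy with a smaller dispersion, so the IQR
            # fallback keeps the primary probe
            lam = 0.4
            dup_signal = normal_scores(
                (signal + lam * rng.standard_normal(n)) / np.sqrt(1 + lam * lam)
            )
            dup_probe = f"{1000 + i:05d}_s_at"
            emit(dup_probe, to_intensity(dup_signal, mean, sd * 0.6), gene)
            duplicate_groups[gene] = frozenset([probe, dup_probe])

    # probes exercising the annotation exclusions, planted at screenable rho
    junk_rhos = [0.50, -0.50, 0.45, -0.45, 0.55, -0.55, 0.48]
    j = 0
    for i in range(config.n_unmappable):
        emit(f"9{j:04d}_at", to_intensity(planted_row(junk_rhos[j % len(junk_rhos)]),
                                          7.0, 1.0), None)
        j += 1
    for i in range(config.n_nonspecific):
        emit(f"9{j:04d}_x_at", to_intensity(planted_row(junk_rhos[j % len(junk_rhos)]),
                                            7.0, 1.0), f"NSG{i + 1}", specific=False)
        j += 1
    for i in range(config.n_noncoding):
        emit(f"9{j:04d}_at", to_intensity(planted_row(junk_rhos[j % len(junk_rhos)]),
                                          7.0, 1.0), f"LINC{i + 1:02d}", coding=False)
        j += 1

    # independent background genes
    background_genes = tuple(f"BG{i + 1:04d}" for i in range(config.n_background))
    for i, gene in enumerate(background_genes):
        mean = float(rng.uniform(5.0, 9.0))
        sd = float(rng.uniform(0.5, 1.5))
        probe = f"{20000 + i:05d}_at"
        emit(probe, rng.normal(mean, sd, size=n), gene)
        probe_of_gene[gene] = probe

    # non-normal contaminants: exponentiated normal (strongly right-skewed)
    contaminants = []
    for i in range(config.n_nonnormal):
        probe = f"{40000 + i:05d}_at"
        emit(probe, 4.0 + np.exp(rng.normal(1.0, 0.5, size=n)), f"CONT{i + 1:02d}")
        contaminants.append(probe)

    matrix = ExpressionMatrix(
        pd.DataFrame(np.vstack(rows), index=probe_ids, columns=sample_ids)
    )

    disorders: dict[str, tuple[frozenset[str], frozenset[str], frozenset[str]]] = {}
    novel: dict[str, frozenset[str]] = {}
    for dis in config.planted_disorders:
        members = frozenset(dis.members)
        causal = frozenset(dis.causal_genes)
        positive = all(planted_rho[g] > 0 for g in dis.members)
        expected = members | {config.seed_gene_symbol} if positive else members
        disorders[dis.name] = (members, causal, expected)
        novel[dis.name] = frozenset(dis.novel_genes)

    truth = SyntheticTruth(
        seed_probe_id=config.seed_probe_id,
        seed_gene_symbol=config.seed_gene_symbol,
        planted_rho=planted_rho,
        contaminant_probes=frozenset(contaminants),
        duplicate_groups=duplicate_groups,
        planted_disorders=disorders,
        planted_novel=novel,
        background_genes=background_genes,
        probe_of_gene=probe_of_gene,
    )
    return matrix, ann, truth


def generate_disease_library(
    truth: SyntheticTruth,
    decoys: int = 20,
    rng_seed: int = 0,
) -> tuple[GeneSetLibrary, dict[str, frozenset[str]]]:
    """Disease library with planted disorder terms plus background-only decoys."""
    if not truth.planted_disorders:
        raise ValueError("truth has no planted disorders")
    if decoys > len(truth.background_genes):
        raise ValueError(
            f"{decoys} decoy terms requested but only "
            f"{len(truth.background_genes)} background genes available"
        )
    rng = np.random.default_rng(rng_seed)
    terms: dict[str, frozenset[str]] = {}
    causal_map: dict[str, frozenset[str]] = {}
    for name, (members, causal, expected) in truth.planted_disorders.items():
        pad = rng.choice(truth.background_genes, size=min(5, len(truth.background_genes)),
                         replace=False)
        term = members | causal | set(pad)
        if truth.seed_gene_symbol in expected:
            term |= {truth.seed_gene_symbol}
        terms[name] = frozenset(term)
        causal_map[name] = causal
    for i in range(decoys):
        size = int(rng.integers(8, 16))
        genes = rng.choice(truth.background_genes, size=size, replace=False)
        terms[f"Decoy Disorder {i + 1:02d}"] = frozenset(genes)
    lib = GeneSetLibrary("synthetic_disease", terms,
                         {t: "synthetic" for t in terms})
    return lib, causal_map


def generate_ontology_library(
    truth: SyntheticTruth,
    rng_seed: int = 0,
    decoys: int = 15,
) -> GeneSetLibrary:
    """Ontology library whose planted terms co-annotate causal and novel genes."""
    rng = np.random.default_rng(rng_seed)
    terms: dict[str, frozenset[str]] = {}
    for name, novel_genes in truth.planted_novel.items():
        if not novel_genes:
            continue
        members, causal, _ = truth.planted_disorders[name]
        bad = novel_genes - set(truth.planted_rho)
        if bad:
            raise ValueError(f"novel genes not among planted genes: {sorted(bad)}")
        pad = rng.choice(truth.background_genes, size=min(3, len(truth.background_genes)),
                         replace=False)
        terms[f"{name} mechanism"] = frozenset(causal | novel_genes | set(pad))
    for i in range(decoys):
        size = int(rng.integers(8, 16))
        genes = rng.choice(truth.background_genes, size=size, replace=False)
        terms[f"Decoy Process {i + 1:02d}"] = frozenset(genes)
    return GeneSetLibrary("synthetic_ontology", terms, {t: "synthetic" for t in terms})
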