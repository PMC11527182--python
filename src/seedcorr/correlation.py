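"""Pearson correlation of every probe against a designated seed probe, the
two-tail t significance filter at a Bonferroni-adjusted alpha, and the nested
signed threshold-list ladder.

The screen centres on one seed gene (SOD3 in the motivating study): every
other probe's expression is correlated against the seed probe across all
samples, significance of each correlation is assessed with

    t = rho * sqrt((n - 2) / (1 - rho^2)),   p = two-tail P(|T_{n-2}| >= |t|),

and correlations surviving the Bonferroni-adjusted cutoff are binned into a
ladder of nested gene lists at |rho| thresholds tau_min..tau_max (default
0.34..0.41 in 0.01 steps). Each full list is split into a positively and a
negatively correlated sub-list ("X+"/"X-"); the seed gene itself (rho = 1 by
definition) is a member of every full and positive list.

Lists are numbered in ascending order of gene count, so "list 1" is the
strictest (highest threshold) list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import ExpressionMatrix

__all__ = [
    "CorrelationRecord",
    "ThresholdList",
    "PipelineConfig",
    "pearson_vs_seed",
    "correlation_pvalue",
    "bonferroni_threshold",
    "filter_significant",
    "filter_rho_threshold",
    "build_ladder",
    "split_signed",
    "SIGNIFICANCE_CRITERION",
    "RHO_CRITERION",
]

SIGNIFICANCE_CRITERION = "Failed Pearson Correlation two-tail t-test"
RHO_CRITERION = "Failed Pearson rho threshold"

#: |rho| comparisons are made on values rounded to this many decimals to
#: avoid float boundary flapping at the ladder thresholds.
RHO_DECIMALS = 10


@dataclass(frozen=True)
class CorrelationRecord:
    probe_id: str
    rho: float
    t_statistic: float
    p_value: float
    n: int
    gene_symbol: str | None = None  # filled in by probe resolution


@dataclass(frozen=True)
class ThresholdList:
    """A named gene list at a |rho| threshold and sign.

    ``members`` is ordered by descending |rho| then symbol; sign is one of
    ``"full"``, ``"positive"``, ``"negative"``.
    """

    label: str
    threshold: float
    sign: str
    members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.sign not in ("full", "positive", "negative"):
            raise ValueError(f"bad sign {self.sign!r}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PipelineConfig:
    """Tunable constants of the screen, with the study's values as defaults."""

    alpha: float = 0.05
    #: Bonferroni divisor for alpha_cor; None -> the sample count n
    #: (0.05 / 2158 = 2.3e-5 in the motivating study).
    bonferroni_divisor: int | None = None
    alpha_norm: float = 0.05
    tau_min: float = 0.34
    tau_max: float = 0.41
    tau_step: float = 0.01
    seed_probe_id: str = "205236_x_at"
    seed_gene_symbol: str = "SOD3"
    q_threshold: float = 0.05
    min_overlap: int = 3
    nboot: int = 1000
    linkage: str = "average"
    #: background policy for enrichment: None = union of the tested library's
    #: genes; an int = fixed universe size; a set = explicit universe.
    background: object = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.tau_min > self.tau_max:
            raise ValueError("tau_min must be <= tau_max")
        if self.tau_step <= 0:
            raise ValueError("tau_step must be > 0")

    @property
    def thresholds(self) -> tuple[float, ...]:
        n = int(round((self.tau_max - self.tau_min) / self.tau_step)) + 1
        return tuple(round(self.tau_min + i * self.tau_step, RHO_DECIMALS) for i in range(n))


def pearson_vs_seed(matrix: ExpressionMatrix, seed_probe: str) -> list[CorrelationRecord]:
    """Correlate every non-seed probe row against the seed probe row."""
    if seed_probe not in matrix:
        raise ValueError(f"seed probe {seed_probe!r} absent from matrix (excluded upstream?)")
    data = matrix.data
    s = data.loc[seed_probe].to_numpy()
    others = data.drop(index=seed_probe)
    x = others.to_numpy()
    n = s.size

    sc = s - s.mean()
    ss = float(np.sqrt(np.sum(sc**2)))
    if ss == 0.0:
        raise ValueError(f"seed probe {seed_probe!r} is constant")
    xc = x - x.mean(axis=1, keepdims=True)
    xnorm = np.sqrt(np.sum(xc**2, axis=1))
    if np.any(xnorm == 0.0):
        bad = others.index[np.where(xnorm == 0.0)[0][0]]
        raise ValueError(f"constant probe {bad!r} reached the correlation stage")
    rho = (xc @ sc) / (xnorm * ss)
    rho = np.clip(rho, -1.0, 1.0)

    records = []
    for probe, r in zip(others.index, rho):
        t, p = _t_and_p(float(r), n)
        records.append(CorrelationRecord(probe, float(r), t, p, n))
    return records


def _t_and_p(rho: float, n: int) -> tuple[float, float]:
    if n < 3:
        raise ValueError(f"need n >= 3 for the correlation t-test, got {n}")
    if abs(rho) >= 1.0:
        return math.copysign(math.inf, rho), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return t, min(p, 1.0)


def correlation_pvalue(record: CorrelationRecord) -> float:
    """Two-tail p for a correlation from Student's t with n-2 df."""
    return _t_and_p(record.rho, record.n)[1]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """alpha_cor = alpha / m."""
    if m < 1:
        raise ValueError(f"Bonferroni divisor must be >= 1, got {m}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return alpha / m


def filter_significant(records, alpha_cor: float, ledger=None) -> list[CorrelationRecord]:
    """Drop records with p > alpha_cor (strict; ties retained)."""
    survivors = [r for r in records if r.p_value <= alpha_cor]
    if ledger is not None:
        ledger.append(
            f"{SIGNIFICANCE_CRITERION} (alpha_cor = {alpha_cor:.3g})",
            len(records),
            len(records) - len(survivors),
        )
    return survivors


def filter_rho_threshold(records, tau_min: float, ledger=None) -> list[CorrelationRecord]:
    """Drop records with |rho| < tau_min (strict, on rounded |rho|)."""
    survivors = [r for r in records if round(abs(r.rho), RHO_DECIMALS) >= tau_min]
    if ledger is not None:
        ledger.append(
            f"{RHO_CRITERION} (rho < {tau_min:g})",
            len(records),
            len(records) - len(survivors),
        )
    return survivors


def split_signed(full_list: ThresholdList) -> tuple[ThresholdList, ThresholdList]:
    """Partition a full list into its positive and negative sub-lists."""
    if full_list.sign != "full":
        raise ValueError("split_signed expects a full (unsigned) list")
    pos, neg = [], []
    for gene, rho in full_list.members:
        if rho > 0:
            pos.append((gene, rho))
        elif rho < 0:
            neg.append((gene, rho))
        else:
            # rho = 0 cannot survive the significance filter (p = 1)
            raise ValueError(f"zero-correlation member {gene!r} in {full_list.label!r}")
    return (
        ThresholdList(full_list.label + "+", full_list.threshold, "positive", tuple(pos)),
        ThresholdList(full_list.label + "-", full_list.threshold, "negative", tuple(neg)),
    )


def build_ladder(records, config: PipelineConfig) -> list[ThresholdList]:
    """Build the nested ladder of full lists plus their signed splits.

    ``records`` must carry resolved, unique gene symbols. The seed gene is
    added to every full/positive list with rho = 1. Returns full lists in
    ascending gene-count order followed by their signed sub-lists
    (default ladder: 8 full + 8 positive + 8 negative = 24 lists).
    """
    by_gene: dict[str, float] = {}
    for r in records:
        if r.gene_symbol is None:
            raise ValueError(f"unresolved gene symbol for probe {r.probe_id!r}")
        if r.gene_symbol in by_gene:
            raise ValueError(f"duplicate gene symbol {r.gene_symbol!r} after resolution")
        by_gene[r.gene_symbol] = r.rho
    by_gene[config.seed_gene_symbol] = 1.0

    thresholds = config.thresholds
    full_lists: list[ThresholdList] = []
    # descending tau == ascending gene count under the nesting invariant
    for i, tau in enumerate(reversed(thresholds), start=1):
        members = sorted(
            ((g, rho) for g, rho in by_gene.items() if round(abs(rho), RHO_DECIMALS) >= tau),
            key=lambda gr: (-abs(gr[1]), gr[0]),
        )
        full_lists.append(ThresholdList(f"list {i}", tau, "full", tuple(members)))

    out = list(full_lists)
    for lst in full_lists:
        pos, neg = split_signed(lst)
        out.append(pos)
        out.append(neg)
    return out
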