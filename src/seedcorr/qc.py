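"""Jarque-Bera normality screening of probe rows with a chi2(df=2) decision.

Expression rows that are to enter a Pearson correlation screen should be
approximately normal; strongly skewed or heavy-tailed probe distributions
(e.g. probes left on a raw intensity scale) inflate spurious correlations.
Each probe row is tested with the classic Jarque-Bera statistic

    JB = (n/6) * (S^2 + (K - 3)^2 / 4)

where S and K are the population (biased, divide-by-n) skewness and
non-excess kurtosis. Under normality JB is asymptotically chi-squared with
two degrees of freedom, whose survival function is exactly exp(-x/2).

Every exclusion is appended to an auditable :class:`ExclusionLedger` whose
step counts chain (the retained count of one step is the starting count of
the next), so the ledger reproduces the probe/gene exclusion-flow table of a
run end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "NormalityRecord",
    "LedgerStep",
    "ExclusionLedger",
    "jarque_bera",
    "chi2_sf_df2",
    "filter_normality",
    "CONSTANT_CRITERION",
    "NORMALITY_CRITERION",
]

CONSTANT_CRITERION = "Constant expression (zero variance)"
NORMALITY_CRITERION = "Failed Jarque-Bera normality test / significance"


@dataclass(frozen=True)
class NormalityRecord:
    probe_id: str
    skewness: float
    kurtosis: float  # non-excess (normal -> 3)
    jb_statistic: float
    p_value: float
    passed: bool


@dataclass(frozen=True)
class LedgerStep:
    criterion: str
    count_before: int
    count_excluded: int


@dataclass
class ExclusionLedger:
    """Ordered exclusion flow; enforces chaining and conservation of counts."""

    initial_count: int
    steps: list[LedgerStep] = field(default_factory=list)

    def append(self, criterion: str, count_before: int, count_excluded: int) -> None:
        if count_excluded < 0 or count_before < 0:
            raise ValueError("ledger counts must be non-negative")
        if count_excluded > count_before:
            raise ValueError(f"cannot exclude {count_excluded} of {count_before}")
        expected = self.current_count
        if count_before != expected:
            raise ValueError(
                f"ledger discontinuity at {criterion!r}: count_before={count_before}, "
                f"expected {expected}"
            )
        self.steps.append(LedgerStep(criterion, count_before, count_excluded))

    @property
    def current_count(self) -> int:
        if not self.steps:
            return self.initial_count
        last = self.steps[-1]
        return last.count_before - last.count_excluded

    @property
    def total_excluded(self) -> int:
        return sum(s.count_excluded for s in self.steps)


def jarque_bera(values) -> tuple[float, float, float]:
    """Return (skewness, kurtosis, JB) using population moments.

    ``values`` must contain at least 4 observations with nonzero variance;
    a constant sequence is a hard error (callers exclude such probes under
    their own ledger criterion).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 values, got {n}")
    d = x - x.mean()
    m2 = float(np.mean(d**2))
    if m2 == 0.0 or m2**1.5 == 0.0:  # exactly constant, or variance underflows
        raise ValueError("zero variance (constant sequence)")
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    s = m3 / m2**1.5
    k = m4 / m2**2
    jb = (n / 6.0) * (s**2 + (k - 3.0) ** 2 / 4.0)
    return s, k, jb


def chi2_sf_df2(x: float) -> float:
    """Exact chi-squared(df=2) survival function: exp(-x/2)."""
    if x < 0:
        raise ValueError(f"chi2 statistic must be >= 0, got {x}")
    return math.exp(-x / 2.0)


def _row_jb(values: np.ndarray) -> np.ndarray:
    """Vectorized JB over matrix rows; constant rows yield NaN."""
    n = values.shape[1]
    d = values - values.mean(axis=1, keepdims=True)
    m2 = np.mean(d**2, axis=1)
    m3 = np.mean(d**3, axis=1)
    m4 = np.mean(d**4, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = m3 / m2**1.5
        k = m4 / m2**2
        jb = (n / 6.0) * (s**2 + (k - 3.0) ** 2 / 4.0)
    jb[m2 == 0.0] = np.nan
    s[m2 == 0.0] = np.nan
    k[m2 == 0.0] = np.nan
    return np.stack([s, k, jb], axis=1)


def filter_normality(
    matrix: ExpressionMatrix,
    alpha_norm: float = 0.05,
    ledger: ExclusionLedger | None = None,
    exempt: frozenset[str] | set[str] = frozenset(),
) -> tuple[ExpressionMatrix, list[NormalityRecord]]:
    """Drop probe rows whose JB p-value falls below ``alpha_norm``.

    Exclusion is strict (``p < alpha_norm``); ties at exactly ``alpha_norm``
    are retained. Constant rows are excluded first under their own ledger
    criterion. Probes named in ``exempt`` (the seed probe) are tested but
    never dropped here and are not counted in the ledger.

    Returns the retained matrix and one :class:`NormalityRecord` per
    non-exempt probe.
    """
    if not (0 <= alpha_norm < 1):
        raise ValueError(f"alpha_norm must be in [0, 1), got {alpha_norm}")
    if matrix.n_samples < 4:
        raise ValueError("need >= 4 samples for the Jarque-Bera test")

    values = matrix.data.to_numpy()
    stats = _row_jb(values)
    records: list[NormalityRecord] = []
    keep: list[str] = []
    n_constant = 0
    n_failed = 0
    counted = [p for p in matrix.probe_ids if p not in exempt]

    for probe, (s, k, jb) in zip(matrix.probe_ids, stats):
        is_exempt = probe in exempt
        if np.isnan(jb):
            if is_exempt:
                raise ValueError(f"exempt probe {probe!r} has zero variance")
            n_constant += 1
            continue
        p = chi2_sf_df2(jb)
        passed = p >= alpha_norm
        if not is_exempt:
            records.append(NormalityRecord(probe, float(s), float(k), float(jb), p, passed))
        if passed or is_exempt:
            keep.append(probe)
        else:
            n_failed += 1

    if ledger is not None:
        n0 = len(counted)
        if n_constant:
            ledger.append(CONSTANT_CRITERION, n0, n_constant)
            n0 -= n_constant
        ledger.append(NORMALITY_CRITERION, n0, n_failed)

    if not keep:
        raise ValueError("no probes survived the normality screen")
    return matrix.subset(keep), records
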