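"""Seed correlation, significance filtering and the threshold-list ladder."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedcorr.correlation import (
    CorrelationRecord,
    PipelineConfig,
    ThresholdList,
    bonferroni_threshold,
    build_ladder,
    correlation_pvalue,
    filter_rho_threshold,
    filter_significant,
    pearson_vs_seed,
    split_signed,
)
from seedcorr.io import ExpressionMatrix


def _matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


class TestPearsonVsSeed:
    def test_identical_probe_has_rho_one(self):
        m = _matrix({"seed": [1, 2, 3, 4, 5], "copy": [1, 2, 3, 4, 5]})
        (rec,) = pearson_vs_seed(m, "seed")
        assert rec.rho == pytest.approx(1.0)
        assert rec.p_value < 1e-12

    def test_negated_probe_has_rho_minus_one(self):
        m = _matrix({"seed": [1, 2, 3, 4, 5], "neg": [-1, -2, -3, -4, -5]})
        (rec,) = pearson_vs_seed(m, "seed")
        assert rec.rho == pytest.approx(-1.0)

    def test_perturbed_probe_matches_covariance_quotient(self):
        seed = [1.0, 2.0, 3.0, 4.0, 5.0]
        probe = [1.0, 2.0, 3.0, 4.0, 6.0]
        m = _matrix({"seed": seed, "probe": probe})
        (rec,) = pearson_vs_seed(m, "seed")
        # independent oracle: explicit covariance quotient in plain python
        ms, mp = sum(seed) / 5, sum(probe) / 5
        cov = sum((s - ms) * (p - mp) for s, p in zip(seed, probe))
        vs = sum((s - ms) ** 2 for s in seed)
        vp = sum((p - mp) ** 2 for p in probe)
        assert rec.rho == pytest.approx(cov / math.sqrt(vs * vp), abs=1e-10)

    def test_missing_seed_probe_is_named(self, tiny_matrix):
        with pytest.raises(ValueError, match="absent_probe"):
            pearson_vs_seed(tiny_matrix, "absent_probe")

    def test_t_statistic_consistency(self, default_truth_run):
        for rec in default_truth_run["result"].correlation_records[:50]:
            if abs(rec.rho) < 1:
                expected = rec.rho * math.sqrt((rec.n - 2) / (1 - rec.rho**2))
                assert rec.t_statistic == pytest.approx(expected, abs=1e-8)
                assert math.copysign(1, rec.t_statistic) == math.copysign(1, rec.rho)


class TestCorrelationPvalue:
    def test_null_center(self):
        rec = CorrelationRecord("p", 0.0, 0.0, 1.0, 100)
        assert correlation_pvalue(rec) == 1.0

    def test_study_scale_t_value(self):
        rec = CorrelationRecord("p", 0.34, float("nan"), float("nan"), 2158)
        t = 0.34 * math.sqrt(2156 / (1 - 0.34**2))
        assert t == pytest.approx(16.79, abs=0.01)
        assert correlation_pvalue(rec) < 1e-30

    def test_perfect_correlation_p_zero(self):
        rec = CorrelationRecord("p", 1.0, float("inf"), 0.0, 10)
        assert correlation_pvalue(rec) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            correlation_pvalue(CorrelationRecord("p", 0.5, 0, 0, 2))


class TestBonferroni:
    def test_study_sample_count_divisor(self):
        assert f"{bonferroni_threshold(0.05, 2158):.1e}" == "2.3e-05"

    def test_identity_at_m_one(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_probe_count_divisor_rejected_alternative(self):
        # dividing by the full probe count instead gives ~9.1e-7
        assert bonferroni_threshold(0.05, 54675) == pytest.approx(9.1e-7, rel=0.01)

    def test_zero_divisor_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestSignificanceFilter:
    def test_boundary_tie_retained(self):
        rec = CorrelationRecord("p", 0.3, 2.0, 0.001, 50)
        assert filter_significant([rec], 0.001) == [rec]

    def test_above_threshold_dropped_and_ledgered(self):
        from seedcorr.qc import ExclusionLedger

        recs = [
            CorrelationRecord("a", 0.3, 2.0, 0.5, 50),
            CorrelationRecord("b", 0.8, 8.0, 1e-9, 50),
        ]
        ledger = ExclusionLedger(initial_count=2)
        out = filter_significant(recs, 1e-3, ledger)
        assert [r.probe_id for r in out] == ["b"]
        assert ledger.steps[0].count_excluded == 1

    def test_rho_threshold_strict(self):
        recs = [
            CorrelationRecord("a", 0.34, 0, 0, 50),
            CorrelationRecord("b", -0.3399999, 0, 0, 50),
            CorrelationRecord("c", -0.35, 0, 0, 50),
        ]
        out = filter_rho_threshold(recs, 0.34)
        assert [r.probe_id for r in out] == ["a", "c"]


def _records(genes: dict[str, float], n=2158):
    return [
        CorrelationRecord(f"probe_{g}", rho, 0.0, 0.0, n, gene_symbol=g)
        for g, rho in genes.items()
    ]


class TestLadder:
    def test_default_config_counts(self):
        cfg = PipelineConfig()
        lists = build_ladder(_records({"A": 0.5, "B": -0.4}), cfg)
        full = [l for l in lists if l.sign == "full"]
        assert len(full) == 8
        assert len(lists) == 24

    def test_enumeration_example(self):
        cfg = PipelineConfig(seed_gene_symbol="SOD3")
        lists = build_ladder(_records({"A": 0.50, "B": -0.36, "C": 0.345}), cfg)
        by = {(l.threshold, l.sign): l for l in lists}
        assert by[(0.34, "full")].genes == {"A", "B", "C", "SOD3"}
        assert by[(0.35, "full")].genes == {"A", "B", "SOD3"}
        assert by[(0.34, "positive")].genes == {"A", "C", "SOD3"}
        assert by[(0.34, "negative")].genes == {"B"}

    def test_numbering_ascends_with_gene_count(self):
        cfg = PipelineConfig()
        lists = build_ladder(_records({"A": 0.5, "B": 0.36, "C": -0.38, "D": 0.342}), cfg)
        full = sorted(
            (l for l in lists if l.sign == "full"),
            key=lambda l: int(l.label.split()[1]),
        )
        sizes = [len(l) for l in full]
        assert sizes == sorted(sizes)
        assert full[0].threshold == 0.41
        assert full[-1].threshold == 0.34

    def test_monotone_nesting_on_synthetic_run(self, default_truth_run):
        lists = default_truth_run["result"].lists
        for sign in ("full", "positive", "negative"):
            ladder = sorted(
                (l for l in lists if l.sign == sign), key=lambda l: l.threshold
            )
            for lo, hi in zip(ladder, ladder[1:]):
                assert hi.genes <= lo.genes

    def test_seed_gene_in_every_positive_list(self, default_truth_run):
        cfg = default_truth_run["result"].config
        for l in default_truth_run["result"].lists:
            if l.sign in ("full", "positive"):
                assert cfg.seed_gene_symbol in l.genes

    def test_unresolved_records_rejected(self):
        cfg = PipelineConfig()
        with pytest.raises(ValueError, match="unresolved"):
            build_ladder([CorrelationRecord("p", 0.5, 0, 0, 100)], cfg)


class TestSplitSigned:
    def test_all_positive_list_has_empty_negative_part(self):
        lst = ThresholdList("list 1", 0.41, "full", (("A", 0.5), ("B", 0.45)))
        pos, neg = split_signed(lst)
        assert pos.genes == {"A", "B"} and neg.genes == frozenset()

    def test_forced_partition(self):
        lst = ThresholdList("list 1", 0.4, "full", (("A", 0.4), ("B", -0.4)))
        pos, neg = split_signed(lst)
        assert pos.genes == {"A"} and neg.genes == {"B"}

    def test_signed_input_rejected(self):
        lst = ThresholdList("list 1+", 0.4, "positive", (("A", 0.4),))
        with pytest.raises(ValueError, match="full"):
            split_signed(lst)

    @given(st.lists(
        st.tuples(st.text("ABCDEFGH", min_size=1, max_size=3),
                  st.floats(-0.99, 0.99).filter(lambda r: abs(r) > 1e-6)),
        min_size=1, max_size=30, unique_by=lambda gr: gr[0],
    ))
    @settings(derandomize=True, max_examples=100)
    def test_partition_property(self, members):
        lst = ThresholdList("list x", 0.0, "full", tuple(members))
        pos, neg = split_signed(lst)
        assert pos.genes | neg.genes == lst.genes
        assert not (pos.genes & neg.genes)
        assert all(r > 0 for _, r in pos.members)
        assert all(r < 0 for _, r in neg.members)
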