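"""Disorder selection: inclusion rule, smallest viable list, discrimination,
optimal-list attachment."""

import pytest

from seedcorr.correlation import ThresholdList
from seedcorr.disorders import (
    DisorderCall,
    discover_disorders,
    discriminate,
    meets_inclusion,
    select_optimal,
    smallest_viable,
)
from seedcorr.enrichment import EnrichmentResult
from seedcorr.io import GeneSetLibrary

SEED = "SOD3"


def _res(overlap, q=0.001, term="D", k=None):
    overlap = frozenset(overlap)
    return EnrichmentResult(
        term_name=term, library_name="lib", overlap_genes=overlap,
        k=len(overlap), n_list=10, K_term=8, N_bg=100,
        p_value=q / 2, q_value=q, odds_ratio=3.0,
    )


class TestMeetsInclusion:
    def test_positive_with_seed_and_two_others(self):
        assert meets_inclusion(_res({SEED, "G1", "G2"}), "positive", SEED)

    def test_positive_without_seed_fails(self):
        assert not meets_inclusion(_res({"G1", "G2", "G3"}), "positive", SEED)

    def test_negative_needs_three_genes(self):
        assert not meets_inclusion(_res({"G1", "G2"}, q=1e-9), "negative", SEED)
        assert meets_inclusion(_res({"G1", "G2", "G3"}, q=1e-9), "negative", SEED)

    def test_insignificant_q_fails(self):
        assert not meets_inclusion(_res({SEED, "G1", "G2"}, q=0.2), "positive", SEED)

    def test_unsigned_list_rejected(self):
        with pytest.raises(ValueError, match="unsigned"):
            meets_inclusion(_res({SEED, "G1", "G2"}), "full", SEED)


def _ladder():
    """Two-rung positive ladder: strict list misses G3, loose list has it."""
    strict = ThresholdList("list 1+", 0.41, "positive",
                           ((SEED, 1.0), ("G1", 0.45), ("G2", 0.44)))
    loose = ThresholdList("list 2+", 0.40, "positive",
                          ((SEED, 1.0), ("G1", 0.45), ("G2", 0.44), ("G3", 0.405)))
    return [strict, loose]


def _library():
    genes = {f"B{i}" for i in range(60)}
    terms = {
        "DeepDisorder": frozenset({SEED, "G1", "G2"} | {f"B{i}" for i in range(5)}),
        "WideDisorder": frozenset({SEED, "G1", "G2", "G3"} | {f"B{i}" for i in range(5, 9)}),
    }
    for i in range(8):
        terms[f"Decoy{i}"] = frozenset(list(sorted(genes))[i * 6:(i + 1) * 6])
    return GeneSetLibrary("disease", terms)


class TestSmallestViable:
    def test_disorder_attached_to_first_qualifying_list(self):
        out = smallest_viable(_ladder(), _library(), {}, seed_gene=SEED)
        assert out["DeepDisorder"][0].label == "list 1+"
        assert out["WideDisorder"][0].label == "list 1+"  # 3-gene overlap there

    def test_disorder_below_reach_is_absent(self):
        lib = GeneSetLibrary("disease", {
            "FarDisorder": frozenset({"Z1", "Z2", "Z3", "B0", "B1"}),
            "near": frozenset({SEED, "G1", "G2", "B2"}),
        })
        out = smallest_viable(_ladder(), lib, {}, seed_gene=SEED)
        assert "FarDisorder" not in out
        assert "near" in out


class TestDiscriminate:
    def _call(self, name, overlap, causal):
        return DisorderCall(
            disorder_name=name, causal_genes=frozenset(causal), sign="positive",
            smallest_viable_list="list 1+", smallest_result=_res(overlap, term=name),
        )

    def test_identical_twins_both_excluded(self):
        calls = [
            self._call("D1", {SEED, "G1", "G2"}, {"C1"}),
            self._call("D2", {SEED, "G1", "G2"}, {"C1"}),
        ]
        assert discriminate(calls) == []

    def test_different_causal_genes_discriminate(self):
        calls = [
            self._call("D1", {SEED, "G1", "G2"}, {"C1"}),
            self._call("D2", {SEED, "G1", "G2"}, {"C2"}),
        ]
        assert {c.disorder_name for c in discriminate(calls)} == {"D1", "D2"}

    def test_declared_synonyms_merge_into_one_call(self):
        calls = [
            self._call("Hereditary Retinoblastoma", {SEED, "G1", "G2"}, {"RB1"}),
            self._call("Non-hereditary Retinoblastoma", {SEED, "G1", "G2"}, {"RB1"}),
        ]
        merge = {
            "Hereditary Retinoblastoma": "Retinoblastoma",
            "Non-hereditary Retinoblastoma": "Retinoblastoma",
        }
        out = discriminate(calls, merge)
        assert len(out) == 1
        assert out[0].disorder_name == "Retinoblastoma"
        assert out[0].merged_from == (
            "Hereditary Retinoblastoma", "Non-hereditary Retinoblastoma",
        )


class TestSelectOptimal:
    def test_larger_overlap_wins(self):
        lists = _ladder()
        lib = _library()
        call = DisorderCall(
            disorder_name="WideDisorder", causal_genes=frozenset({"C1"}),
            sign="positive", smallest_viable_list="list 1+",
            smallest_result=_res({SEED, "G1", "G2"}, term="WideDisorder"),
        )
        out = select_optimal(call, lists, lib, seed_gene=SEED)
        assert out.optimal_list == "list 2+"  # 4-gene overlap beats 3
        assert out.optimal_result.k == 4

    def test_single_qualifying_list_is_optimal(self):
        lists = _ladder()
        lib = GeneSetLibrary("disease", {
            "OnlyDeep": frozenset({SEED, "G1", "G2", "B0", "B1"}),
            "pad": frozenset({f"B{i}" for i in range(2, 40)}),
        })
        call = DisorderCall(
            disorder_name="OnlyDeep", causal_genes=frozenset(),
            sign="positive", smallest_viable_list="list 1+",
            smallest_result=_res({SEED, "G1", "G2"}, term="OnlyDeep"),
        )
        out = select_optimal(call, lists, lib, seed_gene=SEED)
        assert out.optimal_list in ("list 1+", "list 2+")
        assert out.optimal_result.k == 3

    def test_overlap_tie_broken_by_smaller_q(self):
        # same overlap on both lists; the smaller list yields the smaller p/q
        lists = _ladder()
        lib = GeneSetLibrary("disease", {
            "Tied": frozenset({SEED, "G1", "G2", "B0", "B1"}),
            "pad": frozenset({f"B{i}" for i in range(2, 40)} | {"G3"}),
        })
        call = DisorderCall(
            disorder_name="Tied", causal_genes=frozenset(),
            sign="positive", smallest_viable_list="list 1+",
            smallest_result=_res({SEED, "G1", "G2"}, term="Tied"),
        )
        out = select_optimal(call, lists, lib, seed_gene=SEED)
        assert out.optimal_list == "list 1+"


class TestEndToEndDiscovery:
    def test_planted_disorders_and_no_decoys(self, default_truth_run):
        truth = default_truth_run["truth"]
        calls = default_truth_run["result"].disorder_calls
        assert {c.disorder_name for c in calls} == set(truth.planted_disorders)

    def test_every_call_meets_inclusion_on_both_lists(self, default_truth_run):
        cfg = default_truth_run["result"].config
        for call in default_truth_run["result"].disorder_calls:
            for res in (call.smallest_result, call.optimal_result):
                assert meets_inclusion(
                    res, call.sign, cfg.seed_gene_symbol,
                    cfg.q_threshold, cfg.min_overlap,
                )

    def test_negative_disorder_called_from_negative_ladder(self, default_truth_run):
        truth = default_truth_run["truth"]
        by_name = {c.disorder_name: c for c in default_truth_run["result"].disorder_calls}
        for name, (members, _, expected) in truth.planted_disorders.items():
            call = by_name[name]
            if truth.seed_gene_symbol not in expected:
                assert call.sign == "negative"
                assert truth.seed_gene_symbol not in call.smallest_result.overlap_genes
            else:
                assert call.sign == "positive"
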