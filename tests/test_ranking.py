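"""Within-ancestry ranking, cross-ancestry matrix, locus classification."""

import random

import numpy as np
import pytest

from gwaspar import (
    PAREstimate,
    ValidationError,
    build_comparison,
    classify_loci,
    rank_within_ancestry,
)


def est(vid="rs1", locus="L1", ancestry="EUR", par=0.1, raf=0.3, odds_ratio=1.5, rank=0):
    return PAREstimate(variant_id=vid, locus=locus, ancestry=ancestry,
                       raf=raf, odds_ratio=odds_ratio, par=par, rank=rank)


class TestRankWithinAncestry:
    def test_highest_par_gets_rank_one(self):
        es = [est("a", "L1", par=0.30), est("b", "L2", par=0.10), est("c", "L3", par=0.25)]
        ranked = {e.variant_id: e.rank for e in rank_within_ancestry(es)}
        assert ranked == {"a": 1, "c": 2, "b": 3}

    def test_dense_ties_share_rank(self):
        es = [est("a", "L1", par=0.2), est("b", "L2", par=0.2), est("c", "L3", par=0.1)]
        ranked = {e.variant_id: e.rank for e in rank_within_ancestry(es)}
        assert ranked == {"a": 1, "b": 1, "c": 2}
        assert {e.rank for e in rank_within_ancestry([est()])} == {1}

    def test_permutation_invariance(self):
        rng = random.Random(3)
        es = [est(f"rs{i}", f"L{i}", par=round(rng.random(), 3)) for i in range(15)]
        reference = rank_within_ancestry(es)
        for _ in range(5):
            shuffled = es[:]
            rng.shuffle(shuffled)
            assert rank_within_ancestry(shuffled) == reference

    def test_mixed_ancestries_rejected(self):
        with pytest.raises(ValidationError):
            rank_within_ancestry([est(ancestry="EUR"), est("rs2", "L2", ancestry="AFR")])


class TestBuildComparison:
    def test_union_semantics_with_absent_cells(self):
        per = {
            "EUR": rank_within_ancestry([est("a", "L1", "EUR", 0.3), est("b", "L2", "EUR", 0.1)]),
            "AFR": rank_within_ancestry([est("c", "L1", "AFR", 0.2), est("d", "L3", "AFR", 0.15)]),
        }
        cmp = build_comparison(per)
        assert sorted(cmp.loci) == ["L1", "L2", "L3"]
        assert cmp.par_matrix.isna().sum().sum() == 2
        assert cmp.par_matrix.notna().sum().sum() == 4  # matrix conservation
        # rows ordered by descending mean of present PARs
        assert cmp.loci[0] == "L1"

    def test_single_ancestry_degenerates_to_ranked_list(self):
        per = {"EUR": rank_within_ancestry([est("a", "L1", par=0.3), est("b", "L2", par=0.1)])}
        cmp = build_comparison(per)
        assert list(cmp.rank_matrix["EUR"]) == [1, 2]

    def test_column_order_follows_input_order(self):
        per = {
            "EUR": rank_within_ancestry([est("a", "L1", "EUR", 0.3)]),
            "AFR": rank_within_ancestry([est("b", "L1", "AFR", 0.2)]),
        }
        a = build_comparison(per)
        b = build_comparison(dict(reversed(list(per.items()))))
        assert a.ancestries == ["EUR", "AFR"] and b.ancestries == ["AFR", "EUR"]
        assert np.allclose(
            a.par_matrix[["EUR", "AFR"]].values, b.par_matrix[["EUR", "AFR"]].values
        )

    def test_duplicate_locus_rejected(self):
        with pytest.raises(ValidationError):
            build_comparison({"EUR": [est("a", "L1", par=0.3), est("b", "L1", par=0.1)]})

    def test_long_format_roundtrip(self):
        per = {"EUR": rank_within_ancestry([est("a", "L1", par=0.3)])}
        long = build_comparison(per).to_long()
        assert list(long.columns) == ["locus", "ancestry", "par", "rank"]
        assert long.iloc[0].tolist() == ["L1", "EUR", 0.3, 1]


def _three_ancestry_cmp():
    # L1 top-2 everywhere; L2 top-2 only in EUR; L4 top-2 only in AFR;
    # L3 observed only in EAS; L5 present twice but never top-2
    per = {
        "EUR": rank_within_ancestry(
            [est("a", "L1", "EUR", 0.3), est("b", "L2", "EUR", 0.25),
             est("e", "L4", "EUR", 0.01), est("i", "L5", "EUR", 0.005)]),
        "AFR": rank_within_ancestry(
            [est("c", "L1", "AFR", 0.4), est("g", "L4", "AFR", 0.002),
             est("f", "L2", "AFR", 0.001), est("j", "L5", "AFR", 0.0005)]),
        "EAS": rank_within_ancestry([est("d", "L1", "EAS", 0.2), est("h", "L3", "EAS", 0.1)]),
    }
    return build_comparison(per)


class TestClassifyLoci:
    def test_universal_enriched_single_shared(self):
        labels = classify_loci(_three_ancestry_cmp(), top_k=2, min_ancestries=3)
        assert labels["L1"] == "universal"
        assert labels["L2"] == "enriched:EUR"
        assert labels["L4"] == "enriched:AFR"
        assert labels["L3"] == "single"
        assert labels["L5"] == "shared"

    def test_monotone_in_top_k(self):
        cmp = _three_ancestry_cmp()
        for k in range(1, 5):
            small = classify_loci(cmp, top_k=k, min_ancestries=3)
            large = classify_loci(cmp, top_k=k + 1, min_ancestries=3)
            for locus, label in small.items():
                if label == "universal":
                    assert large[locus] == "universal"

    def test_min_ancestries_default_is_all(self):
        labels = classify_loci(_three_ancestry_cmp(), top_k=2)
        assert labels["L1"] == "universal"
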