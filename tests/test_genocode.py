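"""Score encoding, caller merging, tag consolidation, phase handling, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zoymap import genocode
from zoymap.genocode import (
    ConfigError,
    ScoreMatrix,
    VariantCallSet,
    collapse_cosegregating,
    consolidate_tags,
    duplicate_phase_unknown,
    encode_calls,
    expand_bins,
    filter_matrix,
    merge_callers,
    reorient_to_cross,
    segregation_test,
)
from conftest import make_scores


def _callset(records, samples, caller="HC"):
    """records: list of (scaffold, bp, gt_codes, depths)."""
    sites = pd.DataFrame(
        [{"scaffold": s, "bp": p, "ref": "G", "alt": "A", "qd": 25.0,
          "maf": 0.3, "caller": caller} for s, p, _, _ in records]
    )
    gt = np.array([r[2] for r in records], dtype=np.int8)
    dp = np.array([r[3] for r in records], dtype=np.int32)
    return VariantCallSet(sites, gt, dp, list(samples))


class TestEncodeCalls:
    def test_code_mapping_and_depth_threshold(self):
        calls = _callset(
            [("sc1", 100, [0, 1, 2, 1], [10, 7, 8, 20])], ["P1", "P2", "F1", "p1"]
        )
        sm = encode_calls(calls, min_depth=8)
        row = sm.scores.iloc[0]
        # 0/0 depth 10 -> A; het depth 7 -> U (below the inclusive >=8 cut);
        # 1/1 depth 8 -> B (boundary kept); het depth 20 -> H
        assert list(row) == ["A", "U", "B", "H"]

    def test_site_filters_exclude_low_maf_and_qd(self):
        calls = _callset(
            [("sc1", 100, [0, 1], [10, 10]), ("sc1", 200, [0, 1], [10, 10])],
            ["a", "b"],
        )
        calls.sites.loc[0, "maf"] = 0.04
        calls.sites.loc[1, "qd"] = 9.0
        sm = encode_calls(calls)
        assert len(sm.marker_ids) == 0

    def test_missing_genotype_is_u(self):
        calls = _callset([("sc1", 100, [-1, 0], [30, 30])], ["a", "b"])
        assert list(encode_calls(calls).scores.iloc[0]) == ["U", "A"]


class TestMergeCallers:
    def _sets(self):
        hc = _callset(
            [("sc1", 1, [1, 1], [9, 9]), ("sc1", 2, [1, 0], [9, 9])], ["a", "b"], "HC"
        )
        ug = _callset(
            [("sc1", 2, [0, 0], [9, 9]), ("sc1", 3, [2, 2], [9, 9])], ["a", "b"], "UG"
        )
        return hc, ug

    def test_union_by_key_with_common_origin(self):
        hc, ug = self._sets()
        merged = merge_callers(hc, ug)
        assert len(merged.sites) == 3
        tally = merged.sites.attrs["origin_tally"]
        assert tally == {"HC-only": 1, "UG-only": 1, "common": 1}

    def test_disjoint_sets_union(self):
        a = _callset([("sc1", i, [0], [9]) for i in (1, 2, 3)], ["x"], "HC")
        b = _callset([("sc1", i, [0], [9]) for i in (4, 5, 6, 7)], ["x"], "UG")
        merged = merge_callers(a, b)
        assert len(merged.sites) == 7
        assert "common" not in merged.sites.attrs["origin_tally"]

    def test_hc_precedence_resolves_conflicts(self):
        hc, ug = self._sets()
        merged = merge_callers(hc, ug, precedence="HC")
        at2 = merged.sites.index[merged.sites["bp"] == 2][0]
        assert merged.gt[at2, 0] == 1  # HC said het, UG hom-ref
        assert merged.sites.attrs["n_conflicts"] == 1

    def test_conflicts_can_be_dropped_to_missing(self):
        hc, ug = self._sets()
        merged = merge_callers(hc, ug, conflict_to_missing=True)
        at2 = merged.sites.index[merged.sites["bp"] == 2][0]
        assert merged.gt[at2, 0] == -1


class TestConsolidateTags:
    def test_identical_in_tag_snps_collapse_to_one(self):
        sm = make_scores({"m1": "ABHAH", "m2": "ABHAH"})
        sm.meta["bp"] = [100, 500]
        out = consolidate_tags(sm)
        assert len(out.marker_ids) == 1
        assert list(out.scores.iloc[0]) == list("ABHAH")

    def test_definite_absorbs_compatible_partial(self):
        sm = make_scores({"m1": "ABHAA", "m2": "ABHDA"})  # (A, D) -> A
        sm.meta["bp"] = [100, 500]
        out = consolidate_tags(sm)
        assert list(out.scores.iloc[0]) == list("ABHAA")

    def test_contradiction_becomes_missing(self):
        sm = make_scores({"m1": "ABHAA", "m2": "ABHBA"})  # (A, B) -> U
        sm.meta["bp"] = [100, 500]
        out = consolidate_tags(sm)
        assert list(out.scores.iloc[0]) == list("ABHUA")

    def test_window_boundary_starts_new_tag(self):
        sm = make_scores({"m1": "ABHAA", "m2": "ABHAA"})
        sm.meta["bp"] = [100, 1200]
        assert len(consolidate_tags(sm).marker_ids) == 2


class TestReorientAndDuplicate:
    def test_correctly_oriented_marker_unchanged(self):
        sm = make_scores({"m1": "ABHABH"})
        out = reorient_to_cross(sm)
        assert out.scores.equals(sm.scores)

    def test_swapped_parents_reoriented(self):
        sm = make_scores({"m1": "BAHABH"})  # P1=B, P2=A, progeny ABH
        out = reorient_to_cross(sm)
        assert list(out.scores.loc["m1"]) == list("ABHBAH")

    def test_het_parent_left_to_duplication(self):
        sm = make_scores({"m1": "HBHABH"})
        out = reorient_to_cross(sm)
        assert out.scores.equals(sm.scores)

    def test_phase_unknown_markers_duplicated_with_swap(self):
        sm = make_scores({"m1": "HHHAHB", "m2": "ABHCDU", "m3": "AUHCDU"})
        out = duplicate_phase_unknown(sm)
        assert list(out.marker_ids) == ["m1", "m1r", "m2", "m3", "m3r"]
        assert list(out.scores.loc["m1r"]) == list("HHHBHA")
        assert list(out.scores.loc["m3r"]) == list("BUHDCU")  # C<->D, U fixed
        assert bool(out.meta.at["m1r", "reversed"]) is True
        assert bool(out.meta.at["m1", "reversed"]) is False

    def test_phase_swap_twice_is_identity(self):
        sm = make_scores({"m1": "HHHACDBU"})
        once = sm.scores.map(lambda c: genocode.PHASE_SWAP[c])
        twice = once.map(lambda c: genocode.PHASE_SWAP[c])
        assert twice.equals(sm.scores)


class TestCollapseCosegregating:
    def test_identical_vectors_binned_to_lowest_position(self):
        sm = make_scores({"m1": "ABHAB", "m2": "ABHAB", "m3": "ABHBA"})
        sm.meta.loc["m2", "bp"] = 50  # lower than m1
        out, bins = collapse_cosegregating(sm)
        assert set(out.marker_ids) == {"m2", "m3"}
        assert sorted(bins["m2"]) == ["m1", "m2"]

    def test_u_differences_keep_markers_separate(self):
        sm = make_scores({"m1": "ABHAB", "m2": "ABHUB"})
        out, _ = collapse_cosegregating(sm)
        assert len(out.marker_ids) == 2

    def test_reexpansion_restores_original_marker_set(self):
        sm = make_scores(
            {"m1": "ABHAB", "m2": "ABHAB", "m3": "ABHAB", "m4": "ABHBA"}
        )
        out, bins = collapse_cosegregating(sm)
        assert len(out.marker_ids) == 2
        restored = expand_bins(list(out.marker_ids), bins)
        assert sorted(restored) == ["m1", "m2", "m3", "m4"]


class TestFilterMatrix:
    def test_marker_with_excess_missing_removed(self):
        good = "A" * 25 + "H" * 50 + "B" * 25
        bad = "U" * 21 + good[21:]  # 21% missing
        rows = {f"m{i}": "ABH" + good for i in range(9)}
        rows["m9"] = "ABH" + bad
        sm = make_scores(rows)
        out, removed = filter_matrix(sm)
        assert removed["markers_missing"] == ["m9"]
        assert "m9" not in out.marker_ids and len(out.marker_ids) == 9

    def test_progeny_filtered_before_markers(self):
        # one progeny that is mostly missing would otherwise push markers
        # over the missing threshold
        rows = {f"m{i}": "ABH" + "U" + "A" * 24 + "H" * 50 + "B" * 25
                for i in range(5)}
        sm = make_scores(rows)
        out, removed = filter_matrix(sm, max_missing=0.20)
        assert removed["progeny"] == ["p1"]
        assert len(out.marker_ids) == 5

    def test_chi_squared_filter_boundaries(self):
        ok = "A" * 132 + "H" * 265 + "B" * 133      # p ~ 0.98
        distorted = "A" * 530                        # p << 1e-10
        rows = {f"m{i}": "ABH" + ok for i in range(4)}
        rows["m4"] = "ABH" + distorted
        sm = make_scores(rows)
        out, removed = filter_matrix(sm)
        assert removed["markers_distorted"] == ["m4"]
        assert "m4" not in out.marker_ids and len(out.marker_ids) == 4

    def test_all_progeny_removed_is_hard_error(self):
        sm = make_scores({"m1": "ABH" + "U" * 10})
        with pytest.raises(ConfigError):
            filter_matrix(sm)

    def test_clean_simulation_loses_almost_nothing(self, clean_f2_scores):
        """Zero distortion + default filters: <= 0.1% of markers removed."""
        _, scores = clean_f2_scores
        out, removed = filter_matrix(scores)
        n_removed = len(removed["markers_missing"]) + len(removed["markers_distorted"])
        assert n_removed / len(scores.marker_ids) <= 0.001


class TestSegregationTest:
    @pytest.mark.parametrize(
        "counts,ratio,expected_p",
        [
            ((136, 371), (1, 3), 0.343),
            ((34, 103), (1, 3), 0.961),
            ((101, 324), (1, 3), 0.556),
            ((44, 114), (1, 3), 0.408),
        ],
    )
    def test_one_to_three_pvalues(self, counts, ratio, expected_p):
        assert round(segregation_test(counts, ratio).p_value, 3) == expected_p

    def test_exact_ratio_gives_statistic_zero(self):
        res = segregation_test((25, 50, 25), (1, 2, 1))
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_zero_total_raises(self):
        with pytest.raises(ConfigError):
            segregation_test((0, 0), (1, 3))

    def test_rank_ordering_matches_likelihood_ratio_oracle(self):
        """Pearson p-values order random tables like an independently coded
        multinomial likelihood-ratio test (the two are asymptotically
        equivalent; rank agreement is near-perfect, not exact)."""
        rng = np.random.default_rng(2024)
        pearson, lrt = [], []
        for _ in range(100):
            n = int(rng.integers(50, 600))
            counts = rng.multinomial(n, [0.25, 0.5, 0.25]) + 1
            pearson.append(segregation_test(counts, (1, 2, 1)).p_value)
            exp = counts.sum() * np.array([1, 2, 1]) / 4
            G = 2 * np.sum(counts * np.log(counts / exp))
            lrt.append(stats.chi2.sf(G, 2))
        rho = stats.spearmanr(pearson, lrt).statistic
        assert rho >= 0.98


class TestIO:
    def test_tsv_roundtrip(self, tmp_path, two_chrom_scores):
        path = tmp_path / "scores.tsv"
        two_chrom_scores.to_tsv(path)
        back = ScoreMatrix.read_tsv(path)
        assert back.scores.equals(two_chrom_scores.scores)
        assert back.parents == two_chrom_scores.parents
        assert back.f1 == two_chrom_scores.f1
        assert (back.meta["bp"] == two_chrom_scores.meta["bp"]).all()

    def test_vcf_roundtrip_of_definite_calls(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        sm = make_scores({"m1": "ABHAB", "m2": "ABHCU"})
        path = tmp_path / "calls.vcf"
        sm.to_vcf(path, depth=20)
        calls = genocode.read_vcf(path)
        back = encode_calls(calls, min_depth=8,
                            parents=("P1", "P2"), f1="F1")
        assert list(back.scores.iloc[0]) == list("ABHAB")
        assert list(back.scores.iloc[1]) == list("ABHUU")  # C and U -> ./.
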