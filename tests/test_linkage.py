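"""Recombination-fraction estimation, grouping, ordering and map distances."""

import itertools
import math

import numpy as np
import pytest

from zoymap import linkage, simdata
from zoymap.genocode import duplicate_phase_unknown
from zoymap.linkage import (
    PairwiseRF,
    build_linkage_map,
    count_double_recombinants,
    dedupe_mirror_groups,
    estimate_rf,
    filter_double_recombinants,
    group_markers,
    kosambi_cm,
    kosambi_r,
    map_distances,
    order_markers,
    rescue_distorted_regions,
)
from conftest import make_scores


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def _oracle_joint(r):
    """Hand-written 9-cell F2 joint table (independent of the package's)."""
    P = np.zeros((3, 3))
    g = {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2, (0, 1): r / 2, (1, 0): r / 2}
    for (a1, a2), p in g.items():
        for (b1, b2), q in g.items():
            P[a1 + b1][a2 + b2] += p * q
    return P

_ORACLE_COMPAT = {
    "A": [0], "H": [1], "B": [2], "C": [1, 2], "D": [0, 1], "U": [0, 1, 2]
}


def _oracle_loglik(v1, v2, r):
    total = 0.0
    P = _oracle_joint(r)
    for c1, c2 in zip(v1, v2):
        if c1 == "U" or c2 == "U":
            continue
        p = sum(P[g1][g2] for g1 in _ORACLE_COMPAT[c1] for g2 in _ORACLE_COMPAT[c2])
        total += math.log(max(p, 1e-300))
    return total


def _oracle_grid_rhat(v1, v2):
    grid = np.arange(0.0, 0.5001, 0.001)
    lls = [_oracle_loglik(v1, v2, r) for r in grid]
    return float(grid[int(np.argmax(lls))])


# ---------------------------------------------------------------------------
# Two-point estimation
# ---------------------------------------------------------------------------

class TestEstimateRF:
    def test_identical_informative_vectors_pin_r_at_zero(self):
        v = ["A"] * 25 + ["H"] * 50 + ["B"] * 25
        est = estimate_rf(v, v)
        assert est.r_hat == 0.0
        expected_lod = 25 * math.log10(4) + 50 * math.log10(2) + 25 * math.log10(4)
        assert est.lod == pytest.approx(expected_lod, rel=1e-9)

    def test_independent_vectors_estimate_near_half(self):
        rng = np.random.default_rng(3)
        codes = np.array(["A", "H", "B"])
        v1 = codes[rng.choice(3, 800, p=[0.25, 0.5, 0.25])]
        v2 = codes[rng.choice(3, 800, p=[0.25, 0.5, 0.25])]
        est = estimate_rf(list(v1), list(v2))
        assert est.r_hat > 0.42
        assert est.lod < 1.0

    def test_symmetry_in_marker_order(self):
        rng = np.random.default_rng(4)
        codes = np.array(["A", "H", "B", "C", "D", "U"])
        v1 = list(codes[rng.integers(6, size=300)])
        v2 = list(codes[rng.integers(6, size=300)])
        a, b = estimate_rf(v1, v2), estimate_rf(v2, v1)
        assert a.r_hat == pytest.approx(b.r_hat, abs=1e-12)
        assert a.lod == pytest.approx(b.lod, abs=1e-9)

    def test_matches_grid_search_oracle_on_random_tables(self):
        """MLE within 1e-3 of a brute-force grid search of the same likelihood
        (100 random small tables with partial and missing codes)."""
        rng = np.random.default_rng(5)
        codes = np.array(["A", "H", "B", "C", "D", "U"])
        for _ in range(100):
            n = int(rng.integers(20, 80))
            # draw linked-ish pairs so estimates span the whole range
            r_true = rng.uniform(0, 0.5)
            g1 = rng.choice(3, n, p=[0.25, 0.5, 0.25])
            flip = rng.random(n) < r_true
            g2 = np.where(flip, rng.choice(3, n, p=[0.25, 0.5, 0.25]), g1)
            v1 = codes[g1].copy()
            v2 = codes[g2].copy()
            degrade = rng.random(n) < 0.15
            v2[degrade & (v2 == "B")] = "C"
            v2[degrade & (v2 == "A")] = "D"
            v1[rng.random(n) < 0.05] = "U"
            est = estimate_rf(list(v1), list(v2))
            oracle = _oracle_grid_rhat(v1, v2)
            assert abs(est.r_hat - oracle) <= 1e-3

    def test_too_few_informative_pairs_flagged(self):
        est = estimate_rf(["A", "U", "U"], ["U", "H", "B"])
        assert not est.valid
        assert math.isnan(est.r_hat)

    def test_error_aware_likelihood_corrects_inflation(self):
        """With miscodings, the error-blind MLE overestimates r between tightly
        linked markers; modelling the error rate removes most of the bias."""
        genome = simdata.GenomeSpec.uniform([2.0], spacing_cm=2.0)
        truth = simdata.simulate_cross(genome, 800, seed=6)
        model = simdata.ObservationModel(
            min_depth=1, depth_mean=100, depth_dispersion=1e6,
            error_rate=0.01, partial_code_rate=0.0, missing_rate=0.0,
        )
        scores = simdata.observe_genotypes(truth, model, seed=7)
        prog = scores.progeny
        v1, v2 = list(prog.iloc[0]), list(prog.iloc[1])
        blind = estimate_rf(v1, v2, error_rate=0.0)
        aware = estimate_rf(v1, v2, error_rate=0.01)
        r_true = kosambi_r(2.0)  # ~0.02
        assert blind.r_hat > aware.r_hat
        assert abs(aware.r_hat - r_true) < abs(blind.r_hat - r_true)


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

class TestMapFunctions:
    def test_kosambi_values(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.1) == pytest.approx(25 * math.log(1.2 / 0.8), rel=1e-12)
        assert kosambi_cm(0.1) == pytest.approx(10.14, abs=0.01)

    def test_kosambi_roundtrip_to_1e12(self):
        r = np.linspace(0.0, 0.49, 200)
        assert np.max(np.abs(kosambi_r(kosambi_cm(r, max_cm=None)) - r)) < 1e-12

    def test_r_at_half_capped_with_warning(self):
        with pytest.warns(UserWarning):
            assert kosambi_cm(0.5, max_cm=50.0) == 50.0


# ---------------------------------------------------------------------------
# Grouping and mirror-group removal
# ---------------------------------------------------------------------------

class TestGrouping:
    def test_two_chromosomes_make_two_groups(self, two_chrom_scores):
        rf = PairwiseRF(two_chrom_scores)
        groups, ungrouped = group_markers(rf, min_lod=12, no_map_cm=15)
        assert len(groups) == 2
        for g in groups:
            chroms = {m.split("_")[0] for m in g}
            assert len(chroms) == 1  # no cross-chromosome contamination
        assert not ungrouped

    def test_all_missing_marker_ungrouped(self, two_chrom_scores):
        sm = two_chrom_scores.copy()
        sm.scores.iloc[0] = "U"
        rf = PairwiseRF(sm)
        groups, ungrouped = group_markers(rf)
        assert sm.marker_ids[0] in ungrouped

    def test_mirror_groups_collapse_32_to_22(self):
        """10 mirror pairs among 32 raw groups leave 22 after dedup."""
        groups = []
        for i in range(10):
            groups.append([f"a{i}", f"b{i}r"])
            groups.append([f"a{i}r", f"b{i}"])
        for j in range(12):
            groups.append([f"c{j}_1", f"c{j}_2"])
        kept, report = dedupe_mirror_groups(groups)
        assert len(kept) == 22
        dropped = report[report["event"] == "mirror-dropped"]
        # every duplicated marker family appears exactly once in the report
        base = dropped["marker"].str.rstrip("r")
        assert base.is_unique
        assert len(dropped) == 20  # 10 dropped groups x 2 markers

    def test_group_without_twins_untouched(self):
        kept, _ = dedupe_mirror_groups([["x1", "x2"], ["y1", "y2"]])
        assert kept == [["x1", "x2"], ["y1", "y2"]]

    def test_twin_within_one_group_reported_not_dropped(self):
        kept, report = dedupe_mirror_groups([["m1", "m1r", "m2"]])
        assert kept == [["m1", "m1r", "m2"]]
        assert (report["event"] == "twin-in-same-group").sum() == 2


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------

class _TableRF:
    """RF provider backed by a fixed symmetric r table (for ordering tests)."""

    def __init__(self, ids, table):
        self.marker_ids = list(ids)
        self._t = table

    def r(self, a, b):
        return self._t[frozenset((a, b))]


class TestOrdering:
    def test_three_markers_additive_distances(self):
        ids = ["m1", "m2", "m3"]
        t = {frozenset(("m1", "m2")): 0.05, frozenset(("m2", "m3")): 0.05,
             frozenset(("m1", "m3")): 0.10}
        order = order_markers(ids, _TableRF(ids, t))
        assert order in (["m1", "m2", "m3"], ["m3", "m2", "m1"])

    def test_two_opt_matches_exhaustive_sarf_minimum(self):
        """Seriation + 2-opt (exhaustive shortcut disabled) reaches the
        brute-force SARF optimum on random 7-8 marker tables."""
        rng = np.random.default_rng(8)
        for trial in range(10):
            n = int(rng.integers(7, 9))
            ids = [f"m{i}" for i in range(n)]
            true_pos = np.sort(rng.uniform(0, 60, n))
            t = {}
            for i, j in itertools.combinations(range(n), 2):
                d = abs(true_pos[i] - true_pos[j])
                r = kosambi_r(d) + rng.normal(0, 0.01)
                t[frozenset((ids[i], ids[j]))] = float(np.clip(r, 0, 0.5))
            rf = _TableRF(ids, t)
            got = order_markers(ids, rf, exhaustive_limit=2, seed=trial)
            best = min(
                (sum(rf.r(a, b) for a, b in zip(p[:-1], p[1:]))
                 for p in itertools.permutations(ids)),
            )
            assert linkage.sarf(got, rf) == pytest.approx(best, abs=1e-9)

    def test_simulated_order_recovery_kendall_tau(self):
        """50 markers over 100 cM, n=530: ordering recovers the true order
        (Kendall tau >= 0.95 up to reversal)."""
        from scipy.stats import kendalltau

        genome = simdata.GenomeSpec.uniform([100.0], spacing_cm=100.0 / 49)
        truth = simdata.simulate_cross(genome, 530, seed=9)
        scores = simdata.observe_genotypes(truth, simdata.PERFECT_OBSERVATION, seed=10)
        rf = PairwiseRF(scores)
        order = order_markers(list(scores.marker_ids), rf, scores.meta, seed=0)
        true_rank = {m: i for i, m in enumerate(scores.marker_ids)}
        got = [true_rank[m] for m in order]
        tau = kendalltau(got, range(len(got))).statistic
        assert abs(tau) >= 0.95

    def test_reversal_leaves_sarf_and_distances_unchanged(self, two_chrom_scores):
        rf = PairwiseRF(two_chrom_scores)
        groups, _ = group_markers(rf)
        order = order_markers(groups[0], rf, two_chrom_scores.meta)
        adj, cm = map_distances(order, rf)
        radj, rcm = map_distances(order[::-1], rf)
        assert linkage.sarf(order, rf) == pytest.approx(
            linkage.sarf(order[::-1], rf), abs=1e-12
        )
        assert np.allclose(np.diff(cm), np.diff(rcm)[::-1])


# ---------------------------------------------------------------------------
# Double recombinants
# ---------------------------------------------------------------------------

class TestDoubleRecombinants:
    def test_xyx_pattern_counts_one_event(self):
        sm = make_scores({"l": "ABHA", "m": "ABHB", "r": "ABHA"})
        counts = count_double_recombinants(["l", "m", "r"], sm)
        assert list(counts) == [0, 1, 0]

    def test_indefinite_middle_not_counted(self):
        sm = make_scores({"l": "ABHA", "m": "ABHU", "r": "ABHA"})
        assert list(count_double_recombinants(["l", "m", "r"], sm)) == [0, 0, 0]

    def test_marker_above_threshold_removed(self):
        n = 530
        flank = "A" * n
        noisy = "B" * 11 + "A" * (n - 11)  # 11 X-Y-X events
        sm = make_scores({"l": "ABH" + flank, "m": "ABH" + noisy, "r": "ABH" + flank})
        kept, removed = filter_double_recombinants(["l", "m", "r"], sm, max_events=10)
        assert removed == ["m"]
        assert kept == ["l", "r"]


# ---------------------------------------------------------------------------
# Full map build, phase resolution, rescue
# ---------------------------------------------------------------------------

class TestBuildMap:
    def test_build_resolves_duplicated_phases(self, two_chrom_scores):
        """With every marker phase-duplicated, the map keeps one phase per
        marker and still finds the two simulated chromosomes."""
        sm = two_chrom_scores.copy()
        sm.scores["P1"] = "H"  # make parental phase unknown everywhere
        sm.scores["P2"] = "H"
        dup = duplicate_phase_unknown(sm)
        assert len(dup.marker_ids) == 2 * len(sm.marker_ids)
        lmap = build_linkage_map(dup)
        assert len(lmap.groups) == 2
        for g in lmap.groups:
            bases = [m.rstrip("r") for m in g.markers]
            assert len(bases) == len(set(bases))  # no marker with its twin
        total = sum(len(g.markers) for g in lmap.groups)
        assert total == len(sm.marker_ids)

    def test_map_length_close_to_simulated_truth(self, two_chrom_scores):
        lmap = build_linkage_map(two_chrom_scores)
        lengths = sorted(g.length_cm for g in lmap.groups)
        assert lengths[0] == pytest.approx(60, abs=12)
        assert lengths[1] == pytest.approx(80, abs=12)

    def test_rescue_restores_distorted_region(self):
        """A driver locus (zygotic k=0.95) knocks out part of a chromosome at
        the chi-squared filter; rescue re-admits it and the LG spans the
        full simulated chromosome again."""
        from zoymap.genocode import filter_matrix

        genome = simdata.GenomeSpec.uniform([60.0], spacing_cm=5.0)
        d = simdata.DistortionSpec("chr01", 30.0, 0.97, stage="zygotic")
        truth = simdata.simulate_cross(genome, 530, distortions=(d,), seed=30)
        scores = simdata.observe_genotypes(truth, simdata.PERFECT_OBSERVATION, seed=31)
        filtered, removed = filter_matrix(scores)
        assert removed["markers_distorted"]  # the driver region is dropped
        lmap = build_linkage_map(filtered)
        short = max(g.length_cm for g in lmap.groups)
        rescued = rescue_distorted_regions(
            lmap, scores, removed["markers_distorted"],
            {"chr01": lmap.groups[0].name},
        )
        full = max(g.length_cm for g in rescued.groups)
        assert rescued.groups[0].markers != lmap.groups[0].markers
        assert full > short
        assert full == pytest.approx(60, abs=12)

    def test_rescue_with_empty_removal_list_is_noop(self, two_chrom_scores):
        lmap = build_linkage_map(two_chrom_scores)
        same = rescue_distorted_regions(lmap, two_chrom_scores, [], {})
        assert [g.markers for g in same.groups] == [g.markers for g in lmap.groups]
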