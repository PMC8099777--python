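import math

import numpy as np
import pytest

from qpi.assignment import SearchParams, search_and_vote
from qpi.chem import HEAVY_VAL, PHOSPHO
from qpi.fragments import ION_TYPES
from qpi.ladder import PTMLadder, Stretch, build_ladder, stretches_for
from qpi.quant import (
    FragmentPair,
    build_system,
    collect_pairs,
    compare_stretches,
    count_pair_positions,
    detect_occupancy,
    group_isomers,
    prune_candidates,
    solve_abundances,
    stretch_ratio,
)
from qpi.simulate import SimulationConfig, simulate_spectrum_set

from conftest import UBIQUITIN


def make_ladders(spectra, sequence, n_mods, mod, ion_types=("c", "z"),
                 tolerance=3.0, vote_k=2):
    params = SearchParams(ion_types=tuple(ion_types), tolerance_ppm=tolerance,
                          max_mods=n_mods, mod=mod, vote_k=vote_k)
    voted = search_and_vote(spectra, sequence, params)
    L = len(sequence)
    return {
        t: build_ladder(
            voted, t, L, n_mods,
            [(i, "none") for i in ion_types if ION_TYPES[i].terminus == t],
        )
        for t in ("N", "C")
    }


def simulate_ladders(proteoforms, sequence=UBIQUITIN, mod=HEAVY_VAL, seed=0,
                     **sim_kwargs):
    n_mods = len(proteoforms[0][0])
    cfg = SimulationConfig(
        sequence, mod, proteoforms,
        ion_efficiencies={"c": 1.0, "z": 0.9}, seed=seed, **sim_kwargs,
    )
    spectra, truth = simulate_spectrum_set(cfg)
    return make_ladders(spectra, sequence, n_mods, mod), truth


@pytest.fixture(scope="module")
def mix_ladder():
    ladders, _ = simulate_ladders([((17,), 0.5), ((70,), 0.5)], seed=3)
    return ladders["N"]


class TestCollectPairs:
    def _stretch(self):
        return [s for s in stretches_for([17, 70], "N", 76) if s.mod_count == 1][0]

    def test_all_cells_present_pairs_equal_possible(self, mix_ladder):
        st = self._stretch()
        pairs = collect_pairs(mix_ladder, st, 0)
        assert len(pairs) == count_pair_positions(mix_ladder, st, 0)
        assert len(pairs) == st.n_cleavages  # one c-ion pair per cleavage

    def test_absent_high_level_gives_zero_pairs(self, mix_ladder):
        st = [s for s in stretches_for([17, 70], "N", 76) if s.mod_count == 0][0]
        # before site 17 everything is unmodified: no level-1 partner
        assert collect_pairs(mix_ladder, st, 0) == []
        assert count_pair_positions(mix_ladder, st, 0) > 0

    def test_missing_level_skipped_but_counted(self):
        ladder = PTMLadder("N", 12, 1, [("c", "none")])
        for c in range(1, 10):
            ladder.add(c, 0, ("c", "none"), 100.0)
            if c != 5:  # one position misses the modified partner
                ladder.add(c, 1, ("c", "none"), 50.0)
        st = Stretch("N", 1, 9, 0)
        assert len(collect_pairs(ladder, st, 0)) == 8
        assert count_pair_positions(ladder, st, 0) == 9


class TestStretchRatio:
    def _pairs(self, ratios):
        return [
            FragmentPair("N", i + 1, ("c", "none"), 100.0, 100.0 * r)
            for i, r in enumerate(ratios)
        ]

    def test_all_ones(self):
        sr = stretch_ratio(self._pairs([1.0] * 5))
        assert sr.median_ratio == 1.0
        assert sr.sem == 0.0

    def test_known_sem(self):
        ratios = [0.9, 1.0, 1.1, 1.0, 1.0]
        sr = stretch_ratio(self._pairs(ratios))
        assert sr.median_ratio == 1.0
        assert sr.sem == pytest.approx(np.std(ratios, ddof=1) / math.sqrt(5))
        assert sr.sem == pytest.approx(0.0316, abs=0.002)

    def test_below_floor_flagged(self):
        sr = stretch_ratio(self._pairs([1.0, 2.0]))
        assert not sr.reliable

    def test_synthetic_1to1_mix(self):
        ladders, _ = simulate_ladders(
            [((17,), 0.5), ((70,), 0.5)], seed=8,
            noise_cv=0.10, dropout=0.10, ppm_sd=1.0, decoy_density=2.0,
        )
        st = [s for s in stretches_for([17, 70], "N", 76) if s.mod_count == 1][0]
        pairs = collect_pairs(ladders["N"], st, 0)
        sr = stretch_ratio(pairs, st, count_pair_positions(ladders["N"], st, 0))
        assert sr.median_ratio == pytest.approx(1.0, abs=0.05)
        assert sr.reliable


class TestCompareStretches:
    def _sr(self, ratios):
        return stretch_ratio(
            [FragmentPair("N", i + 1, ("c", "none"), 1.0, r)
             for i, r in enumerate(ratios)]
        )

    def test_identical_samples_p1(self):
        a = self._sr([1.0] * 4)
        assert compare_stretches(a, self._sr([1.0] * 4)) == 1.0

    def test_separated_means(self):
        rng = np.random.default_rng(0)
        a = self._sr(list(1.0 + 0.01 * rng.standard_normal(6)))
        b = self._sr(list(3.0 + 0.01 * rng.standard_normal(6)))
        assert compare_stretches(a, b) < 1e-6

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = self._sr(list(1.0 + 0.2 * rng.standard_normal(8)))
        b = self._sr(list(1.3 + 0.2 * rng.standard_normal(8)))
        assert compare_stretches(a, b) == compare_stretches(b, a)

    def test_requires_two_pairs_each(self):
        with pytest.raises(ValueError):
            compare_stretches(self._sr([1.0]), self._sr([1.0, 2.0]))

    def test_two_isomer_mix_middle_site_not_significant(self):
        # A + C only: both stretches share the same ratio -> middle site
        # (residue 26) is not modified
        ladders, _ = simulate_ladders(
            [((17,), 0.5), ((70,), 0.5)], seed=5,
            noise_cv=0.10, dropout=0.10, ppm_sd=1.0,
        )
        stretches = stretches_for([17, 26, 70], "N", 76)
        a = stretch_ratio(collect_pairs(ladders["N"], stretches[1], 0))
        b = stretch_ratio(collect_pairs(ladders["N"], stretches[2], 0))
        assert compare_stretches(a, b) > 0.05

    def test_three_isomer_mix_middle_site_significant(self):
        ladders, _ = simulate_ladders(
            [((17,), 1 / 3), ((26,), 1 / 3), ((70,), 1 / 3)], seed=6,
            noise_cv=0.10, dropout=0.10, ppm_sd=1.0,
        )
        stretches = stretches_for([17, 26, 70], "N", 76)
        a = stretch_ratio(collect_pairs(ladders["N"], stretches[1], 0))
        b = stretch_ratio(collect_pairs(ladders["N"], stretches[2], 0))
        assert compare_stretches(a, b) < 0.05


class TestDetectOccupancy:
    def test_single_isomer_full(self):
        ladders, _ = simulate_ladders([((17,), 1.0)], seed=7)
        assert detect_occupancy(ladders["N"], 17) == "full"

    def test_mix_partial_at_differing_sites(self):
        ladders, _ = simulate_ladders([((17,), 0.5), ((70,), 0.5)], seed=7)
        assert detect_occupancy(ladders, 17) == "partial"
        # past 70 every molecule is modified somewhere, so the N ladder alone
        # shows a clean step; the C ladder exposes the 50% occupancy
        assert detect_occupancy(ladders, 70) == "partial"

    def test_unmodified_site(self):
        ladders, _ = simulate_ladders([((17,), 1.0)], seed=7)
        assert detect_occupancy(ladders, 26) == "unmodified"

    def test_shared_site_full_in_mixture(self):
        # every isomer carries site 26; sites 17/70 differ
        ladders, _ = simulate_ladders(
            [((17, 26), 0.5), ((26, 70), 0.5)], seed=9,
        )
        assert detect_occupancy(ladders, 26) == "full"

    def test_insufficient_evidence(self):
        ladder = PTMLadder("N", 20, 1, [("c", "none")])
        assert detect_occupancy(ladder, 5) == "undetermined"


def rank_deficient_fixture():
    """Hand-built noise-free ladder from a mixture of isomers (17,26) at 0.3
    and (19,26) at 0.7, with no evidence over cleavages 17..25: the two
    isomers become indistinguishable; candidate (26,70) stays excluded."""
    ladder = PTMLadder("N", 76, 2, [("c", "none")])
    for c in range(1, 17):
        ladder.add(c, 0, ("c", "none"), 100.0)
    for c in range(26, 70):
        ladder.add(c, 2, ("c", "none"), 100.0)
    candidates = [(17, 26), (19, 26), (26, 70)]
    return ladder, candidates


class TestBuildAndSolve:
    def test_two_isomer_full_rank(self):
        ladders, _ = simulate_ladders([((17,), 0.5), ((70,), 0.5)], seed=11)
        system = build_system([(17,), (70,)], ladders, prune=False)
        assert system.n_isomers == 2
        assert not system.is_rank_deficient()
        # fractions within a stretch sum to 1
        by_stretch = {}
        for row, a_row in zip(system.rows, system.A):
            by_stretch.setdefault((row.terminus, row.stretch.start), []).append(row)
        for rows in by_stretch.values():
            assert sum(r.fraction for r in rows) == pytest.approx(1.0)

    def test_three_isomer_design_structure(self):
        ladders, _ = simulate_ladders(
            [((17,), 1 / 3), ((26,), 1 / 3), ((70,), 1 / 3)], seed=12,
        )
        system = build_system([(17,), (26,), (70,)], ladders, prune=False)
        # stretch 17..25 separates A from (B, C); stretch 26..69 separates
        # (A, B) from C -> full rank
        assert not system.is_rank_deficient()
        res = solve_abundances(system)
        assert all(abs(a - 1 / 3) < 0.05 for a in res.abundances)

    def test_noise_free_exact_recovery(self):
        truth_alpha = {17: 1 / 13, 26: 4 / 13, 70: 8 / 13}
        ladders, _ = simulate_ladders(
            [((17,), 1 / 13), ((26,), 4 / 13), ((70,), 8 / 13)], seed=13,
        )
        system = build_system([(17,), (26,), (70,)], ladders, prune=False)
        res = solve_abundances(system)
        got = dict(zip((g.members[0][0] for g in res.groups), res.abundances))
        for site, expected in truth_alpha.items():
            assert got[site] == pytest.approx(expected, abs=1e-9)
        # independent exact linear-algebra oracle on the same system
        oracle, *_ = np.linalg.lstsq(system.A, system.b, rcond=None)
        for a, b in zip(res.abundances, oracle):
            assert a == pytest.approx(b, abs=1e-9)
        assert sum(res.abundances) == pytest.approx(1.0, abs=1e-12)

    def test_single_isomer(self):
        ladders, _ = simulate_ladders([((17,), 1.0)], seed=14)
        system = build_system([(17,)], ladders, prune=False)
        res = solve_abundances(system)
        assert res.abundances == (1.0,)

    def test_rank_deficient_isomers_grouped(self):
        ladder, candidates = rank_deficient_fixture()
        system = build_system(candidates, {"N": ladder}, prune=False)
        assert system.is_rank_deficient()
        res = solve_abundances(system)
        grouped = {g.members: a for g, a in zip(res.groups, res.abundances)}
        pair_group = next(m for m in grouped if len(m) == 2)
        assert set(pair_group) == {(17, 26), (19, 26)}
        # grouped sum equals the sum of ground-truth member abundances
        assert grouped[pair_group] == pytest.approx(0.3 + 0.7, abs=1e-9)
        assert grouped[((26, 70),)] == pytest.approx(0.0, abs=1e-9)

    def test_sums_match_truth_with_extra_candidate(self):
        ladders, _ = simulate_ladders(
            [((17, 26), 0.3), ((17, 70), 0.7)], seed=15,
        )
        system = build_system([(17, 26), (17, 70), (26, 70)], ladders, prune=False)
        res = solve_abundances(system)
        total = {m: a for g, a in zip(res.groups, res.abundances) for m in g.members}
        assert sum(res.abundances) == pytest.approx(1.0, abs=1e-9)
        assert total[(17, 26)] == pytest.approx(0.3, abs=1e-6)
        assert total[(17, 70)] == pytest.approx(0.7, abs=1e-6)

    def test_empty_candidates_rejected(self):
        ladders, _ = simulate_ladders([((17,), 1.0)], seed=16)
        with pytest.raises(ValueError):
            build_system([], ladders)


class TestPruneAndGroup:
    def test_pruning_keeps_level_consistent_candidates(self):
        # between sites 17 and 70 both levels are populated, so a middle
        # candidate stays level-consistent; only ratios can exclude it
        ladders, _ = simulate_ladders([((17,), 0.5), ((70,), 0.5)], seed=17)
        kept = prune_candidates([(17,), (26,), (70,)], ladders)
        assert kept == [(17,), (26,), (70,)]

    def test_pruning_removes_level_inconsistent_isomer(self):
        ladders, _ = simulate_ladders([((17,), 1.0)], seed=17)
        # candidate (70,) needs unmodified fragments over 17..69 where only
        # modified ones exist
        assert prune_candidates([(17,), (70,)], ladders) == [(17,)]

    def test_full_rank_all_singletons(self):
        ladders, _ = simulate_ladders([((17,), 0.4), ((70,), 0.6)], seed=18)
        system = build_system([(17,), (70,)], ladders, prune=False)
        groups = group_isomers(system)
        assert all(len(g.members) == 1 for g in groups)

    def test_group_labels_share_and_alternate(self):
        ladder, candidates = rank_deficient_fixture()
        system = build_system(candidates, {"N": ladder}, prune=False)
        groups = group_isomers(system)
        pair = next(g for g in groups if len(g.members) == 2)
        assert pair.shared_sites == (26,)
        assert set(pair.alternative_sites) == {(17,), (19,)}
        assert "|" in pair.label

    def test_empty_candidates_empty_grouping(self):
        assert prune_candidates([], {}) == []


class TestRecoveryProperty:
    @pytest.mark.parametrize("ratio", [1, 2, 4, 8, 16, 32])
    def test_two_isomer_ratio_recovery(self, ratio):
        a = ratio / (ratio + 1)
        ladders, _ = simulate_ladders(
            [((17,), a), ((70,), 1 - a)], seed=100 + ratio,
            noise_cv=0.10, dropout=0.10, ppm_sd=1.0,
        )
        st = [s for s in stretches_for([17, 70], "N", 76) if s.mod_count == 1][0]
        pairs = collect_pairs(ladders["N"], st, 0)
        assert len(pairs) >= 8
        system = build_system([(17,), (70,)], ladders, prune=False)
        res = solve_abundances(system)
        got = dict(zip((g.members[0][0] for g in res.groups), res.abundances))
        recovered = got[17] / got[70]
        assert abs(recovered - ratio) / ratio <= 0.10
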