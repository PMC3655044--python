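import numpy as np
import pytest

from schemarec.alignment import AlignedSequence, ParentPair
from schemarec.energy import CrossoverScheme, disruption_energy, oracle_energy
from schemarec.landscape import (
    DisruptionLandscape,
    composition_stats,
    filter_candidates_by_composition,
    find_minima,
    scan_double,
    scan_single,
)
from schemarec.structure import contact_map_from_pairs
from schemarec.synthetic import (
    SyntheticFamilySpec,
    enumerate_all_energies,
    make_parent_pair,
    make_random_contact_map,
)


@pytest.fixture(scope="module")
def toy():
    fam = make_parent_pair(SyntheticFamilySpec(
        L=12, n_homologs=2, divergence=0.5, n_gap_events=1,
        gap_length_range=(1, 2), seed=21))
    cmap = make_random_contact_map(12, 5, seed=22)
    return fam.pair, cmap


class TestScanSingle:
    def test_identical_parents_all_zero(self):
        pair = ParentPair(AlignedSequence("a", "ACDEFGHIKL"),
                          AlignedSequence("b", "ACDEFGHIKL"))
        cmap = contact_map_from_pairs([(1, 5), (3, 9)])
        assert np.all(scan_single(pair, cmap, "AB") == 0)

    @pytest.mark.parametrize("pattern", ["AB", "BA"])
    def test_elementwise_equals_oracle(self, toy, pattern):
        pair, cmap = toy
        profile = scan_single(pair, cmap, pattern)
        assert len(profile) == pair.n_columns - 1
        for x in range(1, pair.n_columns):
            assert profile[x - 1] == oracle_energy(
                pair, cmap, CrossoverScheme(pattern, (x,)))

    def test_terminal_cut_with_uncontacted_difference(self):
        # last column differs but no contact touches it
        pair = ParentPair(AlignedSequence("a", "ACDEFG"), AlignedSequence("b", "ACDEFY"))
        cmap = contact_map_from_pairs([(1, 4)])
        assert scan_single(pair, cmap, "AB")[-1] == 0

    def test_rejects_double_patterns(self, toy):
        with pytest.raises(ValueError):
            scan_single(*toy, pattern="ABA")


class TestScanDouble:
    def test_identical_parents_all_admitted_zero(self):
        pair = ParentPair(AlignedSequence("a", "ACDEFGHIKLMN"),
                          AlignedSequence("b", "ACDEFGHIKLMN"))
        cmap = contact_map_from_pairs([(1, 7), (3, 11)])
        land = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        assert np.all(land.energies[land.admitted] == 0)

    def test_full_equality_with_exhaustive_oracle(self, toy):
        pair, cmap = toy
        land = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        table = enumerate_all_energies(pair, cmap, "ABA", 2)
        assert land.n_admitted == len(table) <= 66
        for row in table.itertuples():
            assert land.energy_at(row.x1, row.x2) == row.E

    def test_aba_bab_parent_swap_symmetry(self, toy):
        pair, cmap = toy
        land_aba = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        land_bab = scan_double(pair, cmap, "BAB", min_middle_fragment=2)
        assert np.array_equal(land_aba.admitted, land_bab.admitted)
        assert np.array_equal(land_aba.energies[land_aba.admitted],
                              land_bab.energies[land_bab.admitted])

    def test_admissibility_mask_shape(self, toy):
        pair, cmap = toy
        L = pair.n_columns
        land = scan_double(pair, cmap, "ABA", min_middle_fragment=3)
        x1g, x2g = np.meshgrid(np.arange(1, L + 1), np.arange(1, L + 1), indexing="ij")
        expect = (x2g <= L - 1) & (x2g - x1g >= 3)
        assert np.array_equal(land.admitted, expect)

    def test_shrinking_min_middle_only_adds_cells(self, toy):
        pair, cmap = toy
        wide = scan_double(pair, cmap, "ABA", min_middle_fragment=5)
        narrow = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        assert np.all(narrow.admitted[wide.admitted])
        assert np.array_equal(wide.energies[wide.admitted],
                              narrow.energies[wide.admitted])

    def test_sampled_cells_match_per_cell_evaluation(self):
        fam = make_parent_pair(SyntheticFamilySpec(L=150, divergence=0.4, seed=31))
        cmap = make_random_contact_map(150, 200, seed=32)
        land = scan_double(fam.pair, cmap, "ABA", min_middle_fragment=20)
        rng = np.random.default_rng(33)
        cells = np.transpose(np.nonzero(land.admitted))
        for a, b in cells[rng.choice(len(cells), size=100, replace=False)]:
            scheme = CrossoverScheme("ABA", (int(a) + 1, int(b) + 1))
            assert land.energies[a, b] == disruption_energy(fam.pair, cmap, scheme)

    def test_tsv_long_form_orientation(self, toy):
        pair, cmap = toy
        land = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        lines = land.to_tsv_long().strip().splitlines()
        assert lines[0] == "x1\tx2\tE"
        x1, x2, e = (int(v) for v in lines[1].split("\t"))
        assert land.energy_at(x1, x2) == e and x1 < x2


class TestFindMinima:
    def _manual_landscape(self, energies, min_middle=1):
        energies = np.asarray(energies, dtype=np.int64)
        L = energies.shape[0]
        x1g, x2g = np.meshgrid(np.arange(1, L + 1), np.arange(1, L + 1), indexing="ij")
        admitted = (x2g <= L - 1) & (x2g - x1g >= min_middle)
        e = np.where(admitted, energies, 0)
        return DisruptionLandscape("ABA", e, admitted, min_middle, L,
                                   "a", "b", "tmpl", int(energies.max()))

    def test_unique_global_minimum_first(self, toy):
        pair, cmap = toy
        land = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        cands = find_minima(land, pair, neighborhood_radius=50, max_candidates=3)
        assert cands[0].energy == land.min_energy()

    def test_constant_landscape_deterministic_tie_order(self, toy):
        pair, _ = toy
        L = pair.n_columns
        land = self._manual_landscape(np.full((L, L), 7), min_middle=4)
        cands = find_minima(land, pair, neighborhood_radius=2, max_candidates=5)
        keys = [(c.energy, c.x1, c.x2) for c in cands]
        assert keys == sorted(keys) and len(cands) == 5
        assert keys[0] == (7, 1, 5)

    def test_matches_brute_force_neighborhood_check(self, toy):
        pair, cmap = toy
        land = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        r = 2
        expected = []
        cells = np.transpose(np.nonzero(land.admitted))
        for a, b in cells:
            e = land.energies[a, b]
            ok = True
            for a2, b2 in cells:
                if max(abs(a2 - a), abs(b2 - b)) <= r and land.energies[a2, b2] < e:
                    ok = False
                    break
            if ok:
                expected.append((int(e), int(a) + 1, int(b) + 1))
        expected = sorted(expected)[:10]
        got = [(c.energy, c.x1, c.x2) for c in find_minima(land, pair, r, 10)]
        assert got == expected

    def test_fragment_lengths_sum_to_chimera_length(self, toy):
        from schemarec.chimera import build_chimera

        pair, cmap = toy
        land = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        for cand in find_minima(land, pair, 2, 5):
            chim = build_chimera(pair, cand.scheme)
            assert cand.fragment_residue_lengths == chim.fragment_lengths
            assert sum(cand.fragment_residue_lengths) == len(chim)


class TestComposition:
    def test_region_inside_middle_fragment_is_pure_B(self, toy):
        pair, _ = toy
        scheme = CrossoverScheme("ABA", (3, 9))
        assert composition_stats(scheme, (5, 8), pair) == {"A": 0.0, "B": 1.0}

    def test_region_straddling_x2_half_half(self, toy):
        pair, _ = toy
        scheme = CrossoverScheme("ABA", (3, 9))
        comp = composition_stats(scheme, (8, 11), pair)  # cols 8,9 B; 10,11 A
        assert comp == {"A": 0.5, "B": 0.5}

    def test_empty_region_rejected(self, toy):
        pair, _ = toy
        with pytest.raises(ValueError):
            composition_stats(CrossoverScheme("ABA", (3, 9)), (8, 5), pair)

    def test_low_fraction_candidates_are_filtered_out(self, toy):
        """A candidate whose designated region is mostly the wrong parent is
        excluded from the report."""
        pair, cmap = toy
        land = scan_double(pair, cmap, "ABA", min_middle_fragment=2)
        cands = find_minima(land, pair, 2, 10)
        region = (4, 9)
        kept = filter_candidates_by_composition(cands, pair, region, "B", 0.8)
        for c in kept:
            assert c.composition["B"] >= 0.8
        dropped = [c for c in cands if (c.energy, c.x1, c.x2) not in
                   {(k.energy, k.x1, k.x2) for k in kept}]
        for c in dropped:
            assert composition_stats(c.scheme, region, pair)["B"] < 0.8
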