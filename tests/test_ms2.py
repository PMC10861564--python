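"""MS2 acyl-chain decomposition: slot assignment, pair checks, natoms."""

import numpy as np
import pytest

from isoscope.ms2 import (
    AcylChain,
    FragmentSpectrum,
    acyl_natom_equivalents,
    assign_fragments,
    average_scans,
    chain_fractions,
    even_isotopologue_series,
    summed_pair_check,
)
from isoscope.synthetic import emit_ms2_spectra

C181 = AcylChain.parse("18:1")
C182 = AcylChain.parse("18:2")
C183 = AcylChain.parse("18:3")


class TestChains:
    def test_parse_and_formula(self):
        assert C182.carboxylate_formula().to_string() == "C18H31O2"

    def test_oleate_anion_mass(self):
        # 18:1 carboxylate anion, a textbook lipidomics fragment
        assert C181.fragment_mz(0) == pytest.approx(281.2486, abs=5e-4)

    def test_saturation_vs_two_13c_gap(self):
        """18:1 M0 and 18:2 M2 differ by 2.01565 - 2.00671 = 0.00894 Da."""
        gap = C181.fragment_mz(0) - C182.fragment_mz(2)
        assert gap == pytest.approx(0.00894, abs=1e-5)

    def test_bad_chain_string(self):
        with pytest.raises(ValueError):
            AcylChain.parse("18.1")


class TestAssignment:
    def test_m0_and_m2_peaks_fill_two_slots(self):
        spec = FragmentSpectrum(
            "PC(36:4)", 2, 0,
            np.array([[C181.fragment_mz(0), 100.0], [C181.fragment_mz(2), 40.0]]),
        )
        slots, unassigned = assign_fragments(spec, [C181, C182, C183])
        assert slots == {("18:1", 0): 100.0, ("18:1", 2): 40.0}
        assert unassigned == []

    def test_saturation_vs_labeling_resolved_into_distinct_slots(self):
        spec = FragmentSpectrum(
            "PC(36:4)", 2, 0,
            np.array([[C182.fragment_mz(2), 70.0], [C181.fragment_mz(0), 30.0]]),
        )
        slots, _ = assign_fragments(spec, [C181, C182], mz_tol_ppm=10)
        assert slots[("18:2", 2)] == 70.0
        assert slots[("18:1", 0)] == 30.0

    def test_peak_outside_tolerance_unassigned(self):
        spec = FragmentSpectrum(
            "PC(36:4)", 0, 0, np.array([[C181.fragment_mz(0) + 0.05, 10.0]])
        )
        slots, unassigned = assign_fragments(spec, [C181], mz_tol_ppm=10)
        assert slots == {} and unassigned == [0]


class TestScanAveraging:
    def test_identical_scans_unchanged(self):
        m = {("18:1", 0): 5.0}
        assert average_scans([m] * 4) == m

    def test_mean_of_complementary_scans(self):
        a = {("18:1", 0): 0.0, ("18:1", 2): 2.0}
        b = {("18:1", 0): 2.0, ("18:1", 2): 0.0}
        assert average_scans([a, b]) == {("18:1", 0): 1.0, ("18:1", 2): 1.0}

    def test_permutation_invariant_with_noise(self):
        rng = np.random.default_rng(0)
        scans = [{("18:1", s): float(rng.random()) for s in range(3)} for _ in range(4)]
        assert average_scans(scans) == average_scans(scans[::-1])

    def test_noisy_scan_mean_within_clt_bound(self):
        rng = np.random.default_rng(1)
        true = 100.0
        n_scans, cv = 4, 0.05
        scans = [{("18:1", 0): true * rng.lognormal(-0.00125, 0.05)} for _ in range(n_scans)]
        mean = average_scans(scans)[("18:1", 0)]
        assert abs(mean - true) < 3 * true * cv / np.sqrt(n_scans)


class TestPairConsistency:
    def test_valid_2_4_split_at_m6(self):
        slots = {("18:1", 2): 10.0, ("18:3", 4): 10.0}
        rep = summed_pair_check(6, slots)
        assert rep.consistent and rep.inconsistent_fraction == 0.0

    def test_shift_beyond_precursor_flagged(self):
        slots = {("18:1", 7): 5.0, ("18:3", 0): 5.0}
        rep = summed_pair_check(6, slots)
        assert not rep.consistent
        assert rep.inconsistent_fraction == pytest.approx(0.5)

    def test_generator_only_emits_valid_pairs(self):
        pair_mids = {4: {(2, 2): 0.6, (4, 0): 0.4}}
        specs = emit_ms2_spectra("DAG(36:4)", pair_mids, [(1.0, (C181, C183))], scans=1)
        slots, _ = assign_fragments(specs[0], [C181, C183])
        assert summed_pair_check(4, slots).inconsistent_fraction == 0.0


class TestEvenSeries:
    def test_even_subset_renormalized(self):
        even, odd = even_isotopologue_series(np.array([0.5, 0.0, 0.5]))
        assert even == pytest.approx([0.5, 0.5])
        assert odd == 0.0

    def test_all_odd_vector_flagged(self):
        even, odd = even_isotopologue_series(np.array([0.0, 1.0, 0.0]))
        assert even.sum() == 0.0 and odd == 1.0

    def test_acetyl_unit_labeling_keeps_odd_fraction_tiny(self):
        # two-carbon increments put all true mass on even shifts
        v = np.array([0.4, 0.001, 0.3, 0.001, 0.298])
        _, odd = even_isotopologue_series(v)
        assert odd < 0.01


class TestAcylNatoms:
    def test_single_isomer_one_chain_carries_both_labels(self):
        slots = {2: {("18:1", 2): 50.0, ("18:3", 0): 50.0}}
        mid = np.array([0, 0, 1.0])
        res = acyl_natom_equivalents(slots, mid, pool_nmol=3.0, isomers=[(1.0, (C181, C183))])
        by_chain = {r.chain.name: r.natom_13C for r in res}
        assert by_chain["18:1"] == pytest.approx(6.0)
        assert by_chain["18:3"] == pytest.approx(0.0)

    def test_symmetric_labeling_splits_by_isomer_proportions(self):
        """Hand-computed 2-isomer fixture: 50/50 18:1/18:3 vs 18:2/18:2, every
        chain at mean shift 1 for the M2 precursor -> each isomer's chains get
        pool * proportion * multiplicity * 1 natoms."""
        slots = {
            2: {
                ("18:1", 1): 10.0,
                ("18:3", 1): 10.0,
                ("18:2", 1): 20.0,
            }
        }
        mid = np.array([0, 0, 1.0])
        isomers = [(0.5, (C181, C183)), (0.5, (C182, C182))]
        res = acyl_natom_equivalents(slots, mid, pool_nmol=4.0, isomers=isomers)
        by_chain = {r.chain.name: r.natom_13C for r in res}
        assert by_chain["18:1"] == pytest.approx(4.0 * 0.5 * 1)
        assert by_chain["18:3"] == pytest.approx(4.0 * 0.5 * 1)
        # 18:2 appears twice in its isomer: weight 0.5 * 2
        assert by_chain["18:2"] == pytest.approx(4.0 * 0.5 * 2 * 1)
        # total natoms equal pool * precursor shift
        assert sum(by_chain.values()) == pytest.approx(4.0 * 2)

    def test_unlabeled_lipid_gives_zero_natoms(self):
        slots = {0: {("18:1", 0): 10.0, ("18:3", 0): 10.0}}
        res = acyl_natom_equivalents(
            slots, np.array([1.0]), pool_nmol=5.0, isomers=[(1.0, (C181, C183))]
        )
        assert all(r.natom_13C == 0.0 for r in res)

    def test_total_chain_natoms_bounded_by_pool_times_shift(self):
        rng = np.random.default_rng(3)
        pair_mids = {
            4: {(i, 4 - i): p for i, p in zip(range(5), rng.dirichlet(np.ones(5)))}
        }
        specs = emit_ms2_spectra("PC(36:4)", pair_mids, [(1.0, (C181, C183))], scans=1)
        slots, _ = assign_fragments(specs[0], [C181, C183])
        res = acyl_natom_equivalents(
            {4: slots}, np.array([0, 0, 0, 0, 1.0]), 2.0, [(1.0, (C181, C183))]
        )
        assert sum(r.natom_13C for r in res) <= 2.0 * 4 + 1e-9


class TestRoundTrip:
    def test_noiseless_spectra_recover_chain_mids_exactly(self):
        """Generator -> assignment -> chain fractions is the identity when the
        two chains' slot masses do not collide."""
        pair_mids = {
            2: {(2, 0): 0.25, (0, 2): 0.75},
            4: {(2, 2): 1.0},
        }
        isomers = [(1.0, (C181, C183))]
        specs = emit_ms2_spectra("PC(36:4)", pair_mids, isomers, scans=4, noise_cv=0.0)
        for k, expect_a, expect_b in [
            (2, {0: 0.75, 2: 0.25}, {0: 0.25, 2: 0.75}),
            (4, {2: 1.0}, {2: 1.0}),
        ]:
            per_scan = [
                assign_fragments(s, [C181, C183])[0]
                for s in specs
                if s.precursor_shift == k
            ]
            slots = average_scans(per_scan)
            fa = chain_fractions(slots, C181)
            fb = chain_fractions(slots, C183)
            for shift, val in expect_a.items():
                assert fa[shift] == pytest.approx(val, abs=1e-12)
            for shift, val in expect_b.items():
                assert fb[shift] == pytest.approx(val, abs=1e-12)

    def test_inconsistent_pair_spec_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            emit_ms2_spectra("X", {2: {(2, 1): 1.0}}, [(1.0, (C181, C183))])
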