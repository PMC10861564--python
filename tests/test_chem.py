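"""Formula parsing, exact masses, grid enumeration and projections."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoscope.chem import (
    ADDUCTS,
    TRACER_13C,
    TRACER_15N,
    AdductSpec,
    MolecularFormula,
    enumerate_isotopologues,
    is_resolved,
    isotopologue_mz,
    monoisotopic_mass,
    parse_formula,
    project_marginal,
    project_nominal,
    resolving_power_required,
)

DUAL = [TRACER_13C, TRACER_15N]


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C5H10N2O3", {"C": 5, "H": 10, "N": 2, "O": 3}),
        ("C44H80NO8P", {"C": 44, "H": 80, "N": 1, "O": 8, "P": 1}),
        ("H", {"H": 1}),
        ("C2H3O2", {"C": 2, "H": 3, "O": 2}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).counts == expected


def test_parse_formula_round_trips_to_canonical_string():
    f = parse_formula("C5H10N2O3")
    assert parse_formula(f.to_string()).counts == f.counts


@pytest.mark.parametrize("bad", ["", "  ", "Xx3", "C-5", "5C", "C5H10Q"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_formula(bad)


def test_formula_rejects_negative_counts():
    with pytest.raises(ValueError):
        MolecularFormula({"C": -1})


@pytest.mark.parametrize(
    "counts,expected,tol",
    [
        ({"C": 1}, 12.0, 1e-9),
        ({"H": 2}, 2.0156501, 1e-6),
        ({"C": 44, "H": 80, "N": 1, "O": 8, "P": 1}, 781.5622, 5e-4),
    ],
)
def test_monoisotopic_mass(counts, expected, tol):
    assert monoisotopic_mass(MolecularFormula(counts)) == pytest.approx(expected, abs=tol)


def test_monoisotopic_mass_cross_check_against_pyteomics():
    """Independent oracle: pyteomics' own isotope tables for the same formulae."""
    pyteomics_mass = pytest.importorskip("pyteomics.mass")
    for text in ("C5H10N2O3", "C44H80NO8P", "C46H83NO10P", "C18H33O2"):
        ours = monoisotopic_mass(parse_formula(text))
        theirs = pyteomics_mass.calculate_mass(formula=text)
        assert ours == pytest.approx(theirs, abs=5e-4)


class TestEnumeration:
    def test_glutamine_dual_grid_has_18_isotopologues(self, glutamine_grid):
        assert len(glutamine_grid) == 18

    def test_glutamine_13c_only_has_6(self):
        g = enumerate_isotopologues(parse_formula("C5H10N2O3"), [TRACER_13C])
        assert len(g) == 6
        assert g.indices == [(0,), (1,), (2,), (3,), (4,), (5,)]

    def test_no_tracers_gives_single_empty_index(self):
        g = enumerate_isotopologues(parse_formula("C5H10N2O3"), [])
        assert g.indices == [()]

    def test_duplicate_tracer_element_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_isotopologues(parse_formula("C5H10N2O3"), [TRACER_13C, TRACER_13C])

    def test_grid_mz_strictly_increasing_along_sorted_mass_shift(self, glutamine_grid):
        mz = np.sort(glutamine_grid.theoretical_mz)
        assert np.all(np.diff(mz) > 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        nc=st.integers(0, 12),
        nn=st.integers(0, 4),
        nh=st.integers(1, 20),
    )
    def test_grid_size_is_product_of_ne_plus_one(self, nc, nn, nh):
        f = MolecularFormula({"C": nc, "N": nn, "H": nh})
        g = enumerate_isotopologues(f, DUAL, ADDUCTS["[M]"])
        assert len(g) == (nc + 1) * (nn + 1)


class TestIsotopologueMz:
    PC364 = parse_formula("C44H80NO8P")
    ACETATE = ADDUCTS["[M+CH3COO]-"]

    def test_pc364_acetate_m0(self):
        mz = isotopologue_mz(self.PC364, self.ACETATE, (0,), [TRACER_13C])
        assert mz == pytest.approx(840.5760, abs=5e-4)

    def test_pc364_acetate_m6(self):
        mz = isotopologue_mz(self.PC364, self.ACETATE, (6,), [TRACER_13C])
        assert mz == pytest.approx(846.5961, abs=5e-4)

    def test_two_13c_shift_is_2_00671(self):
        m0 = isotopologue_mz(self.PC364, self.ACETATE, (0,), [TRACER_13C])
        m2 = isotopologue_mz(self.PC364, self.ACETATE, (2,), [TRACER_13C])
        assert m2 - m0 == pytest.approx(2.00671, abs=5e-5)

    def test_shift_is_exact_sum_of_heavy_masses(self, glutamine_grid):
        g = glutamine_grid
        m0 = isotopologue_mz(g.neutral, g.adduct, (0, 0), g.tracers)
        for ix in g.indices:
            expected = sum(i * t.heavy_isotope_mass_shift for i, t in zip(ix, g.tracers))
            got = isotopologue_mz(g.neutral, g.adduct, ix, g.tracers) - m0
            assert got == pytest.approx(expected, abs=1e-12)

    def test_heavy_count_beyond_neutral_atoms_rejected(self):
        # adduct carbons are unlabeled mobile-phase carbon: only 44 labelable
        with pytest.raises(ValueError):
            isotopologue_mz(self.PC364, self.ACETATE, (45,), [TRACER_13C])

    def test_positive_mode_electron_correction_sign(self):
        f = parse_formula("C6H12O6")
        plus = isotopologue_mz(f, ADDUCTS["[M+H]+"], (0,), [TRACER_13C])
        minus = isotopologue_mz(f, ADDUCTS["[M-H]-"], (0,), [TRACER_13C])
        # [M+H]+ - [M-H]- = 2 protons (2 * 1.00728) exactly
        assert plus - minus == pytest.approx(2 * (1.00782503 - 0.00054858), abs=1e-9)


class TestProjections:
    def test_uniform_dual_grid_projects_to_lattice_counts(self, glutamine_grid):
        vals = np.full(18, 1 / 18)
        nom = project_nominal(glutamine_grid, vals)
        assert nom == pytest.approx(np.array([1, 2, 3, 3, 3, 3, 2, 1]) / 18)

    def test_nominal_channels_count_is_8(self, glutamine_grid):
        assert len(project_nominal(glutamine_grid, np.ones(18))) == 8

    def test_marginals_have_6_and_3_channels(self, glutamine_grid):
        vals = np.random.default_rng(1).random(18)
        c = project_marginal(glutamine_grid, vals, TRACER_13C)
        n = project_marginal(glutamine_grid, vals, TRACER_15N)
        assert len(c) == 6 and len(n) == 3

    def test_projections_conserve_total_abundance(self, glutamine_grid):
        vals = np.random.default_rng(2).random(18)
        for proj in (
            project_nominal(glutamine_grid, vals),
            project_marginal(glutamine_grid, vals, TRACER_13C),
            project_marginal(glutamine_grid, vals, TRACER_15N),
        ):
            assert proj.sum() == pytest.approx(vals.sum(), rel=1e-14)

    def test_delta_at_origin_projects_to_delta(self, glutamine_grid):
        vals = {(0, 0): 1.0}
        nom = project_nominal(glutamine_grid, vals)
        assert nom[0] == 1.0 and nom[1:].sum() == 0.0

    def test_delta_at_2_1_marginals(self, glutamine_grid):
        vals = {(2, 1): 1.0}
        assert project_marginal(glutamine_grid, vals, TRACER_13C)[2] == 1.0
        assert project_marginal(glutamine_grid, vals, TRACER_15N)[1] == 1.0

    def test_product_form_grid_factorizes_into_marginals(self, glutamine_grid):
        """Independence case: marginals of an outer product recover the factors."""
        rng = np.random.default_rng(3)
        pc = rng.random(6)
        pc /= pc.sum()
        pn = rng.random(3)
        pn /= pn.sum()
        vals = np.array([pc[i] * pn[j] for (i, j) in glutamine_grid.indices])
        assert project_marginal(glutamine_grid, vals, TRACER_13C) == pytest.approx(pc)
        assert project_marginal(glutamine_grid, vals, TRACER_15N) == pytest.approx(pn)


class TestResolution:
    def test_saturation_vs_two_13c_needs_95k_at_846(self):
        delta = 2.01565 - 2.00671
        assert resolving_power_required(846.60, delta) == pytest.approx(94698, rel=1e-3)

    def test_trivial_quotient(self):
        assert resolving_power_required(100, 1) == 100

    def test_rounded_delta_at_840(self):
        assert resolving_power_required(840, 0.009) == pytest.approx(93333, rel=1e-3)

    def test_separation_decision_at_stated_resolution(self):
        # 0.00894 Da at m/z 846.6: FWHM at R=120k is 0.00706 -> separated
        assert is_resolved(846.6, 0.00894, 120_000)
        # at R=35k the FWHM is 0.0242 -> not separated
        assert not is_resolved(846.6, 0.00894, 35_000)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            resolving_power_required(0, 1)
        with pytest.raises(ValueError):
            resolving_power_required(100, 0)
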