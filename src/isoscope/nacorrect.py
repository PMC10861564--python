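"""Natural-abundance (NA) correction for single- and dual-tracer HRMS data.

Measured isotopologue intensities mix tracer-derived labeling with naturally
occurring heavy isotopes (1.07% 13C, 0.36% 15N, ...).  The forward model is
a correction matrix C whose column j is the theoretical measured
distribution of a molecule whose true labeled state is grid index j; it is
built by convolving, atom by atom, the natural isotope distribution of
every non-tracer position of the adduct ion (adduct atoms are real atoms in
the ion and convolve too, but are never tracer-enriched) and the tracer
purity on labeled positions.  Correction solves measured = C @ true by
non-negative least squares, which stays stable on noisy, truncated data
where a direct inverse would produce negative abundances.

Two channel models are supported:

* ``resolved`` — high-resolution: an isotope species contributes to a grid
  channel only when its exact mass falls within half the instrument FWHM of
  that channel; species falling between channels drop out entirely.  At
  Orbitrap-class resolution this keeps e.g. natural 15N off the 13C axis.
* ``nominal`` — unit-mass: all species of equal total neutron shift merge,
  and the measured vector is indexed by nominal shift M0..Mn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import scipy.optimize

from .chem import (
    ELECTRON_MASS,
    ISOTOPE_MASS_SHIFT,
    AdductSpec,
    IsotopologueGrid,
    MolecularFormula,
    TracerSpec,
    ion_formula,
)

__all__ = [
    "IsotopeAbundanceTable",
    "DEFAULT_ABUNDANCES",
    "CorrectionMatrix",
    "build_correction_matrix",
    "convolve_mid",
    "correct_mid",
]

# (neutron shift, exact mass shift in Da, natural fraction) per element.
# Light isotope fraction is the complement; masses are heavy - light.
_NATURAL_HEAVY: Dict[str, List[Tuple[int, float, float]]] = {
    "C": [(1, ISOTOPE_MASS_SHIFT["13C"], 0.0107)],
    "H": [(1, ISOTOPE_MASS_SHIFT["2H"], 0.000115)],
    "N": [(1, ISOTOPE_MASS_SHIFT["15N"], 0.00364)],
    "O": [
        (1, 16.99913176 - 15.99491462, 0.00038),
        (2, ISOTOPE_MASS_SHIFT["18O"], 0.00205),
    ],
    "S": [
        (1, 32.97145876 - 31.97207117, 0.0075),
        (2, 33.96786690 - 31.97207117, 0.0421),
    ],
    "P": [],
    "Na": [],
    "K": [(1, 39.96399848 - 38.96370668, 0.000117), (2, 40.96182576 - 38.96370668, 0.067302)],
    "Cl": [(2, 36.96590259 - 34.96885268, 0.2424)],
    "D": [],
}


@dataclass
class IsotopeAbundanceTable:
    """Natural isotope inventory per element plus tracer purities.

    ``heavy[el]`` lists (neutron shift, exact mass shift, fraction) for each
    naturally occurring heavy isotope of ``el``; the light-isotope fraction
    is 1 minus their sum.
    """

    heavy: Mapping[str, List[Tuple[int, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _NATURAL_HEAVY.items()}
    )

    def __post_init__(self):
        for el, isos in self.heavy.items():
            total = sum(f for _, _, f in isos)
            if not (0.0 <= total < 1.0 + 1e-9):
                raise ValueError(f"heavy fractions of {el} sum to {total}")
            for _, _, f in isos:
                if not (0.0 <= f <= 1.0):
                    raise ValueError(f"fraction outside [0,1] for {el}")

    def for_element(self, el: str) -> List[Tuple[int, float, float]]:
        if el not in self.heavy:
            raise KeyError(f"no natural-abundance data for element {el!r}")
        return list(self.heavy[el])

    def zeroed(self) -> "IsotopeAbundanceTable":
        """Copy with all natural heavy fractions set to zero (testing aid)."""
        return IsotopeAbundanceTable({el: [] for el in self.heavy})


DEFAULT_ABUNDANCES = IsotopeAbundanceTable()


@dataclass
class CorrectionMatrix:
    """Forward NA model: measured = matrix @ true over the isotopologue grid."""

    matrix: np.ndarray  # (n_measured_channels, n_grid_states)
    mode: str  # "nominal" | "resolved"
    grid: IsotopologueGrid
    channel_labels: List[str]

    def __post_init__(self):
        if np.any(self.matrix < -1e-12):
            raise ValueError("correction matrix entries must be non-negative")
        colsum = self.matrix.sum(axis=0)
        if np.any(colsum > 1.0 + 1e-9):
            raise ValueError("correction matrix column mass exceeds 1")


# Species with probability below this are pruned during convolution.
_PRUNE = 1e-12
# Exact-mass bin width (Da) used to merge numerically identical species.
_MASS_BIN = 1e-7


def _convolve_atoms(
    dist: Dict[Tuple[int, int], float],
    n_atoms: int,
    isotopes: List[Tuple[int, float, float]],
    max_shift: int,
) -> Dict[Tuple[int, int], float]:
    """Convolve ``n_atoms`` i.i.d. atoms onto a (neutron shift, mass bin) pmf."""
    if n_atoms == 0 or not isotopes:
        return dist
    light_p = 1.0 - sum(f for _, _, f in isotopes)
    atom = [(0, 0.0, light_p)] + list(isotopes)
    for _ in range(n_atoms):
        new: Dict[Tuple[int, int], float] = {}
        for (ns, mb), p in dist.items():
            for dns, dm, f in atom:
                if f == 0.0:
                    continue
                ns2 = ns + dns
                if ns2 > max_shift:
                    continue
                q = p * f
                if q < _PRUNE:
                    continue
                key = (ns2, mb + round(dm / _MASS_BIN))
                new[key] = new.get(key, 0.0) + q
        dist = new
    return dist


def _species_distribution(
    ion: MolecularFormula,
    tracers: Sequence[TracerSpec],
    labeled_counts: Sequence[int],
    tracer_atoms_available: Sequence[int],
    abundances: IsotopeAbundanceTable,
    max_shift: int,
) -> Dict[Tuple[int, int], float]:
    """Isotope species pmf of an ion whose true labeled state is given.

    Tracer-labeled positions register heavy with probability = purity and
    light otherwise; all remaining atoms follow natural abundance.
    """
    dist: Dict[Tuple[int, int], float] = {(0, 0): 1.0}
    tracer_elements = {t.element: i for i, t in enumerate(tracers)}
    for el, n in ion.counts.items():
        natural_n = n
        if el in tracer_elements:
            t_i = tracer_elements[el]
            # only the neutral compound's atoms are labelable
            natural_n = n - labeled_counts[t_i]
        dist = _convolve_atoms(dist, natural_n, abundances.for_element(el), max_shift)
    # tracer purity: binomial over labeled positions
    for t_i, tracer in enumerate(tracers):
        k = labeled_counts[t_i]
        if k == 0:
            continue
        pur = tracer.purity
        iso = [(1, tracer.heavy_isotope_mass_shift, pur)]
        dist = _convolve_atoms(dist, k, iso, max_shift)
    return dist


def build_correction_matrix(
    grid: IsotopologueGrid,
    abundances: IsotopeAbundanceTable = DEFAULT_ABUNDANCES,
    mode: str = "resolved",
    instrument_resolution: float = 140_000.0,
) -> CorrectionMatrix:
    """Build the forward NA-convolution matrix for a compound's grid.

    In ``resolved`` mode the measured channels are the grid's own exact-mass
    channels; a species lands in the channel whose theoretical mass shift is
    nearest, provided the distance is within half the FWHM (= m/z / R) —
    otherwise it drops out of the grid.  In ``nominal`` mode channels are
    total neutron shifts 0..sum(N_e).
    """
    if mode not in ("nominal", "resolved"):
        raise ValueError(f"invalid mode {mode!r}")
    ion = ion_formula(grid.neutral, grid.adduct)
    for el in ion.counts:
        abundances.for_element(el)  # raises KeyError if missing

    n_states = len(grid)
    max_shift = grid.max_nominal_shift + 2  # room for natural heavies beyond grid

    if mode == "nominal":
        n_channels = grid.max_nominal_shift + 1
        labels = [f"M{k}" for k in range(n_channels)]
    else:
        n_channels = n_states
        labels = ["M(" + ",".join(map(str, ix)) + ")" for ix in grid.indices]
        channel_mass = np.array(
            [
                sum(i * t.heavy_isotope_mass_shift for i, t in zip(ix, grid.tracers))
                for ix in grid.indices
            ]
        )
        m0_mz = float(grid.theoretical_mz[grid.index_of((0,) * len(grid.tracers))])
        half_fwhm = 0.5 * m0_mz / instrument_resolution * abs(grid.adduct.charge)

    C = np.zeros((n_channels, n_states))
    avail = grid.n_per_tracer
    for j, state in enumerate(grid.indices):
        dist = _species_distribution(
            ion, grid.tracers, state, avail, abundances, max_shift
        )
        for (ns, mb), p in dist.items():
            if mode == "nominal":
                if ns <= grid.max_nominal_shift:
                    C[ns, j] += p
            else:
                dm = mb * _MASS_BIN
                k = int(np.argmin(np.abs(channel_mass - dm)))
                if abs(channel_mass[k] - dm) <= half_fwhm:
                    C[k, j] += p
    return CorrectionMatrix(matrix=C, mode=mode, grid=grid, channel_labels=labels)


def convolve_mid(correction: CorrectionMatrix, true_mid: np.ndarray) -> np.ndarray:
    """Forward model: the measured distribution of a known true MID."""
    true_mid = np.asarray(true_mid, dtype=float)
    return correction.matrix @ true_mid


def correct_mid(
    measured: np.ndarray, correction: CorrectionMatrix
) -> Tuple[np.ndarray, float]:
    """Recover the tracer-derived MID from a measured intensity vector.

    Solves ``measured ~= C @ true`` by non-negative least squares and
    renormalizes the solution to sum 1.  Returns (corrected MID, residual
    2-norm of the NNLS fit on the sum-normalized measured vector).
    """
    measured = np.asarray(measured, dtype=float)
    if measured.shape != (correction.matrix.shape[0],):
        raise ValueError(
            f"measured length {measured.shape} != channels {correction.matrix.shape[0]}"
        )
    if np.any(measured < 0):
        raise ValueError("measured intensities must be non-negative")
    total = measured.sum()
    if total == 0:
        raise ValueError("all-zero measured vector")
    y = measured / total
    x, rnorm = scipy.optimize.nnls(correction.matrix, y)
    s = x.sum()
    if s == 0:
        raise ValueError("NNLS returned the zero vector")
    return x / s, float(rnorm)
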