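"""Molecular formulae, exact masses and multivariate isotopologue grids.

The central object is the :class:`IsotopologueGrid`: for a compound traced
with one or more heavy isotopes (e.g. simultaneous 13C and 15N), the set of
distinguishable labeled species is the Cartesian product of per-tracer heavy
atom counts.  With ``N_e`` labelable atoms of each traced element the grid
holds ``prod(N_e + 1)`` isotopologues — glutamine (C5, N2) traced with 13C
and 15N gives 6 x 3 = 18 species.  A high-resolution instrument separates
these by exact mass even when their nominal (unit) mass shifts coincide;
projections back onto nominal shift or onto a single tracer axis reproduce
the channels a lower-resolution or single-tracer experiment would measure.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "ISOTOPE_MASS_SHIFT",
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "TracerSpec",
    "TRACER_13C",
    "TRACER_15N",
    "TRACER_2H",
    "AdductSpec",
    "ADDUCTS",
    "IsotopologueGrid",
    "enumerate_isotopologues",
    "ion_formula",
    "isotopologue_mz",
    "project_nominal",
    "project_marginal",
    "resolving_power_required",
    "is_resolved",
]

# Exact masses of the lightest (monoisotopic) isotope per element, Da.
# NIST/CODATA values; 12C is exactly 12 by definition.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376163,
    "S": 31.97207117,
    "Na": 22.98976928,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "D": 2.01410178,  # deuterium as an explicit element (synthetic standards)
}

# Exact mass difference heavy - light for the common single-neutron tracers.
ISOTOPE_MASS_SHIFT: Dict[str, float] = {
    "13C": 13.00335484 - 12.0,            # 1.00335484
    "15N": 15.00010897 - 14.00307401,     # 0.99703496
    "2H": 2.01410178 - 1.00782503,        # 1.00627675
    "18O": 17.99915961 - 15.99491462,     # 2.00424499
}

ELECTRON_MASS = 0.00054858

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map for a neutral molecule or an adduct ion."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def add_delta(self, delta: Mapping[str, int]) -> "MolecularFormula":
        """Apply a signed element delta (adduct gain/loss); counts must stay >= 0."""
        merged = dict(self.counts)
        for el, n in delta.items():
            new = merged.get(el, 0) + n
            if new < 0:
                raise ValueError(f"adduct removes more {el} than present")
            merged[el] = new
        return MolecularFormula(merged)

    def to_string(self) -> str:
        """Canonical Hill notation (C first, H second, rest alphabetical)."""
        els = sorted(self.counts)
        ordered = [e for e in ("C", "H") if e in self.counts]
        ordered += [e for e in els if e not in ("C", "H")]
        return "".join(f"{e}{self.counts[e] if self.counts[e] != 1 else ''}" for e in ordered)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __repr__(self):
        return f"MolecularFormula({self.to_string()!r})"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation-like formula string, e.g. ``"C5H10N2O3"``.

    Implicit count 1 is accepted (``"H"`` -> {H: 1}); unknown element
    symbols and malformed input raise ``ValueError``.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Sum of lightest-isotope exact masses, Da."""
    if not formula.counts:
        raise ValueError("empty formula")
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items()))


@dataclass(frozen=True)
class TracerSpec:
    """An enriched heavy isotope used as a tracer.

    ``heavy_isotope_mass_shift`` is the exact heavy-light mass difference in
    Da; ``purity`` is the isotopic enrichment of the tracer substrate (a
    heavy position registers light with probability 1 - purity).
    """

    element: str
    heavy_isotope_mass_shift: float
    label: str
    purity: float = 1.0

    def __post_init__(self):
        if self.element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown tracer element {self.element!r}")
        if not (0.0 < self.heavy_isotope_mass_shift < 2.1):
            raise ValueError("mass shift outside single-neutron tracer range")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")


TRACER_13C = TracerSpec("C", ISOTOPE_MASS_SHIFT["13C"], "13C")
TRACER_15N = TracerSpec("N", ISOTOPE_MASS_SHIFT["15N"], "15N")
TRACER_2H = TracerSpec("H", ISOTOPE_MASS_SHIFT["2H"], "2H")


@dataclass(frozen=True)
class AdductSpec:
    """The charged modification turning a neutral molecule into the measured ion.

    ``formula_delta`` is a signed element-count change (e.g. {H: -1} for
    deprotonation); electrons are accounted from ``charge``.
    """

    name: str
    formula_delta: Mapping[str, int]
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}, +1),
    "[M-H]-": AdductSpec("[M-H]-", {"H": -1}, -1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", {"N": 1, "H": 4}, +1),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", {"C": 1, "H": 1, "O": 2}, -1),
    "[M+CH3COO]-": AdductSpec("[M+CH3COO]-", {"C": 2, "H": 3, "O": 2}, -1),
    "[M]": AdductSpec("[M]", {}, +1),  # bare cation fallback
}


def ion_formula(neutral: MolecularFormula, adduct: AdductSpec) -> MolecularFormula:
    """Elemental composition of the adduct ion."""
    return neutral.add_delta(adduct.formula_delta)


@dataclass
class IsotopologueGrid:
    """All multivariate isotopologues of one compound under a tracer set.

    ``indices`` is the full lexicographic list of per-tracer heavy-atom
    count tuples; ``theoretical_mz`` the matching ion m/z values.
    """

    compound: str
    neutral: MolecularFormula
    adduct: AdductSpec
    tracers: List[TracerSpec]
    indices: List[Tuple[int, ...]]
    theoretical_mz: np.ndarray

    @property
    def n_per_tracer(self) -> Tuple[int, ...]:
        return tuple(self.neutral[t.element] for t in self.tracers)

    @property
    def max_nominal_shift(self) -> int:
        return sum(self.n_per_tracer)

    def index_of(self, idx: Tuple[int, ...]) -> int:
        return self.indices.index(tuple(idx))

    def nominal_shifts(self) -> np.ndarray:
        return np.array([sum(i) for i in self.indices], dtype=int)

    def __len__(self):
        return len(self.indices)


def enumerate_isotopologues(
    formula: MolecularFormula,
    tracers: Sequence[TracerSpec],
    adduct: AdductSpec = ADDUCTS["[M-H]-"],
    compound: str = "",
) -> IsotopologueGrid:
    """Build the full multivariate isotopologue grid for a compound.

    The grid has exactly ``prod(N_e + 1)`` entries where ``N_e`` is the
    number of atoms of each tracer's element in the *neutral* molecule
    (adduct atoms come from unlabeled mobile phase and are never traced).
    Indices are in lexicographic order following the tracer list order.
    """
    elements = [t.element for t in tracers]
    if len(set(elements)) != len(elements):
        raise ValueError("duplicate tracer element")
    ns = [formula[t.element] for t in tracers]
    indices = [tuple(ix) for ix in itertools.product(*(range(n + 1) for n in ns))]
    mzs = np.array(
        [isotopologue_mz(formula, adduct, ix, tracers) for ix in indices]
    )
    return IsotopologueGrid(
        compound=compound,
        neutral=formula,
        adduct=adduct,
        tracers=list(tracers),
        indices=indices,
        theoretical_mz=mzs,
    )


def isotopologue_mz(
    neutral: MolecularFormula,
    adduct: AdductSpec,
    index: Sequence[int],
    tracers: Sequence[TracerSpec],
) -> float:
    """Theoretical m/z of one isotopologue of the adduct ion.

    Electron mass is added per negative charge and removed per positive
    charge, so singly charged anion masses match high-accuracy instrument
    readouts to the fourth decimal.
    """
    index = tuple(int(i) for i in index)
    if len(index) != len(tracers):
        raise ValueError("index length must match tracer list")
    for i, t in zip(index, tracers):
        if i < 0 or i > neutral[t.element]:
            raise ValueError(
                f"heavy count {i} exceeds {t.element} atoms of the neutral compound"
            )
    ion = ion_formula(neutral, adduct)
    mass = monoisotopic_mass(ion)
    mass += sum(i * t.heavy_isotope_mass_shift for i, t in zip(index, tracers))
    mass -= adduct.charge * ELECTRON_MASS
    return mass / abs(adduct.charge)


def _as_grid_array(grid: IsotopologueGrid, values) -> np.ndarray:
    if isinstance(values, Mapping):
        arr = np.zeros(len(grid))
        for ix, v in values.items():
            arr[grid.index_of(tuple(ix))] = v
        return arr
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(grid),):
        raise ValueError(f"expected {len(grid)} grid values, got {arr.shape}")
    return arr


def project_nominal(grid: IsotopologueGrid, values) -> np.ndarray:
    """Sum grid abundances by total nominal mass shift k = sum of heavy counts.

    Returns a vector of length ``sum(N_e) + 1`` (the channels a unit-mass
    resolution instrument distinguishes).  Total abundance is conserved.
    """
    arr = _as_grid_array(grid, values)
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    out = np.zeros(grid.max_nominal_shift + 1)
    np.add.at(out, grid.nominal_shifts(), arr)
    return out


def project_marginal(grid: IsotopologueGrid, values, tracer: TracerSpec) -> np.ndarray:
    """Marginal abundance over one tracer axis (sum over all other tracers)."""
    arr = _as_grid_array(grid, values)
    try:
        axis = grid.tracers.index(tracer)
    except ValueError:
        try:
            axis = [t.label for t in grid.tracers].index(
                tracer.label if isinstance(tracer, TracerSpec) else tracer
            )
        except ValueError:
            raise ValueError(f"tracer {tracer!r} not in grid") from None
    n = grid.n_per_tracer[axis]
    out = np.zeros(n + 1)
    for ix, v in zip(grid.indices, arr):
        out[ix[axis]] += v
    return out


def resolving_power_required(mz: float, delta_mz: float) -> float:
    """Resolution R = m / delta-m (FWHM convention) needed to separate a pair."""
    if mz <= 0 or delta_mz <= 0:
        raise ValueError("mz and delta_mz must be positive")
    return mz / delta_mz


def is_resolved(
    mz: float,
    delta_mz: float,
    instrument_resolution: float,
    reference_mz: float | None = None,
    factor: float = 1.0,
) -> bool:
    """Does a stated instrument resolution separate a mass pair?

    FWHM at the pair's m/z is ``mz / R``; the pair counts as separated when
    ``|delta_mz| >= factor * FWHM``.  ``reference_mz`` is accepted for
    instruments quoting R at a fixed m/z; the FWHM is then scaled from the
    reference assuming constant R.
    """
    if instrument_resolution <= 0:
        raise ValueError("resolution must be positive")
    fwhm = mz / instrument_resolution
    return abs(delta_mz) >= factor * fwhm
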