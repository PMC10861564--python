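"""Acyl-chain labeling of two-chain lipids from precursor-isotopologue MS2.

Fragmenting each precursor isotopologue Mk of a diacyl lipid (PC, DAG)
releases the acyl chains as carboxylate anions RCOO-.  At high resolution
a +2 13C shift (+2.00671 Da) is distinguishable from one fewer double bond
(+2.01565 Da), so fragment peaks can be binned into (chain, 13C-shift)
slots.  The labels on the two chains of an Mk precursor must arrive in
summed pairs (i, k - i) — M0/M6, M1/M5, ... for M6 — which gives a built-in
consistency check.  Chain-level mean label counts, weighted by the
precursor MID, lipid pool size and the proportions of acyl-chain isomers
(e.g. 36:4 as 18:1/18:3 vs 18:2/18:2), yield natom equivalents of 13C per
chain.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    ELECTRON_MASS,
    ISOTOPE_MASS_SHIFT,
    MolecularFormula,
    monoisotopic_mass,
)

__all__ = [
    "AcylChain",
    "FragmentSpectrum",
    "AcylLabeling",
    "assign_fragments",
    "average_scans",
    "summed_pair_check",
    "even_isotopologue_series",
    "chain_fractions",
    "acyl_natom_equivalents",
]

_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")
_SHIFT_13C = ISOTOPE_MASS_SHIFT["13C"]


@dataclass(frozen=True)
class AcylChain:
    """A fatty acyl chain, e.g. 18:2 (carbons:double bonds)."""

    carbons: int
    double_bonds: int

    @classmethod
    def parse(cls, text: str) -> "AcylChain":
        m = _CHAIN_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse acyl chain {text!r} (want 'C:D')")
        return cls(int(m.group(1)), int(m.group(2)))

    @property
    def name(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    def carboxylate_formula(self) -> MolecularFormula:
        """RCOO- composition: CnH(2n-2d-1)O2 for an n:d chain."""
        h = 2 * self.carbons - 2 * self.double_bonds - 1
        return MolecularFormula({"C": self.carbons, "H": h, "O": 2})

    def fragment_mz(self, shift: int = 0) -> float:
        """m/z of the carboxylate anion carrying ``shift`` 13C atoms."""
        if not (0 <= shift <= self.carbons):
            raise ValueError(f"shift {shift} outside 0..{self.carbons}")
        return (
            monoisotopic_mass(self.carboxylate_formula())
            + ELECTRON_MASS
            + shift * _SHIFT_13C
        )

    def __str__(self):
        return self.name


@dataclass
class FragmentSpectrum:
    """One MS2 scan of one precursor isotopologue."""

    lipid: str
    precursor_shift: int  # nominal 13C shift of the isolated precursor
    scan: int
    peaks: np.ndarray  # (n, 2): m/z, intensity

    def __post_init__(self):
        p = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if np.any(p[:, 1] < 0):
            raise ValueError("negative fragment intensity")
        self.peaks = p[np.argsort(p[:, 0])]


@dataclass
class AcylLabeling:
    """Per-chain labeling result for one lipid."""

    lipid: str
    chain: AcylChain
    fractions: np.ndarray  # over chain-carbon shifts, sums to 1 when observed
    natom_13C: float


SlotKey = Tuple[str, int]  # (chain name, 13C shift)


def assign_fragments(
    spectrum: FragmentSpectrum,
    chains: Sequence[AcylChain],
    mz_tol_ppm: float = 10.0,
    max_shift: Optional[int] = None,
) -> Tuple[Dict[SlotKey, float], List[int]]:
    """Bin fragment peaks into (chain, 13C shift) slots by nearest exact mass.

    Each peak goes to at most one slot, within the ppm tolerance of its
    theoretical carboxylate m/z; slots for different chains sit 0.00894 Da
    apart per saturation step and are separable at the tolerances of
    high-resolution MS2.  Returns the slot intensity map and the row
    indices of unassigned peaks.
    """
    slots: List[Tuple[SlotKey, float]] = []
    for ch in chains:
        top = ch.carbons if max_shift is None else min(ch.carbons, max_shift)
        for s in range(top + 1):
            slots.append(((ch.name, s), ch.fragment_mz(s)))
    slot_mz = np.array([mz for _, mz in slots])
    out: Dict[SlotKey, float] = {}
    unassigned: List[int] = []
    for i, (mz, inten) in enumerate(spectrum.peaks):
        j = int(np.argmin(np.abs(slot_mz - mz)))
        ppm = abs(mz - slot_mz[j]) / slot_mz[j] * 1e6
        if ppm <= mz_tol_ppm:
            key = slots[j][0]
            out[key] = out.get(key, 0.0) + float(inten)
        else:
            unassigned.append(i)
    return out, unassigned


def average_scans(slot_maps: Sequence[Mapping[SlotKey, float]]) -> Dict[SlotKey, float]:
    """Arithmetic mean of slot intensities over repeated scans.

    Slots absent from a scan count as zero, so the mean is over the full
    scan count and is permutation-invariant.
    """
    if not slot_maps:
        raise ValueError("need at least one scan")
    keys = set()
    for m in slot_maps:
        keys |= set(m)
    n = len(slot_maps)
    # fsum: exact accumulation makes the mean independent of scan order
    return {k: math.fsum(m.get(k, 0.0) for m in slot_maps) / n for k in sorted(keys)}


@dataclass
class PairConsistency:
    precursor_shift: int
    total_intensity: float
    inconsistent_intensity: float

    @property
    def inconsistent_fraction(self) -> float:
        return 0.0 if self.total_intensity == 0 else self.inconsistent_intensity / self.total_intensity

    @property
    def consistent(self) -> bool:
        return self.inconsistent_intensity == 0.0


def summed_pair_check(
    precursor_shift: int, chain_slots: Mapping[SlotKey, float]
) -> PairConsistency:
    """Check that chain labels respect the summed-pair constraint.

    For a two-chain lipid at precursor shift k the chains carry (i, k - i)
    labels, so no chain slot can exceed shift k.  Intensity in slots with
    shift > k is reported as inconsistent mass.
    """
    total = float(sum(chain_slots.values()))
    bad = float(sum(v for (ch, s), v in chain_slots.items() if s > precursor_shift))
    return PairConsistency(precursor_shift, total, bad)


def even_isotopologue_series(mid_vector: np.ndarray) -> Tuple[np.ndarray, float]:
    """Even-shift sub-series (M0, M2, M4, ...) renormalized, plus odd fraction.

    Labeling fed from uniformly 13C-labeled glucose enters acyl chains in
    two-carbon (acetyl) units, so genuine label mass sits on even shifts;
    the odd-shift fraction is a QC number (residual NA or noise).
    """
    v = np.asarray(mid_vector, dtype=float)
    total = v.sum()
    even = v[0::2].copy()
    odd_fraction = float(v[1::2].sum() / total) if total > 0 else 0.0
    s = even.sum()
    if s > 0:
        even = even / s
    return even, odd_fraction


def chain_fractions(
    chain_slots: Mapping[SlotKey, float], chain: AcylChain
) -> np.ndarray:
    """Normalized shift-fraction vector of one chain from slot intensities."""
    v = np.zeros(chain.carbons + 1)
    for (name, s), inten in chain_slots.items():
        if name == chain.name:
            v[s] += inten
    total = v.sum()
    return v / total if total > 0 else v


def acyl_natom_equivalents(
    slots_by_precursor: Mapping[int, Mapping[SlotKey, float]],
    precursor_mid: np.ndarray,
    pool_nmol: float,
    isomers: Sequence[Tuple[float, Tuple[AcylChain, AcylChain]]],
    lipid: str = "",
) -> List[AcylLabeling]:
    """Per-chain 13C natom equivalents from pair-decomposed MS2 slots.

    For each analyzed precursor shift k the slot intensities give each
    chain's label distribution; the mean label count per chain, weighted by
    the (NA-corrected) precursor MID, the lipid pool and the proportion of
    the acyl isomer the chain belongs to (counting a chain twice in
    symmetric isomers like 18:2/18:2) accumulates into
    ``pool * sum_k MID_k * p_isomer * mult * mean_shift(chain, k)``.
    """
    if pool_nmol <= 0:
        raise ValueError("pool_nmol must be positive")
    props = [p for p, _ in isomers]
    if abs(sum(props) - 1.0) > 1e-6:
        raise ValueError("isomer proportions must sum to 1")
    mid = np.asarray(precursor_mid, dtype=float)

    # chain -> sum over isomers of proportion x multiplicity within isomer
    weight: Dict[str, float] = {}
    chain_by_name: Dict[str, AcylChain] = {}
    for p, (a, b) in isomers:
        for ch in (a, b):
            weight[ch.name] = weight.get(ch.name, 0.0) + p
            chain_by_name[ch.name] = ch

    results = []
    for name, ch in sorted(chain_by_name.items()):
        natom = 0.0
        agg = np.zeros(ch.carbons + 1)
        for k, slots in slots_by_precursor.items():
            if k >= len(mid) or mid[k] == 0:
                continue
            f = chain_fractions(slots, ch)
            mean_shift = float(np.arange(len(f)) @ f)
            natom += pool_nmol * mid[k] * weight[name] * mean_shift
            agg += mid[k] * f
        s = agg.sum()
        if s > 0:
            agg = agg / s
        results.append(AcylLabeling(lipid=lipid, chain=ch, fractions=agg, natom_13C=natom))
    return results
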