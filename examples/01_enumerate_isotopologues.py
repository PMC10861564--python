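"""Enumerate the multivariate isotopologues of a dual-traced amino acid.

Glutamine has 5 carbons and 2 nitrogens.  Fed [13C5,15N2]glutamine, every
molecule can carry 0-5 heavy carbons and 0-2 heavy nitrogens: 6 x 3 = 18
distinct species.  A unit-mass instrument collapses these to 8 nominal
channels (M0-M7); high-resolution MS keeps all 18 apart because the 13C and
15N mass shifts differ by 6.3 mDa.
"""

import numpy as np

from isoscope import enumerate_isotopologues, parse_formula, resolving_power_required
from isoscope.chem import ADDUCTS, TRACER_13C, TRACER_15N, project_nominal

glutamine = parse_formula("C5H10N2O3")
grid = enumerate_isotopologues(
    glutamine, [TRACER_13C, TRACER_15N], ADDUCTS["[M-H]-"], "glutamine"
)

print(f"dual-tracer grid size: {len(grid)} isotopologues")
print(f"13C-only view: {grid.neutral['C'] + 1} channels (M0-M5)")
print(f"15N-only view: {grid.neutral['N'] + 1} channels (M0-M2)")
print(f"nominal-mass view: {grid.max_nominal_shift + 1} channels (M0-M7)")

# the closest pair on the grid: one 13C vs one 15N (both nominal M1)
mz_c = grid.theoretical_mz[grid.index_of((1, 0))]
mz_n = grid.theoretical_mz[grid.index_of((0, 1))]
gap = mz_c - mz_n
print(f"\n(1,0) vs (0,1) gap: {gap*1000:.2f} mDa at m/z {mz_c:.4f}")
print(f"resolution needed: {resolving_power_required(mz_c, gap):,.0f} (FWHM)")

# a uniform abundance over all 18 species sums into lattice-point counts
nominal = project_nominal(grid, np.full(18, 1 / 18))
print(f"\nuniform grid projected to nominal channels x18: {np.round(nominal*18).astype(int)}")
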