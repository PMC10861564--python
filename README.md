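# isoscope

Post-processing for transient stable-isotope-labeling experiments measured
by high-resolution mass spectrometry (HRMS).

Untargeted LC-HRMS runs of tissue fed a heavy tracer ([U-¹³C₆]glucose,
[¹³C₅,¹⁵N₂]glutamine, ...) are first peak-picked by XCMS or MZmine.  What
comes out is a flat feature table — m/z, retention time, one intensity
column per sample — in which the isotopologues of every labeled compound
are buried among thousands of features.  `isoscope` takes that table, a
compound library (name, neutral formula, retention time, adduct, optional
pool size) and sample metadata, and produces the quantities a tracer study
actually needs: mass isotopomer distributions (MIDs) over time,
natural-abundance-corrected labeling, pool-size-scaled label quantities,
flux-model-ready export tables, per-acyl-chain labeling of lipids from MS²
fragments, and clustering of compounds by their labeling kinetics.  It is
aimed at metabolomics and lipidomics groups running isotopically
nonstationary labeling time courses.

## The core model

For a compound with `N_e` atoms of each traced element *e*, the number of
multivariate isotopologues is

```
I = prod_e (N_e + 1)
```

Glutamine (C₅, N₂) under simultaneous ¹³C + ¹⁵N tracing has 6 × 3 = 18
species `(i, j)` with `0 ≤ i ≤ 5` heavy carbons and `0 ≤ j ≤ 2` heavy
nitrogens.  Their exact masses differ — ¹³C−¹²C = 1.00336 Da but
¹⁵N−¹⁴N = 0.99703 Da — so an Orbitrap at R = 140,000 separates all 18,
while a unit-mass instrument sees only the 8 nominal channels M0–M7.
Summing the 18-point grid by total shift, or marginalising onto one tracer
axis, reproduces exactly the data a nominal-mass or single-tracer
experiment would have measured: one dual-label experiment carries the
information of three.

Measured intensities mix tracer labeling with natural heavy isotopes
(1.07% ¹³C, 0.36% ¹⁵N, ...).  `isoscope` builds the forward convolution
matrix **C** over the grid — in `resolved` mode a natural-isotope species
contributes to a grid channel only if its exact mass lands within half the
instrument FWHM of it — and recovers the true MID **x** from the measured
vector **y** by non-negative least squares, `y ≈ C x`.  From corrected
MIDs it computes, for N labelable atoms and pool size P (nmol):

* average labeling (%) = `100 · Σ_k k·MID_k / N`
* nmol labeled product = `P · (1 − MID₀)`
* natom equivalents of ¹³C = `P · Σ_k k·MID_k`

For diacyl lipids, fragmenting each precursor isotopologue Mk releases the
acyl chains as carboxylate anions; HRMS separates a +2 ¹³C shift (2.00671
Da) from one fewer double bond (2.01565 Da), a 0.009 Da gap.  The two
chains' labels always arrive in summed pairs (i, k−i), which the module
both exploits and verifies.

## Worked example

`examples/03_end_to_end_pipeline.py` simulates a dual-tracer time course
for a glutamine-like compound (pool 50 nmol, asymptotic labeled fraction
0.7, rate 0.4 h⁻¹), writes it as an XCMS-style feature table, and runs the
full pipeline:

```
glutamine: nmol labeled product formed (mean +/- SD over 3 replicates)
  t =   0 h:   0.04 +/- 0.07 nmol
  t =   2 h:  19.09 +/- 0.24 nmol
  t =   4 h:  28.23 +/- 0.20 nmol
  t =   8 h:  33.78 +/- 0.45 nmol
```

The recovered curve follows `50 · 0.7 · (1 − e^{−0.4 t})` — 0, 19.3, 27.9,
33.6 nmol at the sampled times — so matching, NA correction and the
pool-scaled metric reproduce the planted kinetics to within replicate
noise.  The other examples demonstrate grid enumeration and resolution
requirements (01), NA correction round trips (02), MS² acyl-chain
decomposition (04) and clustering of labeling kinetics (05); each prints
what the numbers mean.

The same stages are scriptable from the shell:

```
isoscope simulate --panel both --times 0,2,4,8 --reps 3 --seed 0 --out demo
isoscope run --features demo/features.csv --db demo/compounds.csv \
             --meta demo/metadata.csv --out demo/out --seed 0
```

which writes `matched.csv`, `mids.csv`, `metrics.csv`, cluster/PCA tables
and per-compound flux-ready MID exports (¹³C marginal, ¹⁵N marginal,
nominal sum) under `demo/out/`.

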