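# Methods

This note records the models, conventions and design choices behind
`isoscope`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the edges are.

## Isotopologue grids and exact masses

A compound traced with tracers t = 1..T (each a single element with a
single heavy isotope) is represented by the multivariate grid of heavy-atom
count tuples `(i_1, ..., i_T)`, `0 ≤ i_t ≤ N_t`, where `N_t` counts the
tracer element's atoms in the **neutral** molecule.  Grid size is
`prod(N_t + 1)`.  Adduct atoms (the proton removed, the acetate added, ...)
are real atoms of the measured ion — they participate in natural-abundance
convolution — but are never tracer-enriched, because adduct groups come
from unlabeled mobile phase.  Indices are kept in lexicographic order of
the user's tracer list; all exports inherit that stable order.

Monoisotopic masses use fixed NIST/CODATA values (¹²C exactly 12,
¹H 1.00782503, ¹⁴N 14.00307401, ¹⁶O 15.99491462, ³¹P 30.97376163,
³²S 31.97207117; shifts ¹³C−¹²C = 1.00335484, ¹⁵N−¹⁴N = 0.99703496,
²H−¹H = 1.00627675).  Ion m/z adds one electron mass (0.00054858) per
negative charge and subtracts one per positive charge, divided by |z|;
without the electron term the reference ion masses would be off by ~0.5
mDa, which is visible at four printed decimals.  Only |z| = 1 is exercised
(soft ESI without fragmentation); multiple charging is out of scope.

The lipid reference ion is the acetate adduct: PC(36:4) (neutral
C₄₄H₈₀NO₈P) + CH₃COO⁻ gives C₄₆H₈₃NO₁₀P⁻ at m/z 840.5760 (M0) and 846.5961
(M6).  Acetate, not formate, is the composition consistent with these
masses and with an ammonium-acetate mobile phase; lipidomics reports
sometimes label such ions "formate" loosely, so the adduct table carries
both and the numbers decide.

Resolution bookkeeping uses the FWHM convention R = m/Δm at the stated
m/z, with a pair counted as separated when |Δm| ≥ FWHM (factor
configurable).  No m/z-dependent scaling of R is applied; users quoting
Orbitrap resolutions at a reference m/z should supply the effective R near
their mass range.

## Matching

Candidate features must satisfy |rt − rt_library| ≤ rt_tol (default 10 s)
and |mz − mz_theor|/mz_theor ≤ mz_tol (default 5 ppm) — defaults mirror
common XCMS pre-processing settings and are flags, not constants, since no
single tolerance suits every dataset.  The RT window is per compound (all
isotopologues share the library RT): the workflow is library-driven, not
apex-driven.  Within a compound each feature may serve at most one grid
slot (its nearest theoretical m/z); per slot the smallest |ppm error|
wins, ties broken by higher summed intensity.  Across compounds no
uniqueness is enforced — co-eluting isobars are a data problem the matcher
cannot resolve.  Unmatched slots are retained as zeros so MID vectors stay
full-length for correction.  A compound is "identified" when its M0
matched and carries signal in a time-0 (unlabeled control) sample.

## Natural-abundance correction

Column j of the correction matrix is the predicted measured distribution
of a molecule in true labeled state j: every atom of the ion is convolved
atom-by-atom over its natural isotopes (defaults: ¹³C 0.0107, ²H 0.000115,
¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205, ³³S 0.0075, ³⁴S 0.0421;
overridable), tracer-labeled positions register heavy with probability =
tracer purity (default 1.0) and light otherwise.  Species are tracked as
(neutron shift, exact-mass shift) pairs with probability pruning at 1e−12
and a mass-binning width of 0.1 µDa.

Two measurement models:

* **resolved** (default, R from config, default 140,000): a species is
  assigned to the grid channel whose theoretical mass shift is nearest,
  only if the distance is within half the FWHM at the compound's m/z;
  otherwise the species leaves the measured window entirely.  This is what
  makes heteroatom correction separable at high resolution: natural ¹⁵N
  stays on the ¹⁵N axis, ¹⁸O (2.00424) misses the 2×¹³C channel (2.00671)
  by 2.5 mDa and drops out.  Columns therefore sum to ≤ 1.
* **nominal**: channels are total neutron shifts M0..M(ΣN_t); all species
  of equal shift merge.  For a pure-carbon molecule this reproduces the
  classical binomial correction matrix exactly.

Inversion is by non-negative least squares (scipy), then renormalisation
to sum 1, with the NNLS residual reported.  NNLS rather than a direct
inverse keeps noisy vectors from going negative and handles the
rectangular nominal-mode system.  Both raw and corrected MIDs are carried
through to output.

## Metrics

With N labelable atoms and corrected MID m over shifts 0..N: average
labeling = 100·Σk·m_k/N; nmol labeled product = pool·(1 − m₀) (a
steady-state pool is assumed, so the pool size measured in unlabeled
controls applies throughout the time course); natom equivalents =
pool·Σk·m_k = pool·N·(avg/100) identically.  Under dual tracing the
nominal projection feeds the headline average labeling and per-tracer
marginals feed per-element views; all three are first-class outputs.
Metrics are computed per sample and summarised as mean ± SD per time
point over replicates.  Pool sizes come from the compound database, e.g.
via bucket quantification: the analyte is ratioed against each applicable
spiked internal standard ("bucket") separately and the bucket estimates
averaged; zero-intensity buckets are excluded with a warning.

## MS² acyl-chain decomposition

Fragment model: acyl carboxylate anions CnH(2n−2d−1)O₂⁻ (the dominant
diacyl-lipid fragments in negative mode), masses from the same exact-mass
machinery.  Peaks are binned to (chain, ¹³C-shift) slots by nearest
theoretical m/z within a ppm tolerance (default 10 ppm, well below the
8.94 mDa labeling-vs-saturation gap at R = 120,000); centroided slot
assignment replaces manual peak integration.  Slot intensities are
averaged over four scans per precursor isotopologue.  Valid decompositions
obey summed pairs — chains of an Mk precursor carry (i, k−i) labels — and
intensity in slots with shift > k is reported as an inconsistency
fraction.  By default the even precursor isotopologues (M2, M4, M6, M8)
are analyzed, since label from uniformly ¹³C-labeled glucose enters acyl
chains in two-carbon acetyl units; the odd-channel fraction is a QC
output.  Chain natoms: for chain c in isomer I with proportion p_I (and
multiplicity 2 in symmetric isomers like 18:2/18:2),
`natom_c = pool · Σ_k MID_k · p_I · mult · mean_shift(c, k)`, which
conserves `Σ_chains natom = pool · Σ_k k·MID_k` for consistent
decompositions.  Isomer proportions default to the unlabeled sample's
fragment ratios and are overridable.

## Clustering

Trajectories are replicate means of a chosen metric (default nmol labeled
product — deliberately not z-scored, because pool-size scaling is what
makes compounds comparable; a z-score flag exists for mixed-magnitude
panels).  k-means (scikit-learn, 10 restarts, fixed seed, default k = 3
with a silhouette report since no principled k is implied by the data
model), average-linkage Euclidean hierarchical clustering, and
mean-centered PCA.  Cluster ids are canonicalised by descending centroid
magnitude and PCA component signs by largest-magnitude loading, so results
are bit-reproducible across runs and implementations.

## Synthetic data

The generator emulates the two study designs the toolkit targets: a
dual-tracer amino-acid time course (0–8 h, 4 replicates) and a
single-tracer lipid time course (0–32 h, 3 replicates).  Labeled fraction
follows L(t) = A(1 − e^{−kt}); labeled molecules draw heavy atoms
independently per tracer axis as Binomial(N_t, enrichment) — the simplest
structure consistent with a uniform tracer, a modeling convenience and not
a claim about real positional enrichment.  Defaults: glutamine-like
compound A = 0.7, k = 0.4 h⁻¹, enrichment 0.9 per axis, pool 50 nmol;
lipid A = 0.6, k = 0.15 h⁻¹, enrichment 0.25, pool 12 nmol.  Measured
abundances are the true MIDs pushed through the same forward NA matrix the
corrector inverts, then perturbed with Gaussian m/z error (SD 1 ppm),
Gaussian RT jitter (SD 2 s) and multiplicative log-normal intensity noise
(CV 2%, representative of strong, well-behaved Orbitrap features).  All
draws hang off a single integer seed.

What passing the synthetic round trips does **not** show: the generator
has no chromatographic peak-shape or integration error, no co-eluting
isobars (decoys are placed a fixed 0.02 Da off), no detector saturation or
missingness, no RT drift between samples, and the NA forward model is by
construction the corrector's own — so round trips validate correctness of
the algebra and the pipeline plumbing, not robustness to model
misspecification in real data.

## Numerical choices and degenerate inputs

All-zero intensity vectors are flagged missing rather than normalized;
all-unmatched compounds yield zero matrices and are excluded from metrics
as unidentified.  Scan averaging uses exact (fsum) accumulation so it is
permutation-invariant to the bit.  Matching tie-breaks and sample ordering
are fully specified (ppm error, then summed intensity; time then
replicate), making every pipeline output byte-reproducible for a given
input and seed; outputs embed the software version, a config hash
(path-independent) and the seed.  Problem sizes throughout the test suite
are desk-scale by design — grids up to ~100 states, panels of a few
compounds, 10-seed benchmark sweeps — which keeps the full suite around
ten seconds.

## Known limitations

No fine isotope structure beyond the declared tracers (³⁴S vs ¹⁸O
multiplets are not modeled in theoretical spectra); no charge states
beyond ±1; no peak detection, RT alignment or gap filling (upstream
territory); no sn-position assignment and no lipids with more than two
acyl chains in MS²; no calibration-curve quantification beyond
single-point internal-standard ratios; flux estimation itself is the job
of downstream INST-MFA software, for which the marginal/nominal MID tables
are the hand-off.
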