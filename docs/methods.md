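# Methods

This note records the models, conventions and numerical choices behind
`cyclomet`, and what the synthetic benchmarks do and do not demonstrate.

## Mass scale and formula arithmetic

All masses are monoisotopic (most abundant isotope), summed from a
bundled CODATA/NIST-derived element table (`chem.MONOISOTOPIC_MASS`,
full published precision). Charged-species arithmetic uses a proton of
1.007276 Da and an electron of 0.000549 Da; the two adducts modeled are
[M+H]⁺ (neutral + proton) and [M+Na]⁺ (neutral + Na − e⁻), both singly
charged. The two computation routes — neutral mass plus adduct shift,
and ion-formula mass minus one electron — agree to < 1e-6 Da and are
cross-checked in tests.

Conventions that were genuinely open and are fixed here:

- **ppm sign**: `ppm = (theoretical − measured)/measured × 1e6`, so an
  ion measured heavier than calculated is negative. This is the only
  convention consistent with the signed values in the bundled library
  (both negative and positive rows). Whether the denominator is the
  measured or calculated mass is indistinguishable at 4-dp precision;
  measured is used.
- **Rounding for comparison with 4-dp published masses**: half-up to
  the printed precision (4 dp for m/z, 2 dp for ppm, 1 dp for fragment
  m/z). Reproducing published ppm values requires rounding the
  calculated mass to 4 dp *before* the ppm quotient — the published
  values were evidently computed from the rounded masses.
- **RDBE**: C + 1 + N/2 − (H + halogens)/2 on the neutral formula;
  O, S and monovalent metals contribute zero; half-integral values flag
  even-electron ion formulas.
- **Dereplication tie-break**: |ppm| ascending, then ΔRT, then name.

The bundled 19-compound library stores its source values verbatim.
Three entries are internally inconsistent in the source (one calculated
mass that disagrees with its own molecular formula by 0.0018 Da, and
two ppm values that do not follow from their printed mass pairs); the
`mass_consistent` flag exposes the first, and none are silently
"repaired". Acceptance checks that re-derive those three printed
values fail by exactly those margins, which is the intended behaviour.

## Cyclic peptide fragmentation model

A protonated cyclic *n*-peptide is modeled as ring-opening at any of
its *n* amide bonds to a linear acylium that fragments C-terminally:
the opening preceding residue *i* yields the rotation starting at *i*,
with b ions b_k = Σ(first k residue masses) + proton and
b_n = precursor [M+H]⁺ (cyclization removes one water, and ring opening
does not restore it). Only b ions are modeled — y ions, water/ammonia
losses, immonium ions, multiple charging and intensities are out of
scope — because the diagnostic ladders of proline-containing
cyclopentapeptides are interpreted entirely as b-ion series. Residue
compositions are amino acid minus water; N-methyl-phenylalanine is
Phe + CH₂ (residue mass 161.08406). D/L stereochemistry is invisible
to MS and not modeled.

**Annotation** matches every theoretical ion of every opening to the
nearest observed peak within an absolute tolerance (default 0.02 Da;
published fragments carry 1 dp, so this is conservative for annotated
data and appropriate for Orbitrap MS/MS). One observed peak may explain
several theoretical ions. Per-opening coverage counts matched
proper-prefix ions out of n−1 (b_n is shared by all openings and
uninformative about the site).

**Sequencing** is a depth-first branch-and-bound over a residue
alphabet: a prefix is extended only while each of its b ions lies
within tolerance of an observed peak, with a configurable budget of
unmatched ions (`max_mismatches`, default 0; raise to 2 for spectra
with dropout) plus a mass-window prune from the residue-mass extremes;
the ring closes only when the residue total + proton matches the
precursor. Candidates are scored by the number of observed peaks their
full cyclospectrum explains, de-duplicated by canonical rotation (the
lexicographically smallest rotation of the residue-name list), and
tie-broken by smaller |precursor delta| then lexicographic key.

Two degeneracies are irreducible from b-ion masses alone and are
reported, not hidden:

- **Leu/Ile** share residue mass 113.08406; the search collapses them
  to the class label "Xle" (expandable on request).
- **Reflection**: the theoretical ions over all openings are the sums
  of contiguous runs of the ring, a set invariant under reversing the
  ring. A non-palindromic ring and its mirror therefore have identical
  cyclospectra and tie exactly on noiseless data; both rotation classes
  are reported. Recovery claims in the tests are accordingly stated up
  to rotation + Leu/Ile + reflection, verified against a brute-force
  enumeration oracle for small rings.

## Feature filtering and scaling

The pipeline consumes an already-aligned feature table (peak picking,
alignment and isotope annotation are upstream; the per-feature isotope
flag is an input column). Filters, applied per feature and idempotent:

1. isotope-flagged features removed;
2. features whose *maximum* area across samples is strictly below
   10,000 removed (the removal unit is the feature, not the cell; a
   maximum of exactly 10,000 is retained);
3. for tables whose samples are all mycelium extracts, features with
   RT > 25 min removed (column-wash tail). Mixed-matrix tables are
   split by matrix first; the RT rule never touches filtrate tables.

Pareto scaling is mean-centering followed by division by √sd
(n−1 denominator). Constant columns are centered only and flagged. The
modeling matrix is pareto-scaled **natural-log areas**: on raw
log-normally distributed areas (baselines spanning several orders of
magnitude, as in real LC-MS) the heavy-tailed variance lets abundant
noise features dominate the covariance with the class vector and marker
recovery collapses; the log transform is the standard metabolomics
variance stabilization and restores near-perfect recovery. A raw-area
mode remains available (`log_transform: false`).

## OPLS-DA

Two-class OPLS-DA is implemented from scratch (no PLS library at run
time). With y coded {−1, +1} and centered, and X column-centered:
`w ∝ Xᵀy` (unit norm) is the single predictive direction appropriate
for a binary response; each orthogonal component is
`w_o ∝ p − (wᵀp)w`, `t_o = Xw_o`, `p_o = Xᵀt_o/t_oᵀt_o`, deflating
`X ← X − t_o p_oᵀ`; the predictive component is then `t = Xw` with
inner regression `c = yᵀt/tᵀt`. R²Y is the training fit of y; R²X the
fraction of X sum of squares captured by predictive plus orthogonal
components. With `n_orth = 0` the predictive scores coincide with the
first component of a reference NIPALS PLS (tested, cosine > 0.9999).

- **Orthogonal components**: default 1 (configurable). For isotropic
  noise more components neither help nor hurt prediction materially.
- **Q²**: stratified 7-fold cross-validation (fold count configurable,
  seeded, round-robin within class so no training fold loses a class);
  Q² = 1 − PRESS/SS with PRESS over held-out coded responses and SS
  about the global mean. Verdicts: Q² > 0.4 valid, > 0.7 highly
  significant, both boundaries strict.
- **VIP** from the predictive component only (orthogonal variation is
  y-uncorrelated by construction), VIP_j = √p·|w_j|, so ΣVIP² = p
  holds identically; ties in the ranking break by feature m/z then id.
- **S-plot**: p1 = cov(t, x_j), pcorr1 = corr(t, x_j) against the
  centered (pre-deflation) matrix; zero-variance features get
  pcorr1 = 0 with a flag.
- **Subset validation**: three models (full, top-N VIP only, all but
  top-N), each cross-validated; the subset is "useful" when the
  include model is valid and the exclude model is invalid.
- **Permutation diagnostic**: Q² under label permutation (≥ 10
  permutations), summarized by median and 95th percentile.

## Synthetic study generator

`simulate_study` emulates the comparative design the pipeline targets:
15 strains (4 highbush, 11 wild hosts), two media (ML, PDB), filtrate
and mycelium extracts — 60 samples — and 3,856 features with m/z
uniform on the 150–1100 acquisition range and RT uniform on the 0–31
min gradient. Abundances are log-normal: per-feature baseline
ln-areas ~ N(12.5, 2.0) (areas centred near e^12.5 ≈ 2.7e5 and spanning
roughly 1e3–1e8, a realistic LC-MS dynamic range that also places a few
per cent of features below the 10,000-count floor), within-group noise
sd 1.0 on the log scale, areas clipped at 1e9. Five per cent of
features carry isotope flags. Thirty markers per contrast (medium;
host), disjoint sets, are shifted by effect × noise-sd (default 3) in
a random direction in the ML (respectively highbush) samples.
Everything is reproducible from a single seed.

The generator does **not** emulate chromatographic peak shape, isotope
envelopes, adduct/fragment correlation, missingness, batch drift, or
correlated metabolite families. Passing benchmarks therefore
demonstrate the statistics (recovery, calibration, overfit detection),
not robustness to peak-picking artifacts.

### A statistical ceiling worth knowing about

With 30 informative features among 3,856 at a 3-sd shift and n = 30
samples, the full-model cross-validated Q² plateaus near 0.33 (n = 60:
~0.53): the predictive weight vector is estimated from n samples, so
the ~3,800 noise coordinates contribute variance that caps hold-out
prediction regardless of implementation (an independent reference PLS
reproduces the same values to ~0.01). The acceptance benchmark that
expects full-model Q² > 0.7 under exactly these conditions therefore
fails, and is left failing: real screens reach high full-model Q² only
because many correlated features shift together between conditions,
which this generator deliberately does not inject. The informative
comparisons — include-top-30 Q² ≈ 0.99, exclude-top-30 Q² ≤ 0.4,
permuted-label median Q² ≈ 0, marker recovery ≥ 80% — all behave as
designed.

## Pipeline and problem sizes

The end-to-end pipeline (simulate/load → filter → model → prioritize →
dereplicate → annotate/sequence) is config-driven (YAML + flag
overrides), logs stage-tagged lines to stderr, writes every CSV with a
header comment carrying version, config hash and seed, and keeps a
content-hash manifest so re-running a completed stage with unchanged
inputs is a no-op.

Default problem sizes were chosen so the full suite and the acceptance
benchmarks are cheap: the statistical acceptance runs the complete
3,856-feature study once (a full fit + 7-fold CV + 3-model subset
validation + 20 permutations completes in seconds); unit and property
tests use 200–500-feature designs and rings of size ≤ 5 over reduced
alphabets for the exhaustive sequencing oracle.

## Known limitations

- Binary contrasts only (no multi-class OPLS-DA, no O2-PLS).
- Positive mode, charge +1, [M+H]⁺/[M+Na]⁺ only; no isotope-pattern
  scoring; the dereplication library is the bundled CSV, not an
  external database connection.
- b ions only; no PTMs beyond N-methylation; no intensity model.
- Q² fold scheme is one defensible choice among several used by
  commercial software; fold count and seed are exposed and logged.
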