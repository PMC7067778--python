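# cyclomet

Metabolomic-guided discovery tooling for fungal natural products:
untargeted LC-MS feature prioritization by OPLS-DA/VIP, accurate-mass
dereplication, and annotation plus de novo sequencing of cyclic
nonribosomal peptides from their b-ion fragment ladders.

It is written for natural-product and metabolomics researchers who run
comparative untargeted LC-MS screens of microbial culture extracts
(multiple strains × media × extract matrices) and want to go from an
aligned feature table to a short list of statistically discriminant,
dereplicated features — and, when those features are cyclic peptides,
from their MS/MS spectra to candidate residue sequences.

## What it computes

**Feature prioritization.** For a two-group contrast, the features ×
samples abundance matrix is filtered (isotopic ions removed, features
with maximum integrated area < 10,000 removed, late-eluting features
removed for mycelium extracts), log-transformed and pareto-scaled
(x′ = (x − x̄)/√s), then modeled with a from-scratch two-class OPLS-DA:
a single predictive component `t = Xw` with `w ∝ Xᵀy`, after iterative
removal of *y*-orthogonal components `(w_o, t_o, p_o)`. Model quality is
summarized by R²X, R²Y and the 7-fold cross-validated prediction
statistic **Q² = 1 − PRESS/SS**, with Q² > 0.4 marking a valid model
and Q² > 0.7 a highly significant one. Features are ranked by
**VIP** (normalized so ΣVIP² = p; VIP > 0.7 is treated as significant)
and visualized via S-plot coordinates (cov(t, xⱼ) vs corr(t, xⱼ)).
A parallel *include-top-N / exclude-top-N* validation decides whether
the prioritized subset actually carries the class difference.

**Dereplication.** Observed accurate masses and retention times are
matched against a bundled 19-compound library (griseofulvin and
congeners, cytochalasins, hirsutatin A, piliformic acid, xylarotide A
and the cyclic pentapeptide family including ellisiiamides A–H), using
monoisotopic [M+H]⁺/[M+Na]⁺ arithmetic, signed ppm errors and RDBE
integrity checks.

**Cyclic peptide MS/MS.** A protonated cyclic *n*-peptide ring-opens at
any of its *n* amide bonds; each opening yields a b-ion ladder
`b_k = Σ first-k residue masses + 1.007276`, with `b_n` equal to the
precursor [M+H]⁺. The package enumerates all openings, builds the full
theoretical cyclospectrum, annotates observed spectra per opening, and
sequences unknowns by branch-and-bound search over a residue alphabet
(20 proteinogenic residues + N-methyl-phenylalanine). Two degeneracies
are inherent to mass-only sequencing and reported honestly: Leu/Ile
(isobaric, collapsed to "Xle") and ring reflection (a ring and its
mirror share every b-ion mass).

## Worked example

`examples/prioritize_features.py` simulates the full study design
(15 strains × 2 media × 2 extract matrices, 3,856 features, 30 planted
medium-discriminant markers at a 3-sd log shift), filters the filtrate
table and runs the prioritization. Output:

```
filter: removed 218 isotopic, 16 below area 10000, 0 after 25 min (mycelium rule not applicable); 3622 kept
full model: R2X=0.079 R2Y=1.000 Q2=0.344 -> invalid
top-30 VIP contains 28/28 planted medium markers
          model  n_features      r2x      r2y        q2            verdict
           full        3622 0.078667 0.999959  0.344451            invalid
include_top_vip          30 0.726144 0.995049  0.986190 highly significant
exclude_top_vip        3592 0.070470 0.999929 -0.021192            invalid
useful subset: True
permuted-label null: median Q2 -0.017, 95th pct 0.089 (the observed structure is not an overfitting artifact)
```

Reading this: the full 3,622-feature model fits training data perfectly
(R²Y ≈ 1) but cross-validates poorly — with only 30 informative
features among thousands, most of the weight vector is noise. The VIP
ranking nevertheless recovers every planted marker, and the subset
validation shows the classic useful-subset signature: the top-30 model
alone is highly significant (Q² = 0.99) while everything else together
is uninformative (Q² ≤ 0), and permuted labels produce no spurious Q².

`examples/annotate_cyclopeptide.py` annotates the diagnostic fragments
of cyclo(NMePhe-Ala-Ile-Leu-Pro) ([M+H]⁺ 556.3493): the ladder
162.1 → 233.1 → 346.2 → 459.3 gets full coverage only for the
Pro–NMePhe ring opening, identifying the dominant fragmentation
pathway (sequential loss of Pro, Leu, Ile, Ala).
`examples/sequence_cyclopeptide.py` re-derives that ring de novo from a
spectrum with 20% of peaks missing, and
`examples/dereplicate_ion.py` matches an observed ion (550.3973 at
15.97 min) to xylarotide A at −1.82 ppm.

A thin CLI mirrors the library — subcommands `simulate`,
`simulate-msms`, `filter`, `model`, `prioritize`, `derep`, `annotate`,
`sequence` and `run` (the config-driven end-to-end pipeline); see
`cyclomet --help`.

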