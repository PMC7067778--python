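"""b-ion ladder annotation of a cyclic pentapeptide MS/MS spectrum.

A protonated cyclic peptide fragments by ring opening: each of the five
amide bonds can cleave, giving five linear acylium ions whose sequential
losses form five b-ion ladders. Annotating an observed spectrum against
every opening shows which cleavage sites dominate.
"""

import numpy as np

from cyclomet import CyclicPeptide, MsMsSpectrum, annotate_spectrum, b_series

peptide = CyclicPeptide.from_string("cyclo(NMePhe-Ala-Ile-Leu-Pro)")
print(f"{peptide}: [M+H]+ = {peptide.precursor_mz:.4f}, formula {peptide.formula}")

# the four diagnostic fragments reported for this compound (1 dp)
observed = MsMsSpectrum(
    precursor_mz=556.35,
    mz=np.array([162.09, 233.13, 346.21, 459.30]),
    intensity=np.array([40.0, 55.0, 80.0, 100.0]),
)

annotations, coverage = annotate_spectrum(peptide, observed, tol=0.05)
print("\ncoverage by ring-opening site (matched fraction of b1..b4):")
for opening, frac in sorted(coverage.items(), key=lambda kv: -kv[1]):
    print(f"  {opening:15s} {frac:.2f}")
# Full coverage of the Pro-NMePhe opening identifies the dominant
# fragmentation pathway: the ring opens between Pro and NMePhe and loses
# Pro, Leu, Ile, Ala in turn.

best = "Pro-NMePhe"
print(f"\nb-ion ladder of the {best} opening "
      f"({[round(float(b), 1) for b in b_series(dict(peptide.ring_openings())[best])]}):")
for a in annotations:
    if a.opening == best and a.observed_mz is not None:
        loss = f"(next loss: -{a.residue_lost_next})" if a.residue_lost_next else ""
        print(f"  b{a.ordinal}: theo {a.theoretical_mz:.4f}  obs {a.observed_mz:.2f}  "
              f"delta {a.delta:+.3f} {loss}")
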