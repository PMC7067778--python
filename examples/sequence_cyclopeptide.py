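"""De novo sequencing of a cyclic pentapeptide from a degraded spectrum.

Simulates an imperfect MS/MS spectrum (20% of theoretical peaks lost),
then searches all rings of 5 residues over the default alphabet whose
b-ion ladders fit the surviving peaks. Two degeneracies are inherent to
mass-only sequencing: Leu/Ile (identical mass, reported as Xle) and the
ring reading direction (a ring and its mirror share every b-ion mass).
"""

from cyclomet import CyclicPeptide, sequence_candidates, simulate_msms

truth = CyclicPeptide.from_string("cyclo(NMePhe-Ala-Ile-Leu-Pro)")
spectrum = simulate_msms(truth, dropout=0.2, seed=7)
print(f"true ring: {truth}  precursor {truth.precursor_mz:.4f}")
print(f"spectrum: {len(spectrum)} of 21 theoretical peaks survive\n")

candidates = sequence_candidates(
    spectrum.precursor_mz, spectrum, ring_size=5, tol=0.01, keep=5, max_mismatches=2
)
print("rank  ring (canonical rotation, Leu/Ile as Xle)   matched peaks")
for i, c in enumerate(candidates, 1):
    marker = ""
    if c.rotation_key == truth.rotation_key(collapse_isobaric=True):
        marker = "  <- true ring"
    elif c.rotation_key == truth.reversed().rotation_key(collapse_isobaric=True):
        marker = "  <- mirror of true ring"
    print(f"{i:>4}  cyclo({'-'.join(c.rotation_key)})  {c.matched_peaks:>3}{marker}")
# The matched-peak count is the number of observed peaks explained by a
# candidate's full theoretical cyclospectrum at 0.01 Da; the true ring
# (or its mirror) should lead despite the missing peaks.
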