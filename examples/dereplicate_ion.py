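"""Accurate-mass dereplication of an observed LC-MS ion.

Matches a measured m/z + retention time against the bundled library of
known and new metabolites (PKS, cytochalasins, cyclic pentapeptides) and
prints the ppm error and RT difference of each hit.
"""

from cyclomet import dereplicate, ion_mz, ppm_error, rdbe

# an intense filtrate ion: measured m/z 550.3973 eluting at 15.97 min
hits = dereplicate(observed_mz=550.3973, observed_rt=15.97, tol_ppm=5.0, tol_rt=0.5)
for h in hits:
    print(f"{h.entry.name}: class {h.entry.compound_class}, "
          f"ppm {h.ppm:+.2f}, delta RT {h.delta_rt:.2f} min")
# A single hit within 5 ppm / 0.5 min means the feature is a known
# compound and not worth re-isolating.

# formula-level arithmetic behind the match
print(f"[M+H]+ of C29H51N5O5 = {ion_mz('C29H51N5O5'):.4f}")
print(f"ppm(measured 550.3973 vs calc) = {ppm_error(550.3973, ion_mz('C29H51N5O5')):+.2f}")
print(f"RDBE of C29H51N5O5 = {rdbe('C29H51N5O5'):.0f} "
      "(5 amide C=O + the macrocycle + 1 further unsaturation)")
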