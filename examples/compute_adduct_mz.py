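"""Exact-mass adduct calculation for suspect screening.

Computes theoretical precursor and fragment m/z values for two
groundwater contaminants — hexafluoropropane-2,2-diol (a PFAS detected
as its deprotonated molecule and formate adduct) and the herbicide
hexazinone — the numbers one compares against observed high-resolution
feature masses at a 5 ppm accuracy threshold.
"""

from speclib import ELECTRON_MASS, monoisotopic_mass, ppm_difference, precursor_mz

diol = monoisotopic_mass("C3H2F6O2")
print(f"hexafluoropropane-2,2-diol   M        = {diol:.5f} Da")
print(f"  [M-H]-       m/z = {precursor_mz(diol, '[M-H]-'):.4f}")
print(f"  [M+CH2O2-H]- m/z = {precursor_mz(diol, '[M+CH2O2-H]-'):.4f}  (formate adduct)")
print(f"  CF3-         m/z = {monoisotopic_mass('CF3') + ELECTRON_MASS:.4f}  (fragment anion)")
print(f"  CF3COO-      m/z = {monoisotopic_mass('C2F3O2') + ELECTRON_MASS:.4f}  (fragment anion)")

hexazinone = monoisotopic_mass("C12H20N4O2")
print(f"hexazinone                   M        = {hexazinone:.5f} Da")
print(f"  [M+H]+       m/z = {precursor_mz(hexazinone, '[M+H]+'):.4f}")

observed = 182.9887  # a measured feature mass for the diol, negative mode
theoretical = precursor_mz(diol, "[M-H]-")
print(f"observed {observed} vs theoretical {theoretical:.4f}: "
      f"{abs(ppm_difference(theoretical, observed)):.2f} ppm"
      " -> inside a 5 ppm match window")
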