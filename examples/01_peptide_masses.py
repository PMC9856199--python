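"""Peptide mass bookkeeping for the epitope panel.

Builds the eight hcTn I aa184-aa198 epitope peptides (wild type plus seven
SNP-derived variants) by applying single-amino-acid exchanges to the wild
type, then prints monoisotopic masses and the m/z of the charge states seen
in nanoESI.  The calc_mz column is what a calibrated instrument should read
for each peptide, so it doubles as an identity check on synthesized stocks.
"""

from epibind.peptides import apply_sap, mass_report
from epibind.reference import PANEL, PANEL_CHARGES, WILDTYPE

variants = [PANEL[i] for i in sorted(PANEL)]
charges = [PANEL_CHARGES[i] for i in sorted(PANEL)]

print(mass_report(variants, charges).to_string(index=False))

double = apply_sap(WILDTYPE, ["R192P", "K193E"])
print(f"\nDouble exchange {double.label}: {double.sequence}")
print("Each row's calc_mz is the expected [M+zH]z+ position; a stock whose "
      "measured m/z deviates by more than ~0.02 Th failed synthesis or "
      "carries an unintended modification.")
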