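"""Published reference values for the anti-hcTn I [MF4] epitope peptide panel.

The eight 15-mer peptides cover hcTn I aa184-aa198 (UniProt P19429 numbering):
the wild type plus seven SNP-derived single-amino-acid polymorphisms at
positions 186, 190, 192 and 193 (peptide 8 carries two exchanges).  Alongside
the sequences, this module records the published gas-phase dissociation course
parameters, apparent gas-phase thermodynamic values, and in-solution ITC
results for the panel.  These serve as ground-truth inputs for simulations and
as fixed points for identity checks; they are data, not computed results.
"""

from __future__ import annotations

from .peptides import PeptideVariant, apply_sap

__all__ = [
    "WILDTYPE",
    "PANEL",
    "PANEL_CHARGES",
    "PANEL_CALC_MZ",
    "CV_STEPS",
    "ANTIBODY_MASS_AVG",
    "ANTIBODY_CHARGE_RANGE",
    "COURSE_PARAMS",
    "GAS_THERMO",
    "ITC_RESULTS",
]

#: Wild-type epitope peptide, hcTn I aa184-aa198.
WILDTYPE = PeptideVariant(
    sequence="ENREVGDWRKNIDAL", start_residue=184, label="wt",
)

#: Peptide panel keyed by peptide number; values built by applying the SAP
#: edits to the wild type (peptide 8 is the R192P + K193E double exchange).
PANEL = {
    1: WILDTYPE,
    2: apply_sap(WILDTYPE, "R186Q"),
    3: apply_sap(WILDTYPE, "R192H"),
    4: apply_sap(WILDTYPE, "R192L"),
    5: apply_sap(WILDTYPE, "R192C"),
    6: apply_sap(WILDTYPE, "D190G"),
    7: apply_sap(WILDTYPE, "R192P"),
    8: apply_sap(WILDTYPE, ["R192P", "K193E"]),
}

#: Charge state of the published calculated m/z per peptide.
PANEL_CHARGES = {1: 3, 2: 3, 3: 3, 4: 3, 5: 3, 6: 3, 7: 3, 8: 2}

#: Published calculated m/z (Th) per peptide at the charge above.
PANEL_CALC_MZ = {
    1: 605.64, 2: 596.30, 3: 599.30, 4: 591.30,
    5: 587.95, 6: 586.31, 7: 585.96, 8: 878.91,
}

#: Collision-cell voltage-difference schedule (V), 13 steps.
CV_STEPS = (2, 4, 6, 8, 12, 16, 20, 30, 40, 50, 60, 70, 80)

#: Measured average molecular mass of the intact anti-hcTn I antibody (Da).
ANTIBODY_MASS_AVG = 146756.2

#: Observed antibody charge-state range under native nanoESI.
ANTIBODY_CHARGE_RANGE = (23, 27)

#: Published breakdown-course characteristics per peptide:
#: (initial %, final %, dcv50 V, dx V, slope %/V, r2); None where the course
#: was flat or absent and no sigmoid was fitted.
COURSE_PARAMS = {
    1: (77.36, 36.24, 30.0, 15.2, -0.67, 0.997),
    2: (87.39, 47.63, 30.3, 11.7, -0.85, 0.998),
    3: (52.55, 32.68, 27.1, 12.3, -0.40, 0.997),
    4: (41.60, 23.12, 27.2, 13.2, -0.35, 0.996),
    5: (58.77, 29.41, 27.7, 13.0, -0.57, 0.996),
    6: (58.83, 23.33, 32.1, 11.8, -0.75, 0.997),
    7: (15.37, 5.90, None, None, None, None),
    8: (0.00, 0.00, None, None, None, None),
}

#: Published apparent gas-phase values per orthodox-binding peptide:
#: (kD 1/s, KD, dG kJ/mol, dH kJ/mol, TdS kJ/mol at 298 K).
GAS_THERMO = {
    1: (1.87e12, 4.55e-12, 64.70, -1.91, -66.60),
    2: (7.83e11, 4.41e-12, 64.78, -1.57, -66.33),
    3: (5.09e12, 4.71e-12, 64.62, -2.21, -66.82),
    4: (7.37e12, 4.77e-12, 64.59, -2.25, -66.82),
    5: (3.89e12, 4.67e-12, 64.64, -2.04, -66.67),
    6: (2.90e12, 4.62e-12, 64.67, -1.85, -66.50),
}

#: Published in-solution ITC values per measured peptide:
#: (KD, KA 1/M, dG kJ/mol, dH kJ/mol, TdS kJ/mol at 298 K).
ITC_RESULTS = {
    1: (2.19e-7, 4.58e6, -38.05, -60.40, -22.35),
    2: (0.36e-7, 27.9e6, -42.59, -109.10, -66.51),
    4: (2.43e-7, 4.12e6, -37.77, -52.10, -14.33),
    6: (4.11e-7, 2.43e6, -36.49, -45.40, -8.91),
}
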