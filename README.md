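# epibind

Gas-phase fine-mapping of antibody–epitope binding strength, with an
in-solution calorimetry companion.

## The problem

Point-of-care assays detect disease markers (e.g. human cardiac troponin I
after myocardial infarction) with monoclonal antibodies aimed at a short
epitope.  Single amino acid polymorphisms (SAPs) inside or near that
epitope can weaken or abolish antibody binding and silently produce false
negatives.  `epibind` implements the analysis chain for measuring this
residue by residue: intact antibody–peptide complexes are electrosprayed
under native conditions, dissociated in a collision cell at stepped voltage
differences (ΔCV), and the surviving complex ("educt") signal is tracked
into a breakdown curve.  Wild-type and SAP-variant epitope peptides are
then ranked by their apparent gas-phase dissociation thermodynamics, and
cross-checked against single-site isothermal titration calorimetry (ITC)
in solution.

## What it computes

- **Peptide bookkeeping** — SAP variants (`R192P`, chained edits), monoisotopic
  / average masses, [M+zH]z+ m/z.
- **Spectrum processing** — scan averaging, iterated Savitzky–Golay smoothing,
  species apex reading, Gaussian charge-envelope fits with imputation, mean
  charge, normalized educt fractions, zero-charge mass deconvolution.
- **Quality gate** — four acceptance criteria (species resolution in ≥5 charge
  states, sodium-adduct limit, no outlier exclusions, R² ≥ 0.99); a series
  passes on 3 of 4.
- **Boltzmann fitting** — y(x) = A2 + (A1−A2)/(1+exp((x−x0)/dx)) on the educt
  course; midpoint ΔCV50 = x0, tangent slope −(A1−A2)/(4·dx).
- **Apparent thermodynamics** — per-charge midpoints → center-of-mass collision
  energy → effective temperature → Eyring/van't Hoff/Arrhenius extrapolation
  to a resting neutral complex at 298 K (ΔH, ΔG, TΔS, K_D, k_D), and binder
  groups I–IV (split at ΔH = −2 kJ/mol; flat course = III; no complex = IV).
- **ITC** — Wiseman single-site fit of injection heats with perfusion dilution;
  K_A, ΔH, n and the exact derived ΔG = −RT ln K_A, TΔS = ΔH − ΔG.
- **Synthetic data** — a deterministic generator for breakdown series and
  titrations with known ground truth, used throughout the tests.

See `docs/methods.md` for the model details and their assumptions.

## Worked example

`python examples/02_breakdown_pipeline.py` simulates a wild-type-like series
(2% intensity noise, seed 7), processes it and fits the course:

```
Boltzmann fit: A1=74.00%  A2=37.53%  DCV50=31.9 V  dx=12.9 V  slope=-0.71 %/V  R2=0.9993
(generating truth: A1=77.36  A2=36.24  DCV50=30.0  dx=15.2)
QC gate (3 of 4 needed): passed=True  [resolution=True sodium=True outliers=True r2=True]
```

The fitted midpoint (31.9 V) is the voltage at which half the educt signal
has dissociated — the per-peptide quantity whose shifts across SAP variants
report binding-strength differences; the R² above 0.99 means the series
would survive the quality gate.  `examples/01_peptide_masses.py` prints the
epitope-panel mass table (wild type `ENREVGDWRKNIDAL`, 605.64 Th at 3+), and
`examples/03_itc_fit.py` fits a synthetic titration at the real experiment's
geometry, recovering K_A = 4.9e6 /M against a ground truth of 4.58e6 /M at
5% heat noise.

A thin CLI wraps the same calls:
`epibind simulate | process | fit-rank | itc | masses` (see `--help`).

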