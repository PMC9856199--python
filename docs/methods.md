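# Methods

## The experiment this package models

An intact monoclonal antibody is mixed with a short epitope peptide and the
complex is electrosprayed under native conditions (nanoESI, ammonium
acetate).  The multiply charged antibody and antibody–peptide complex ions
(typically 23+ to 27+, m/z 5000–7000) pass a collision cell whose voltage
difference (ΔCV) is stepped, here over the 13-step schedule
2, 4, 6, 8, 12, 16, 20, 30, 40, 50, 60, 70, 80 V.  As the activation
increases, the complex dissociates, the released peptide appears at 2+/3+,
and the surviving "educt" signal (complex with one or two bound peptides)
falls along a sigmoidal breakdown course.  The midpoint and steepness of
that course, compared across wild-type and single-amino-acid-polymorphism
(SAP) variants of the epitope, rank the variants' gas-phase binding
strength.  A companion isothermal-titration-calorimetry (ITC) fit gives the
in-solution reference.

## Spectrum processing

Scans within one voltage step are averaged (pointwise mean; mismatched m/z
grids are linearly resampled onto the first scan's grid, which preserves the
total ion current to well within 1%).  The averaged spectrum is smoothed by
20 passes of a Savitzky–Golay filter.  The filter's window is specified as
10 data points; symmetric SG kernels need an odd length, so 10 is widened to
11, and the polynomial order — unspecified in vendor software — is set
to 2, the closest standard filter to vendor mean-smoothing.

Species apex heights are read as the maximum smoothed intensity within a
tolerance window around the predicted m/z of each species (antibody mass
plus 0, 1 or 2 peptide masses, at each charge).  Default tolerances: 5 Th
for the heavy species near m/z 6000, 0.5 Th for peptide ions.  Expected
positions closer than one tolerance trigger a collision warning and the
taller apex dominates.  The background is the median intensity over
configured signal-free windows (default m/z 4400–4700).

Each species' charge-state envelope is fitted with a Gaussian over charge.
The fit needs at least five points; when fewer charge states were measured,
flanking charge states are imputed at background intensity, alternating
below and above the measured range (starting below).  The Gaussian center
is the species' **mean charge**; the Gaussian apex is the species height
used everywhere downstream.  Envelopes whose points never rise above
background are non-detects (apex = background, center undefined).

The **normalized educt fraction** at each step is

    100 · (h_complex1 + h_complex2) / Σ h_species

with the denominator over antibody, both complex stoichiometries, and the
released peptide.  Antibody fragment ions are excluded by default
(configurable): they appear only at high ΔCV where counting them alongside
the released peptide would double-count dissociation products.  Per-charge
courses, which feed the thermodynamic chain, normalize over the three heavy
species at that charge only, because the released peptide carries its own
unrelated charge states.

Zero-charge deconvolution of consecutive multiply charged peaks follows the
adjacent-spacing rule (for neighbours m1 > m2 with charges z and z+1,
z = (m2 − m_proton)/(m1 − m2)); per-peak masses must agree, otherwise the
peak list mixes species and is rejected.

## Quality gate

A series enters further analysis when at least three of four criteria hold:
(i) antibody/complex1/complex2 are differentiated in at least five charge
states, read as the valley between adjacent species signals staying at or
below 50% of the smaller apex (the published phrasing is ambiguous; this
valley reading is the default strategy); (ii) the sodiated released-peptide
2+ signal at the final step is at most 35% of the protonated 2+ signal —
undecidable for series that release no peptide, recorded as a pass with a
warning so non-binder series can still be classified; (iii) the Boltzmann
fit used every course point; (iv) the fit's R² (1 − SS_res/SS_tot on the
course means) is at least 0.99.  Both thresholds are boundary-inclusive.

## Boltzmann fitting

The course is fitted with y(x) = A2 + (A1 − A2)/(1 + exp((x − x0)/dx)) by
nonlinear least squares on the replicate means (optionally 1/SD² weighted).
Initial guesses: A1 = max, A2 = min, x0 = first midlevel crossing by linear
interpolation, dx = span/10.  By default the parameters are constrained to
their identifiable region — plateaus in [0, 100]%, midpoint inside the
scanned window, dx within half the window span — and the best of three
starts is kept.  Without the constraints the sigmoid can degenerate into a
straight line (x0 and dx off to infinity) on noisy courses; the constraints
encode only what the experiment already guarantees (fractions are
percentages and the schedule was chosen to bracket the transition).
Courses spanning less than 10 percentage points are refused as
transition-free ("no transition"; the weak-binder course spanning
15.4 → 5.9% was not fitted for the same reason).  The midpoint tangent has
slope −(A1 − A2)/(4·dx), exactly.

Under 2-percentage-point course noise a single 13-point fit recovers the
midpoint only to a few volts (the Cramér–Rao bound for the unconstrained
four-parameter problem is ≈4.4 V), so recovery statements are made about
the median over many seeded replicates.  Both the fitted asymptotes (A1,
A2) and the endpoint data values (course at 2 V and 80 V, how the published
initial/final columns are defined) are reported.

## Apparent thermodynamics ("m0g" chain)

The published extrapolation to a resting, neutral complex at ambient
temperature references earlier protocol papers without closed forms, so the
chain here is the package's own documented reconstruction from the four
named ingredients (Eyring–Polanyi, Arrhenius, Gibbs–Helmholtz, van't Hoff)
and the stated anchors.  Per charge state z with midpoint ΔCV50(z):

1. center-of-mass collision energy
   E = z·e·ΔCV50·N_A · m_Ar/(m_Ar + M_complex) · n_collisions (kJ/mol);
2. effective temperature T_eff = T_source + E/((3N − 6)·R) with
   T_source = 313 K (40 °C source) and N = 20,000 atoms (IgG1 anchor);
3. midpoint condition: half the educt survives the collision-cell residence
   time τ (default 1 ms), so k = ln 2/τ; Eyring turns each rate into a
   quasi-equilibrium constant K = k·h/(k_B·T_eff);
4. van't Hoff regression of ln K on 1/T_eff over the charge ladder gives
   ΔH (slope) and ΔS/R (intercept); the regression line evaluated at
   T_amb = 298 K gives K_D, hence ΔG = −R·T_amb·ln K_D and
   TΔS = ΔH − ΔG (both identities exact by construction); the Arrhenius
   intercept evaluated at 298 K gives the apparent rate constant.

With a single charge state the temperature series is lost and the chain
falls back to the midpoint rate alone (ΔH, TΔS undetermined).  The chain
also accepts externally supplied per-charge rate constants, which makes it
exactly invertible: a forward simulator that chooses (ΔH, ΔS) and builds
the ladder through the inverse chain is recovered to regression precision.

Limitations, stated plainly: with the default midpoint rate (constant
k = ln 2/τ), ln K is a pure function of T_eff, so the recovered ΔH sits
near −R·T̄_eff ≈ −2.6 kJ/mol regardless of the course; absolute rate and
equilibrium constants depend on τ and n_collisions, which the source
protocol does not publish.  Absolute published values (~10¹² 1/s, ~10⁻¹²)
are therefore **not** reproduced or claimed — only the internal identities,
orderings, and round trips are.  Binder groups: IV when no complex signal
exists at the lowest step, III when complex exists but no valid transition,
otherwise I (ΔH > −2 kJ/mol) or II (ΔH ≤ −2 kJ/mol).

## ITC single-site model

Injection heats follow the Wiseman isotherm: the bound-site fraction Θ
solves Θ² − Θ(1 + L/(nM) + 1/(n·K_A·M)) + L/(nM) = 0 (smaller root), with
per-injection perfusion dilution of both cell species by (1 − dV/V0) — the
standard fixed-volume overflow correction, which also expels a share of
formed complex.  The heat of injection i is the change in cell heat content
V0·n·M_i·Θ_i·ΔH minus the expelled share.  Fitting runs over
(log10 K_A, ΔH, n) with bounds and a small multistart; the first injection
is excluded by default (syringe-tip diffusion).  Flat heat traces (every
|q| below a configurable 0.5 µJ floor) are refused as "not binding".
Derived values are exact: K_D = 1/K_A, ΔG = −RT ln K_A (K_A referenced to
1 M), TΔS = ΔH − ΔG.

## Synthetic data

The generator emulates the deposited raw data's layout: heavy-species
charge envelopes (Gaussian over charge, default centered at 25 with width
1.2 over 23–27), educt decay following a chosen Boltzmann course (default:
the wild-type course parameters 77.36%, 36.24%, 30.0 V, 15.2 V over the
13-step schedule), a 0.7/0.3 occupancy split toward the singly bound
complex (the singly bound signal is the most intense in the real spectra;
the true split is not published), released peptide at 2+/3+ growing with
the cumulatively dissociated educt, optional sodiated 2+ satellites
(+21.981943 Da) and optional broadband antibody-fragment signal at
m/z 1200–2300 (off by default).  The free-antibody height takes up the
balance so the species heights sum to the recipe's total intensity, which
also makes the normalized educt fraction equal the generating curve
exactly.  Additive Gaussian noise (SD relative to the total intensity) is
applied per grid point and clipped at zero; everything is deterministic
given the recipe seed.

Two rendering choices make the generator exactly invertible by the
processing chain and are deliberate idealizations: every peak shares one
Gaussian m/z width (default 3 Th), and peak centers are quantized to the
m/z grid (default 0.25 Th).  Smoothing then attenuates every peak by one
common factor and height ratios survive the pipeline unchanged, so the
noise-free closed loop is exact to ~1e−14.  What the generator does *not*
emulate: isotope fine structure, charge-dependent peak widths, detector
saturation, chemical background, or calibration drift — passing closed-loop
tests therefore validate the algebra and the estimators, not robustness to
every real-data artifact.

ITC titrations are simulated from the same Wiseman forward model at the
real experiment's geometry (190 µL cell, 1.95 µM antibody, 40 µM peptide,
19 × 2 µL injections) with additive per-injection heat noise in µJ.

## Problem sizes and numerics

Simulated series use a 0.25 Th grid over m/z 400–8000 (13 spectra of ~30k
points), processed in ~0.3 s.  Stochastic recovery statements use 2000
seeded replicates of the 13-point course (median midpoint recovered within
0.5 V of the generating 30.0 V); ITC recovery uses 100 replicates at 2%
heat noise (median errors below 5% for ΔH and 15% for K_A at the default
c-value ≈ 9).  Physical constants come from scipy.constants; masses from
pyteomics (proton 1.007276 Da, water 18.010565 Da).  Reported rounding:
masses 3 dp, m/z 2 dp.
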