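# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `sodmimic`, in the spirit of the methods
documentation of packages like lmfit or statsmodels.

## Mass engine

Element monoisotopic masses and isotope abundances come from the NIST
table shipped with pyteomics (`pyteomics.mass.nist_mass`); amino-acid
residue compositions from `pyteomics.mass.std_aa_comp`. These tables are
the single source of truth — no mass constant is duplicated elsewhere.
A peptide's composition is the residue sum plus H₂O for a free acid or
NH₃ (replace terminal OH by NH₂) for an amide, plus modification deltas:
acetyl +C₂H₂O (N-terminus), Nε-methyl +CH₂ and Nε-tosyl +C₇H₆O₂S (both
legal only on His1).

**Charge-carrier convention.** Protonated m/z uses the *charged* adduct
masses: proton 1.00727646688 Da and Na⁺ 22.98922070 Da, i.e. the
electron is removed from the adduct. This convention reproduces all
eight model-peptide [M+H]⁺ calc. values to ≤ 5×10⁻⁶ Da; the H-atom
convention (1.0078250 Da) misses them by ~0.5 mDa.

**Ni(II) adducts.** The elemental delta for a bound Ni defaults to
+Ni −2H (Ni(II) displacing two protons). Calculated masses of
Ni(II)-peptide ions are sensitive to the electron/proton bookkeeping a
vendor tool applies and differ between conventions by fractions of a
mDa; the delta is therefore configurable, and no Ni-complex mass is
used as a reference value in the tests.

**Isotope patterns** are computed by iterated convolution: each
element's natural isotope distribution is expressed on an integer grid
of bin width 0.01 Da (default), raised to the atom count by binary
exponentiation of sparse convolutions, and multiplied across elements.
Peaks below 10⁻⁴ of the base peak (default) are dropped and the result
renormalized to sum 1. At 0.01 Da binning, isotopologues within one
nominal mass (¹³C vs ¹⁵N vs ²H) partially split into adjacent bins;
envelope *comparison* therefore uses a coarser 0.05 Da grid (below),
matching the ~unit-resolved TOF envelopes the method targets. Fine
isotopic structure is not modeled.

## Degradation-species model

A degradation species of a two-cysteine base peptide is
(n, d, k): an n-mer joined by d disulfides carrying k added oxygens,
with composition n·base − 2d·H + k·O. Constraints: a connected n-mer
needs d ≥ n−1; the 2n cysteines cap d at n (the d = n case is a chain
plus one intramolecular ring; for n = 1 it is the intramolecular-
disulfide monomer). Defaults enumerate n ≤ 4, d ∈ {n−1, n}, k ≤ 7,
charges 1–3, H⁺ and Na⁺ adducts. Oxygen *placement* (sulfenate /
sulfinate / sulfonate, cystine-S-oxides) is mass-isomeric and not
modeled; only the additive O count matters.

Peak assignment matches each observed m/z against all candidates within
a ppm tolerance (default 5 ppm — a typical calibrated-TOF accuracy;
no instrument value is asserted) and ranks matches by isotope-envelope
cosine similarity (when envelopes are available) then |ppm|. The cosine
is computed after binning both envelopes on a shared 0.05 Da grid;
disjoint envelopes score 0. Note that a protonated monomer and a
doubly-protonated disulfide dimer differ only by ~0.7 ppm (an electron
mass plus 2×(H − SS/2) bookkeeping); such near-isobars are separable
only by envelope spacing, which is why the ranking prefers the isotope
score over the mass error.

## Kinetics

The mixed-order superoxide decay −da/dt = k₂a² + k_obs·a has the closed
form a(t) = a₀e^(−k_obs t) / ((k₂/k_obs)a₀(1−e^(−k_obs t)) + 1) + C.
Numerics:

* (1−e^(−kt))/k is evaluated via `expm1` for accuracy at small kt;
  the exponent is clamped at 700 so large k_obs·t tends cleanly to C;
* at k_obs < 10⁻⁹ s⁻¹ the expression is replaced by its limit, the
  classical second-order law a₀/(1 + k₂a₀t) + C, avoiding 0/0;
* the independent check integrates the ODE with `scipy.solve_ivp`
  (DOP853, rtol 10⁻¹², atol 10⁻¹⁴·a₀); closed form and integration
  agree to < 10⁻⁹·a₀ across the physical parameter ranges
  (a₀ ∈ [10⁻⁵, 10⁻³] M, k₂ ∈ [10³, 10⁵] M⁻¹s⁻¹, k_obs ∈ [1, 500] s⁻¹).

Units are seconds and molar throughout the math layer; absorbance is
converted via Beer–Lambert (A = ε·l·c) only at I/O boundaries. The
offset C is kept in concentration units during fitting.

## Trace fitting

* **Preprocessing.** Replicates (typically 5–10) sharing wavelength and
  concentration are averaged pointwise on the first trace's grid
  (linear interpolation if grids differ); an optional blank (buffer/DMSO
  mixing) is subtracted; the first 5 ms are always discarded.
* **Windows.** Catalyzed fits use 5–500 ms; above 30 µM catalyst the
  window end shortens to 350 ms because the decaying Ni(II)-peptide
  absorbance contaminates the tail. The windowing test demonstrates the
  motivating property: with a degradation-like baseline enabled in the
  generator, the shorter window strictly reduces the k_obs bias.
* **Optimizer.** lmfit trust-region least squares, numerical Jacobian,
  max 500 evaluations, bounds [0, ∞) on a₀, k₂, k_obs and ±0.1 on C
  (concentration units), up to 3 seeded random restarts from perturbed
  initial guesses on non-convergence, then a hard error. Initial
  guesses: C from the final 5% of points, a₀ from the first point,
  k_obs from the log-linear slope of the first third of the window.
* **Order of operations.** k₂ (and k₁) come from the uncatalyzed run and
  k₂ is held fixed during catalyzed fits; a co-fit mode
  (`fix_k2=False`) exists. Replicates are averaged before fitting;
  fitting each replicate and averaging afterwards is possible through
  the same API but is not the default.
* **Activity regression.** k_obs vs b is fit by weighted least squares
  with weights 1/SE², treating the per-point SEs as *known* variances
  (fixed-scale covariance) rather than re-estimating the error scale
  from the 3 residual degrees of freedom of a five-point line; when the
  points scatter more than their SEs claim (χ²/dof > 1) the parameter
  SEs are inflated by √(χ²/dof). In repeated synthetic campaigns this
  gives ≈93% empirical coverage for the nominal 2-SE interval.
* **Degradation fits** operate in absorbance units (the 258–262 nm and
  460 nm chromophore extinctions differ from the 250 nm superoxide
  value, so no conversion is attempted). t½ = ln2/k with SE by linear
  propagation (SE(t½) = ln2·SE(k)/k²). Rising traces are flagged;
  traces shorter than three half-lives warn that the plateau is poorly
  constrained.

## Synthetic data

The generators emulate the assay conditions the fitters assume:

* superoxide traces: 1 kHz sampling, duration up to 4 s (1 s default in
  campaigns, ample for k_obs ≥ 5 s⁻¹), a₀ = 10⁻⁴ M, ε = 2000 M⁻¹cm⁻¹,
  path 1 cm, iid Gaussian noise σ = 0.002 AU. True instrument noise is
  not documented anywhere; this default makes recovery tests
  discriminating rather than matching any hardware.
* mixing artifact: an exponential spike strictly confined to t < 5 ms,
  consistent with the discard rule (its shape within the discarded
  region is a free choice).
* baseline drift: off by default; the "first-order" kind adds
  amplitude·e^(−t·ln2/16) in AU, mimicking the disappearing
  Ni(II)-peptide absorbance with its ~16 s half-life.
* campaigns: five concentrations 10–50 µM × five replicates plus five
  background runs, truth k_cat = 2×10⁶ M⁻¹s⁻¹, k₁ = 5 s⁻¹,
  k₂ = 2×10⁴ M⁻¹s⁻¹; child seeds are spawned from one `SeedSequence`.
* spectra: theoretical m/z × (1 + N(0, σ_ppm·10⁻⁶)), relative intensity
  noise, uniform decoy peaks, optional per-peak envelopes scaled by the
  peak intensity.

What the generators do **not** model: photodiode shot-noise spectra and
drift correlations, KO₂/crown-ether mixing chemistry, chromatographic
profiles, isotope-envelope interference between co-eluting species, and
detector saturation. Passing recovery tests therefore demonstrates the
*statistical* soundness of the estimators under the stated noise model,
not robustness to every instrument pathology.

## Problem sizes used in the shipped checks

Mass targets are desk-scale (exact). The stochastic checks use: 100
parameter draws for the closed-form/ODE sweep; one 5×5-replicate
campaign for headline k_cat recovery (plus 200 repeated campaigns for
bias/coverage); 100 noisy degradation traces for coverage; 50 repeats
for the window-bias property; 20 truth species + 15 decoys for
assignment recovery. These sizes give stable pass/fail behaviour under
reseeding while keeping the suite quick.

## Known limitations

* The activity pipeline assumes the closed-form law holds over the
  whole window; mechanistic multi-species schemes (e.g. explicit
  Ni(III)/Ni(II) cycling) are out of scope.
* Degradation half-lives assume a single exponential; biphasic decays
  are not detected beyond fit diagnostics.
* Mixed oligomers of *different* base peptides are not enumerated.
* Average (not monoisotopic) masses and MS² fragment prediction are not
  provided.
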