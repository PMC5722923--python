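# sodmimic

Quantitative analysis of nickel superoxide dismutase (NiSOD) **model
peptides**: stopped-flow superoxide-decay kinetics, Ni(II)-peptide
degradation half-lives, and mass-spectrometric identification of
oxidative degradation products.

## Who this is for

Bioinorganic and peptide chemists who assay short Ni-hook mimics
(HCDLPCG-NH₂ and variants) for SOD activity and oxidative stability.
The package turns raw two-column stopped-flow traces and centroided ESI
peak lists into catalytic rate constants, half-lives and annotated
species tables — and ships seeded synthetic-data generators so the whole
chain is testable without instrument data.

## The science in brief

**Activity.** In a stopped-flow assay, superoxide (followed at 250 nm,
ε = 2000 M⁻¹ cm⁻¹) decays by two parallel routes — second-order
self-disproportionation and pseudo-first-order catalyzed decay:

    -da/dt = k₂ a² + k_obs a

with closed-form solution (C an offset)

    a(t) = a₀ e^(−k_obs t) / ((k₂/k_obs) a₀ (1 − e^(−k_obs t)) + 1) + C

The catalytic rate decomposes as **k_obs = k₁ + b·k_cat**: fitting
traces at several catalyst concentrations *b* and regressing k_obs on
*b* gives the catalytic rate constant k_cat (M⁻¹ s⁻¹) as the slope.
An uncatalyzed run pins down k₂ and the background rate k₁ first; the
first 5 ms of every trace (mixing artifact) are discarded, and the fit
window shortens from 500 ms to 350 ms above 30 µM catalyst, where the
peptide's own degradation distorts the baseline.

**Stability.** The Ni(II)-peptide chromophore (≈260 nm and 460 nm bands)
decays first-order under the oxidative load; its half-life is
t½ = ln 2 / k.

**Degradation products.** Oxidation converts the two-cysteine peptides
into disulfide-bridged n-mers (composition n·M − 2d·H + k·O for d
bridges and k added oxygens). The package enumerates these species,
predicts exact m/z under the charged-proton convention, simulates
isotope envelopes by per-element convolution, and annotates peak lists
by ppm error and envelope cosine similarity.

## Worked example

```sh
python examples/activity_campaign.py
```

```
background run: k2 = 1.991e+04 M^-1 s^-1, k1 = 4.97 s^-1
  b =   10 uM: k_obs =  24.877 +/- 0.067 s^-1  (window 0.005-0.50 s)
  b =   20 uM: k_obs =  44.957 +/- 0.160 s^-1  (window 0.005-0.50 s)
  b =   30 uM: k_obs =  64.884 +/- 0.312 s^-1  (window 0.005-0.50 s)
  b =   40 uM: k_obs =  85.339 +/- 0.474 s^-1  (window 0.005-0.35 s)
  b =   50 uM: k_obs = 104.714 +/- 0.765 s^-1  (window 0.005-0.35 s)
k_cat = 2.006e+06 +/- 9e+03 M^-1 s^-1, intercept k1 = 4.82 s^-1, R^2 = 0.99998
truth k_cat = 2e+06 M^-1 s^-1
```

The campaign was generated with truth k_cat = 2×10⁶ M⁻¹ s⁻¹ and 0.002 AU
Gaussian noise; the pipeline recovers the slope to 0.3% with a fully
linear k_obs-vs-b correlation. The other examples cover peptide masses
(`peptide_masses.py`), the closed-form/ODE agreement
(`superoxide_kinetics.py`), half-life fitting
(`degradation_half_life.py`) and degradation-species annotation
(`species_assignment.py`).

A thin CLI wraps the same workflows:

```sh
sodmimic simulate --kind activity --out camp --seed 5
sodmimic fit-activity --manifest camp/manifest.yaml --out report.json
sodmimic fit-degradation --trace deg.csv --wavelength 260
sodmimic assign-species --peaks peaks.csv --peptide "HCDLPCG-NH2"
sodmimic peptide-mass "{ac-}HCDLPCG-NH2"
```

Peptide spec grammar: `[{modtag-}]SEQUENCE[-NH2]` with built-in mods
`ac` (N-terminal acetyl, +C₂H₂O), `meH` (His1 Nε-methyl, +CH₂) and
`tosH` (His1 Nε-tosyl, +C₇H₆O₂S); `-NH2` marks an amidated C-terminus.

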