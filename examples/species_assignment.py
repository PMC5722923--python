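"""Identifying oxidative degradation products in a simulated spectrum.

Superoxide treatment turns the two-cysteine model peptides into
disulfide-bridged dimers, trimers and tetramers carrying extra oxygen
atoms on sulfur.  This script enumerates all such species of HCDLPCG-NH2
(up to tetramers, up to 7 added oxygens, charges 1-3), simulates a
centroided ESI peak list from a random subset plus decoy peaks, and
re-assigns every peak by exact mass at 5 ppm.  All truth peaks should be
recovered; decoys should stay unassigned.
"""

import numpy as np

from sodmimic import (
    SpectrumGeneratorConfig,
    assign_peaks,
    enumerate_species,
    parse_peptide,
    simulate_spectrum,
)

base = parse_peptide("HCDLPCG-NH2")
candidates = enumerate_species(base, n_max=4, k_max=7, charges=(1, 2, 3), adducts=("H",))
print(f"{len(candidates)} candidate species enumerated")

rng = np.random.default_rng(7)
truth = tuple(candidates[i] for i in rng.choice(len(candidates), size=8, replace=False))
peaks, truth_out = simulate_spectrum(
    SpectrumGeneratorConfig(species=truth, mz_jitter_ppm=1.0, n_decoys=6, seed=21)
)

assignments = assign_peaks(peaks, candidates, tol_ppm=5.0)
recovered = 0
for i in range(len(peaks)):
    matches = assignments[i]
    is_truth = i < len(truth_out)
    if matches:
        top = matches[0]
        tag = "truth" if is_truth else "decoy"
        recovered += is_truth and any(a.species == truth_out[i] for a in matches)
        print(f"{peaks.mz[i]:10.5f} ({tag}) -> {top.species.label}  {top.ppm_error:+.2f} ppm")
    else:
        print(f"{peaks.mz[i]:10.5f} ({'truth' if is_truth else 'decoy'}) -> unassigned")
print(f"recovered {recovered}/{len(truth_out)} truth species")
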