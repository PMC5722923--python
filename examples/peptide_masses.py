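"""Exact masses of the Ni-hook model peptides.

Builds each of the eight synthesized peptides (HCDLPCG-NH2 and variants)
from its spec string and prints the elemental formula, the neutral
monoisotopic mass and the protonated m/z.  The [M+H]+ values use the
charged-proton convention (1.0072765 Da) and should match the values a
TOF instrument's calibration software would report.
"""

from sodmimic import adduct_mz, parse_peptide

PEPTIDES = [
    "HCDLPCG-NH2",
    "{meH-}HCDLPCG-NH2",
    "ACDLPCG-NH2",
    "{ac-}HCDLPCG-NH2",
    "QCDLPCG-NH2",
    "{tosH-}HCDLPCG-NH2",
    "HCDLPCGVY-NH2",
    "HCDLPCGVYDPA-NH2",
]

print(f"{'peptide':24s} {'formula':22s} {'M (Da)':>12s} {'[M+H]+':>12s} {'[M+2H]2+':>12s}")
for spec in PEPTIDES:
    pep = parse_peptide(spec)
    m = pep.monoisotopic_mass()
    print(
        f"{spec:24s} {pep.composition().hill_formula():22s} "
        f"{m:12.5f} {adduct_mz(m, 'H', 1):12.5f} {adduct_mz(m, 'H', 2):12.5f}"
    )
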