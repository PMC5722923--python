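import pytest

from sodmimic import parse_peptide

# The eight synthesized model peptides with their calculated [M+H]+ values
# (charged-proton convention, printed to 5 decimals).
PRINTED_MH = [
    ("HCDLPCG-NH2", 743.29634),
    ("{meH-}HCDLPCG-NH2", 757.31199),
    ("ACDLPCG-NH2", 677.27454),
    ("{ac-}HCDLPCG-NH2", 785.30691),
    ("QCDLPCG-NH2", 734.29601),
    ("{tosH-}HCDLPCG-NH2", 897.30519),
    ("HCDLPCGVY-NH2", 1005.42808),
    ("HCDLPCGVYDPA-NH2", 1288.54490),
]


@pytest.fixture(scope="session")
def base_peptide():
    """The seven-residue Ni-hook model peptide, amidated C-terminus."""
    return parse_peptide("HCDLPCG-NH2")
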