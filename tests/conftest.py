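import pytest

# N-terminal stretches of the three proteins whose processing states anchor
# the screen's worked examples (human AK2, EIF2A, STXBP2).
AK2_NTERM = "MAPSVPAAEPEYPKGIRAVLLGPPGAGKGTQAPRLAENFCVCHLA"
EIF2A_NTERM = "MAPSTPLLTVRGSRASALHAWSLHAEGDSLLIATQ"
STXBP2_NTERM = "MAPSGLKAVVGEKIMHDVIKKVKKKGEWKVLVVDQ"


@pytest.fixture
def ak2_seq() -> str:
    return AK2_NTERM


@pytest.fixture
def eif2a_seq() -> str:
    return EIF2A_NTERM


@pytest.fixture
def stxbp2_seq() -> str:
    return STXBP2_NTERM


@pytest.fixture
def toy_fasta(tmp_path):
    """Six-record CCDS-dialect proteome: two hidden IBMs (AK2, EIF2A) planted."""
    entries = {
        "CCDS1.1|AK2": AK2_NTERM,
        "CCDS2.1|EIF2A": EIF2A_NTERM,
        "CCDS3.1|STXBP2": STXBP2_NTERM,
        "CCDS4.1|ASPD": "MDAVTKLLERSGHKLMNPQ",  # D at position 2: no rule applies
        "CCDS5.2|MPST": "MPSTARRGGELLKWYHNDE",  # DPP9 short site, STAR fails the IBM
        "CCDS6.1|CTRL": "GSSHHHHHHSSGLVPRGSH",  # no initiator methionine
    }
    path = tmp_path / "toy.fasta"
    with path.open("w") as fh:
        for header, seq in entries.items():
            fh.write(f">{header}\n{seq}\n")
    return path


@pytest.fixture
def toy_gene_map(tmp_path):
    path = tmp_path / "genes.tsv"
    rows = [
        ("CCDS1", "AK2"),
        ("CCDS2", "EIF2A"),
        ("CCDS3", "STXBP2"),
        ("CCDS4", "ASPD"),
        ("CCDS5", "MPST"),
        ("CCDS6", "CTRL"),
    ]
    path.write_text("\n".join(f"{a}\t{g}" for a, g in rows) + "\n")
    return path
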