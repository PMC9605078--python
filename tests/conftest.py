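import pytest
from hypothesis import HealthCheck, settings

from pepsilico import load_enzyme_rules, load_motif_db
from pepsilico.fixtures import load_fixture
from pepsilico.peptide import AminoAcidTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: The 11 distinct screened peptides of the study input.
STUDY_PEPTIDES = [
    "GPPGPQWPLDF",
    "GPPGPRGPTGRMG",
    "GPGGPGPGM",
    "APDMAFPR",
    "GGFPGGPG",
    "GPGMMGP",
    "GPPGASGPLGIAGSM",
    "GPSGPPGP",
    "GEPFPKF",
    "PGGPGPGM",
    "DPIFFPS",
]


@pytest.fixture(scope="session")
def motif_db():
    return load_motif_db()


@pytest.fixture(scope="session")
def rules():
    return load_enzyme_rules()


@pytest.fixture(scope="session")
def aa_table():
    return AminoAcidTable.default()


@pytest.fixture(scope="session")
def table1_items():
    from pepsilico import RankedPeptide, parse_peptide

    fixture = load_fixture("table1")
    return [
        RankedPeptide(
            peptide=parse_peptide(row["sequence"]),
            score=float(row["score"]),
            sample_label=row["sample"],
        )
        for row in fixture.rows
    ]


def brute_force_scan(sequence: str, fragments: list[str]) -> set[tuple[str, int, int]]:
    """Independent O(N * |DB| * L) substring oracle for the motif scanner."""
    hits = set()
    for frag in fragments:
        for start in range(len(sequence) - len(frag) + 1):
            if sequence[start : start + len(frag)] == frag:
                hits.add((frag, start + 1, start + len(frag)))
    return hits
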