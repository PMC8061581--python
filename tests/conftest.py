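import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from barcode_audit.io_qc import SpecimenRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# a stop-free 658-bp frame: ACT codons are >=2 substitutions away from
# TAA/TAG, so single-site edits in tests can never create a stop codon
CLEAN_BASE = ("ACT" * 220)[:658]


def make_record(
    specimen_id: str,
    species: str = "Aus bus",
    sequence: str = CLEAN_BASE,
    genus: str = "Aus",
    family: str = "Aidae",
    region: str = "mid_latitude",
) -> SpecimenRecord:
    return SpecimenRecord(
        specimen_id=specimen_id, species=species, genus=genus,
        family=family, region=region, sequence=sequence,
    )


def mutate(sequence: str, position_1based: int, base: str) -> str:
    i = position_1based - 1
    return sequence[:i] + base + sequence[i + 1 :]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def clean_base():
    return CLEAN_BASE
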