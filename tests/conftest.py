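import pytest
from hypothesis import HealthCheck, settings

from srnaprofiler.sequence_io import CatalogEntry

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def toy_catalog() -> list[CatalogEntry]:
    """Four mature miRNAs across two families; miR901a/b identical (merge
    candidates), miR901c distinct within the family, miR902a separate."""
    m901 = "TGACAGAAGAGAGTGAGCACA"  # 21 nt
    m901c = "TTGACAGAAGATAGAGAGCAC"  # same family, different sequence
    m902 = "TTTGGATTGAAGGGAGCTCTA"
    flank5, flank3 = "GGGGGTTTTTCCCCC", "AAAAACCCCCGGGGG"
    return [
        CatalogEntry("zma-miR901a", "miR901", m901, flank5 + m901 + flank3),
        CatalogEntry("zma-miR901b", "miR901", m901, "ACGTACGTACGTACG" + m901 + "TGCATGCATGCATGC"),
        CatalogEntry("zma-miR901c", "miR901", m901c, None),
        CatalogEntry("zma-miR902a", "miR902", m902, flank5 + m902 + flank3),
    ]
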