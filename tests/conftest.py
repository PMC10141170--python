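import pytest
from hypothesis import HealthCheck, settings

from glycomod.taxonomy import Lineage

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_lineage(genus: str, species: str, family: str = "Bacteroidaceae") -> Lineage:
    return Lineage(
        domain="Bacteria",
        phylum="Bacteroidota",
        klass="Bacteroidia",
        order="Bacteroidales",
        family=family,
        genus=genus,
        species=species,
    )


@pytest.fixture(scope="session")
def bacteroides_taxonomy() -> dict[str, Lineage]:
    """Small reference taxonomy of gut Bacteroides / relatives."""
    return {
        "refA": make_lineage("Bacteroides", "Bacteroides faecis"),
        "refB": make_lineage("Bacteroides", "Bacteroides thetaiotaomicron"),
        "refC": make_lineage("Bacteroides", "Bacteroides uniformis"),
        "refD": make_lineage("Parabacteroides", "Parabacteroides distasonis",
                             family="Tannerellaceae"),
    }
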