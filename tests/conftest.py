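import pytest
from hypothesis import settings

from metazoanome.ortho_model import GeneID, GroupCollection, OrthologGroup
from metazoanome import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_group(gid: str, codes, paralogs=()) -> OrthologGroup:
    """Group with one gene per species code plus optional extra paralogs."""
    members = [GeneID(c, f"{gid}_{i}") for i, c in enumerate(codes)]
    members += [GeneID(c, f"{gid}_p{i}") for i, c in enumerate(paralogs)]
    return OrthologGroup(group_id=gid, members=frozenset(members))


SMALL_COUNTS = {
    "metazoan_core": 20,
    "eumetazoan_core_no_focal": 10,
    "eukaryote_core": 15,
    "clade_restricted": 15,
    "promiscuous": 10,
    "contaminated_metazoan": 10,
}


@pytest.fixture(scope="session")
def schema():
    return synthetic.default_schema()


@pytest.fixture(scope="session")
def small_world():
    return synthetic.generate_world(
        synthetic.WorldConfig(n_groups=SMALL_COUNTS, seed=7)
    )
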