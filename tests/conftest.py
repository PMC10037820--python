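import pytest

from founderera.simulate import SimConfig, noiseless_config, simulate_dataset
from founderera.taxonomy import TaxonNode, TaxonomyDB, focal_lineage


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Exact-recovery regime: no noise, no loss, no contamination, slow decay."""
    return simulate_dataset(noiseless_config(seed=7), tmp_path_factory.mktemp("sim_noiseless"))


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Default study conditions: 5% score noise, 5% ring-loss rate."""
    return simulate_dataset(SimConfig(seed=11), tmp_path_factory.mktemp("sim_noisy"))


def build_db(rows):
    """TaxonomyDB from (taxid, parent, rank, name) tuples."""
    return TaxonomyDB({t: TaxonNode(t, p, r, n) for t, p, r, n in rows})


@pytest.fixture
def chain_db():
    """species(1) < genus(2) < family(3) < root(4), with ring species
    20x diverging at the genus level, 30x at family, 40x at root."""
    rows = [
        (1, 2, "species", "focal"),
        (2, 3, "genus", "genus_A"),
        (3, 4, "family", "family_A"),
        (4, 4, "no rank", "root"),
        (21, 2, "species", "sib_genus"),
        (31, 3, "species", "sib_family"),
        (41, 4, "species", "sib_root"),
    ]
    return build_db(rows)


@pytest.fixture
def chain_lineage(chain_db):
    return focal_lineage(chain_db, 1)
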