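import pytest

from mgotu.core_io import MGDatabase
from mgotu.fixtures import make_species_clusters
from mgotu.mg_database import extend_database


@pytest.fixture(scope="session")
def planted_genomes():
    """Five well-separated species, one genome each, with planted labels."""
    genomes, truth = make_species_clusters(
        5, 1, within_id=0.99, between_id=0.88, seed=101
    )
    return genomes, truth


@pytest.fixture(scope="session")
def small_db(planted_genomes):
    """Database built from the five planted species."""
    genomes, _truth = planted_genomes
    db, report = extend_database(MGDatabase.empty(version="test"), genomes)
    assert report.n_new_motus == 5
    return db
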