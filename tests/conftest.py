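import numpy as np
import pytest

from maveritax import marker_detection, synthetic, taxonomy


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_spec():
    """Three families of ten genomes — big enough for profile building
    (clusters of >= 10) but quick to generate and classify."""
    return synthetic.FixtureSpec(
        seed=7,
        n_families=3,
        genomes_per_family=10,
        genome_length_range=(12000, 16000),
        n_decoy_genes=4,
        n_plv_genomes=2,
        n_decoys=1,
    )


@pytest.fixture(scope="session")
def small_set(small_spec):
    return synthetic.generate_fixture_set(small_spec)


@pytest.fixture(scope="session")
def small_profiles(small_set):
    return marker_detection.build_marker_profiles(small_set.marker_proteins)


@pytest.fixture(scope="session")
def small_db(small_set):
    return taxonomy.FamilyReferenceDB(
        sequences=small_set.reference_mcp, labels=small_set.reference_labels
    )


@pytest.fixture(scope="session")
def small_cutoffs(small_db):
    return taxonomy.derive_cutoffs(small_db)
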