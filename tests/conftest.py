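import numpy as np
import pytest

from pccr.annotation import build_cirs
from pccr.catalog import CatalogParams, build_catalog
from pccr.energies import build_kmer_table
from pccr.fixtures import FixtureSpec, make_toy_genome, make_toy_tracks


@pytest.fixture(scope="session")
def k5_table():
    return build_kmer_table(5, 2)


@pytest.fixture(scope="session")
def small_toy():
    """10-gene toy genome with 24 planted panhandles."""
    return make_toy_genome(FixtureSpec(seed=7, n_genes=10, n_panhandles=24))


@pytest.fixture(scope="session")
def small_cirs(small_toy):
    return build_cirs(small_toy.genes, small_toy.conserved)


@pytest.fixture(scope="session")
def small_catalog(small_toy, small_cirs, k5_table):
    return build_catalog(
        small_toy.genes, small_cirs, small_toy.genome, CatalogParams(),
        table=k5_table,
    )


@pytest.fixture(scope="session")
def small_tracks(small_toy):
    return make_toy_tracks(small_toy.spec, small_toy)


@pytest.fixture(scope="session")
def big_toy():
    """The 50-gene / 120-panhandle study-condition fixture."""
    return make_toy_genome(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def big_catalog(big_toy, k5_table):
    cirs = build_cirs(big_toy.genes, big_toy.conserved)
    return build_catalog(
        big_toy.genes, cirs, big_toy.genome, CatalogParams(), table=k5_table
    )
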