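import numpy as np
import pytest

from eukfinder.simulate import (
    MockCommunitySpec,
    build_titration_series,
    generate_genomes,
    simulate_background,
    simulate_euk_pool,
)
from eukfinder.taxonomy import TaxonomyMap, build_kmer_index


@pytest.fixture(scope="session")
def toy_taxmap() -> TaxonomyMap:
    """A hand-built taxonomy: one species per superkingdom plus nested euks."""
    nodes = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        2157: (1, "superkingdom", "Archaea"),
        10239: (1, "superkingdom", "Viruses"),
        2759: (1, "superkingdom", "Eukaryota"),
        562: (2, "species", "Escherichia coli"),
        2287: (2157, "species", "Sulfolobus"),
        10710: (10239, "species", "phage lambda"),
        4932: (2759, "species", "Saccharomyces"),
        49977: (4932, "no rank", "yeast mitochondrion"),
        7777: (7777, "no rank", "orphan-selfloop"),
    }
    return TaxonomyMap(nodes)


@pytest.fixture(scope="session")
def tiny_spec() -> MockCommunitySpec:
    """A minutes-not-hours community for unit/integration tests."""
    return MockCommunitySpec(
        n_background=3,
        background_genome_size=50_000,
        euk_genome_size=40_000,
        mito_size=5_000,
        total_background_reads=4_000,
        euk_read_levels=(1_000, 2_000),
        replicates=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_refs(tiny_spec):
    return generate_genomes(tiny_spec)


@pytest.fixture(scope="session")
def tiny_db(tiny_refs):
    return build_kmer_index(tiny_refs.ref_entries())


@pytest.fixture(scope="session")
def tiny_communities(tiny_spec, tiny_refs):
    bg, bg_truth = simulate_background(tiny_refs, tiny_spec)
    pool, pool_truth = simulate_euk_pool(tiny_refs, tiny_spec)
    return build_titration_series(
        bg,
        bg_truth,
        pool,
        pool_truth,
        tiny_spec.euk_read_levels,
        tiny_spec.replicates,
        seed=tiny_spec.seed,
        refs=tiny_refs,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
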