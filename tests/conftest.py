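import pytest

from mytipav.synthetic_data import SimConfig, default_seed, generate_cohort
from mytipav.translated_search import recover_variants

#: fixed raw-score threshold for fixture searches: far above the shuffled
#: null (best null scores are ~40-60) and far below real hits (>400)
FIXTURE_MIN_SCORE = 120.0


@pytest.fixture(scope="session")
def seed_precursor():
    return default_seed()


@pytest.fixture(scope="session")
def small_cohort():
    """3 individuals x 3 clusters x 2 alleles, everything retained."""
    cfg = SimConfig(
        n_individuals=3,
        n_clusters=3,
        alleles_per_cluster=2,
        retention_prob_per_cluster=1.0,
        pseudogene_prob=0.0,
        contig_length=4000,
        rng_seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def pseudo_cohort():
    """Panel with pseudogenized copies and partial retention."""
    cfg = SimConfig(
        n_individuals=4,
        n_clusters=4,
        alleles_per_cluster=2,
        retention_prob_per_cluster=0.8,
        pseudogene_prob=0.3,
        contig_length=4000,
        rng_seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_search(small_cohort):
    seed = small_cohort.panel.seed
    return recover_variants(
        small_cohort.genomes,
        seed.protein,
        seed.annotation.mature,
        min_score=FIXTURE_MIN_SCORE,
    )
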