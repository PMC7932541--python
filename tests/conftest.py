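import numpy as np
import pytest

from srescan import augment, cnn, couples, fixtures


TINY_FIXTURE_CONFIG = fixtures.FixtureConfig(
    n_chromosomes=2,
    chrom_length=100_000,
    n_positive_pairs=12,
    n_control_peaks=60,
    n_genes=30,
    go_n_terms=8,
    go_genes_per_term=12,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def tiny_fixture() -> fixtures.Fixture:
    """A small but complete synthetic data set shared across module tests."""
    return fixtures.make_fixture(TINY_FIXTURE_CONFIG)


@pytest.fixture(scope="session")
def small_training_data(tiny_fixture):
    """Balanced labeled windows derived from the tiny fixture."""
    fx = tiny_fixture
    pairs = couples.find_couples(fx.sre_peaks, fx.nfy_peaks)
    pos = couples.positive_windows(pairs, fx.genome)
    neg = couples.build_negative_set(
        fx.control_peaks, fx.sre_peaks, fx.nfy_peaks, fx.genome
    )
    tracks = [fx.conservation[w.chrom].slice(w.start, w.end) for w in pos]
    augmented = augment.augment_set(
        pos, tracks, augment.AugmentConfig(copies_per_seed=4, rng_seed=11)
    )
    n = min(len(augmented), len(neg))
    return augment.split_train_val(
        augmented[:n] + neg[:n], augment.AugmentConfig(rng_seed=11)
    )


@pytest.fixture(scope="session")
def tiny_model() -> cnn.SREClassifier:
    """An untrained small network for structural tests."""
    return cnn.build_model(
        cnn.ModelConfig(n_filters=32, kernel_size=6, rng_seed=5)
    )
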