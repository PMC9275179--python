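import numpy as np
import pytest

from methylga.platforms import Platform
from methylga.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def two_class_cohort():
    """Clearly separated 2-class cohort (informative loci first)."""
    spec = CohortSpec(
        n_samples_per_class=10,
        class_labels=(("A", True), ("B", True)),
        n_informative_loci=30, n_noise_loci=70,
        informative_separation=1.0, noise_concentration=60.0, seed=3)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def three_class_cohort():
    """The default desk-scale study cohort: 3 types x 20 samples, 500 loci."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def separable_cohort():
    """Six-class cohort (3 cancer types, each with malignant and benign
    samples) with strong separation, for classifier tests."""
    spec = CohortSpec(
        n_samples_per_class=12,
        class_labels=(("BRCA", True), ("BRCA", False), ("OV", True),
                      ("OV", False), ("STAD", True), ("STAD", False)),
        n_informative_loci=40, n_noise_loci=160,
        informative_separation=0.9, noise_concentration=50.0, seed=7)
    return generate_cohort(spec)


@pytest.fixture
def tiny_platform():
    """A 10-locus stand-in platform carrying the 27k rejection threshold."""
    return Platform("27k", 10, rejection_threshold=0.10)
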