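import numpy as np
import pytest

from divcover.pipeline import run_study
from divcover.simulate import StudyConfig, simulate_study


def small_config(seed: int = 7, **overrides) -> StudyConfig:
    """A miniature but structurally complete study for fast tests."""
    defaults = dict(
        n_species=12,
        n_clades=4,
        genome_prob_per_clade=(0.0, 0.0, 0.8, 1.0),
        backbone_size=6,
        outgroup_size=4,
        seq_length=300,
        replicates_per_species=(1, 3),
        seed=seed,
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def small_result(small_bundle):
    return run_study(small_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


def mutate(rng, sequence: str, p: float) -> str:
    out = list(sequence)
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)
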