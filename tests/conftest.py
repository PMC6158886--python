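import numpy as np
import pandas as pd
import pytest

import galdose as gd


@pytest.fixture
def rng():
    return np.random.default_rng(20180926)


@pytest.fixture
def truth_d():
    """Default ground truth for the 1% pure-galactose environment."""
    return gd.default_ground_truth("D")


@pytest.fixture
def neutral_truth_d():
    return gd.default_ground_truth("D", neutral=True)


@pytest.fixture
def small_experiment(truth_d):
    """One simulated competition at modest event count, fixed seed."""
    g = gd.Genotype.from_reduced(["GAL80"])
    return gd.simulate_competition(g, "D", truth_d, seed=11, n_events=5000)


@pytest.fixture
def small_config():
    """A scaled-down but structurally complete study configuration."""
    return gd.StudyConfig(
        environments=("C", "D", "E"), n_replicates=3, n_events=4000, seed=5
    )


def random_fitness_summary(rng, sem_lo=0.004, sem_hi=0.02, spread=0.15):
    """Random 16-strain fitness lattice with positive s.e.m. values."""
    genotypes = gd.enumerate_genotypes()
    return pd.DataFrame(
        {
            "genotype": [g.code for g in genotypes],
            "fitness_mean": 1.0 + rng.uniform(-spread, spread, len(genotypes)),
            "fitness_sem": rng.uniform(sem_lo, sem_hi, len(genotypes)),
        }
    )


@pytest.fixture
def fitness_lattice(rng):
    return random_fitness_summary(rng)
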