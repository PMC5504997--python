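import numpy as np
import pytest
from hypothesis import settings

import growthqr as gq

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """A small strong-signal F2 dataset shared across module tests."""
    cfg = gq.default_strong_signal_config(n_animals=120, n_markers=30,
                                          n_effects=3, seed=7)
    panel = gq.simulate_genotypes(cfg)
    records, covariates, truth = gq.simulate_phenotypes(panel, cfg)
    return cfg, panel, records, covariates, truth


@pytest.fixture(scope="session")
def small_adjusted(small_sim):
    """Fixed-effect-corrected traits plus the aligned genotype matrix."""
    cfg, panel, records, covariates, _ = small_sim
    fits = gq.fit_all(records)
    adjusted = gq.adjust_fixed_effects(fits, covariates)
    pos = {a: i for i, a in enumerate(panel.animal_ids)}
    X = panel.dosage_matrix()[[pos[a] for a in adjusted.animal_ids]]
    return adjusted, X, panel


def make_records(animal_id, ages, weights):
    return gq.GrowthRecords(animal_id, np.asarray(ages, float), np.asarray(weights, float))
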