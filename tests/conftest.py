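"""Shared fixtures: generated cohorts at the default study conditions plus
small/noiseless variants for fast unit tests.  Everything is seeded."""

import numpy as np
import pytest

import bulbswitch as bw

DEFAULT_COHORT_SEED = 90210


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort: 5 animals, 353 ROIs, default generator."""
    return bw.generate_cohort(bw.GeneratorConfig(), seed=DEFAULT_COHORT_SEED)


@pytest.fixture(scope="session")
def default_tables(default_cohort):
    """Epoch-equalized response tables for the default cohort."""
    equalized = [bw.equalize_fine_epochs(s) for s, _ in default_cohort]
    return [bw.compute_responses(s) for s in equalized]


@pytest.fixture(scope="session")
def default_modulation(default_tables):
    return [bw.task_modulation_test(t) for t in default_tables]


@pytest.fixture(scope="session")
def default_truth(default_cohort):
    return np.concatenate([g.is_modulated for _, g in default_cohort])


def small_config(**overrides) -> bw.GeneratorConfig:
    """2 animals x 12 ROIs with short epochs: fast but structurally complete."""
    kwargs = dict(
        n_animals=2,
        rois_per_animal=12,
        epoch_length_range=(8, 12),
    )
    kwargs.update(overrides)
    return bw.GeneratorConfig(**kwargs)


def noiseless_config(**overrides) -> bw.GeneratorConfig:
    """All stochastic amplitude terms off: frame noise, jitter, sniff coupling."""
    kwargs = dict(
        noise_sd=0.0,
        amplitude_jitter_sd=0.0,
        sniff_coupling=0.0,
        sniff_rate_sd=0.0,
        lapse_rate=0.0,
    )
    kwargs.update(overrides)
    return small_config(**kwargs)


@pytest.fixture()
def small_session():
    session, gt = bw.generate_session(small_config(), seed=11, n_rois=8)
    return session, gt


@pytest.fixture()
def noiseless_session():
    session, gt = bw.generate_session(noiseless_config(), seed=5, n_rois=10)
    return session, gt
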