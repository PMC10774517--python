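"""Shared fixtures: the standard synthetic fixture cohort and trained models.

The standard fixture is the package's reference study condition: 10 regions,
40 training + 30 test subjects per group, 200 timepoints, 10 planted edges
with delta-r 0.4 (high) / 0.2 (low), and per-group diffusion models trained
at T=200 for 300 epochs.  Session-scoped so the expensive pieces are built
once.
"""

import numpy as np
import pytest

from gdrn import (
    GROUPS,
    GroupModelSet,
    SyntheticSpec,
    TrainConfig,
    generate_cohort,
    sample,
    train,
)

FIXTURE_SEED = 11
N_TRAIN = 40
N_TEST = 30
TRAIN_KW = dict(T=200, epochs=300, batch_size=16)


@pytest.fixture(scope="session")
def cohort():
    spec = SyntheticSpec(seed=FIXTURE_SEED, n_subjects_per_group=N_TRAIN + N_TEST)
    ts, fc, truth = generate_cohort(spec)
    return spec, ts, fc, truth


@pytest.fixture(scope="session")
def train_fc(cohort):
    _, _, fc, _ = cohort
    return {g: fc[g][:N_TRAIN] for g in GROUPS}


@pytest.fixture(scope="session")
def test_fc(cohort):
    _, _, fc, _ = cohort
    return {g: fc[g][N_TRAIN:] for g in GROUPS}


@pytest.fixture(scope="session")
def sched():
    return TrainConfig(**TRAIN_KW).make_schedule()


@pytest.fixture(scope="session")
def models(train_fc):
    out = {}
    for gi, g in enumerate(GROUPS):
        out[g] = train(train_fc[g], TrainConfig(**TRAIN_KW, seed=50 + gi))
    return out


@pytest.fixture(scope="session")
def group_samples(models, sched):
    return {g: sample(models[g], sched, 64, seed=17 + i) for i, g in enumerate(GROUPS)}


@pytest.fixture(scope="session")
def model_set(models, sched):
    return GroupModelSet(models=models, sched=sched, t_noise=50, n_repeats=8, seed=23)


@pytest.fixture()
def tiny_fc():
    """A cheap 6-region cohort for unit tests that just need valid matrices."""
    spec = SyntheticSpec(
        n_regions=6, n_subjects_per_group=8, n_timepoints=80, n_planted=3, seed=1
    )
    _, fc, truth = generate_cohort(spec)
    return fc, truth
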