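"""Shared fixtures: reference systems, a trained committee, and the scaled
active-learning campaign (session-scoped; several tests read it)."""

from __future__ import annotations

import numpy as np
import pytest

from nanoreax.active_learning import (
    ALConfig,
    ALState,
    al_generation,
    bootstrap_dataset,
)
from nanoreax.builders import BuilderPolicy, miller_system
from nanoreax.ensemble import TrainConfig, train_ensemble
from nanoreax.md import MDParams
from nanoreax.potentials import ToyReactivePotential
from nanoreax.schedules import SchedulePolicy
from nanoreax.system import Cell, Configuration, LabeledSample


@pytest.fixture(scope="session")
def toy_potential():
    return ToyReactivePotential()


@pytest.fixture(scope="session")
def miller_box():
    """Packed 228-atom Miller-experiment box (12.1 Å cube)."""
    return miller_system(np.random.default_rng(42))


@pytest.fixture(scope="session")
def dimer_sweep_dataset(toy_potential):
    """200 C2 dimer configurations spanning the bonded well (1.2–3.6 Å)."""
    cell = Cell.cubic(20.0)
    samples = []
    for r in np.linspace(1.2, 3.6, 200):
        config = Configuration(
            ("C", "C"),
            np.array([[10 - r / 2, 10, 10], [10 + r / 2, 10, 10]]),
            cell,
        )
        energy, forces = toy_potential.evaluate(config)
        samples.append(LabeledSample(config, energy, forces))
    return samples


@pytest.fixture(scope="session")
def dimer_ensemble(dimer_sweep_dataset):
    """Committee trained on the dimer sweep (shared across tests)."""
    return train_ensemble(
        dimer_sweep_dataset,
        TrainConfig(seed=3),
        n_members=8,
        rng=np.random.default_rng(3),
    )


def campaign_config() -> ALConfig:
    """The desk-scale campaign conditions used by the end-to-end tests."""
    return ALConfig(
        bootstrap_cells=96,
        simulations_per_generation=6,
        t_max=1000.0,
        convergence_target=800.0,
        builder_policy=BuilderPolicy(
            atom_count_range=(14, 24), density_range=(0.4, 1.0)
        ),
        schedule_policy=SchedulePolicy(
            t_start_range=(300.0, 900.0),
            t_end_range=(1500.0, 3000.0),
            t_amp_range=(0.0, 500.0),
        ),
        md_params=MDParams(dt=0.5, monitor_interval=25),
        train_config=TrainConfig(),
        seed=7,
    )


CAMPAIGN_GENERATIONS = 9


@pytest.fixture(scope="session")
def al_campaign():
    """Seeded 9-generation toy campaign; returns (final state, config)."""
    config = campaign_config()
    rng = np.random.default_rng(config.seed)
    labeler = ToyReactivePotential()
    state = ALState(dataset=bootstrap_dataset(config, labeler, rng))
    for _ in range(CAMPAIGN_GENERATIONS):
        state = al_generation(state, config, labeler, rng)
    return state, config
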