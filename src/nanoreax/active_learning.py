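"""The iterative nanoreactor active-learning driver.

One *generation* = train the committee on the current dataset, run a batch
of nanoreactor simulations on freshly drawn systems and schedules, label
every uncertainty-flagged configuration with the reference labeler, and
append the labels to the dataset.  The campaign converges when the mean
simulation time before a flag (flag-free runs count their full length)
reaches the configured target — the committee is then confident across new
nanoreactor sampling.

Desk-scale defaults (16 bootstrap cells, 8 simulations/generation, 10 ps
per simulation, 5 ps convergence target) are scaled-down analogues of the
production campaign settings (100 cells, up to 1 ns per simulation, ~50 ps
target); every knob is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .builders import BuilderPolicy, random_nr_system
from .ensemble import (
    EnsembleModel,
    SelectionThresholds,
    TrainConfig,
    thresholds_for_generation,
    train_ensemble,
)
from .md import MDParams, MDState, maxwell_boltzmann_velocities, run_nanoreactor
from .potentials import Calculator, label
from .schedules import SchedulePolicy, draw_schedule, oscillating_value
from .system import LabeledSample


@dataclass
class ALConfig:
    """Campaign configuration (desk-scale defaults)."""

    bootstrap_cells: int = 16
    simulations_per_generation: int = 8
    t_max: float = 10_000.0  # fs per nanoreactor simulation
    convergence_target: float = 5_000.0  # fs mean simulation time
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    threshold_ramp_generations: int = 6
    builder_policy: BuilderPolicy = field(default_factory=BuilderPolicy)
    schedule_policy: SchedulePolicy = field(default_factory=SchedulePolicy)
    md_params: MDParams = field(default_factory=MDParams)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    n_members: int = 8
    bootstrap_jitter: float = 0.06  # Å; thermal rattle of bootstrap snapshots
    #: packing separation per bootstrap cell is drawn uniformly from this
    #: range (Å) so labeled data covers the intermolecular approach region
    bootstrap_separation_range: tuple[float, float] = (1.0, 2.0)
    randomize_monitor: bool = False  # draw monitor_interval per simulation from [5, 50]
    warm_start: bool = False  # reuse previous-generation weights as initialization
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_cells < 1 or self.simulations_per_generation < 1:
            raise ValueError("counts must be >= 1")
        if self.t_max <= 0 or self.convergence_target < 0:
            raise ValueError("t_max must be positive, convergence target >= 0")


@dataclass
class GenerationRecord:
    """Per-generation bookkeeping row."""

    generation: int
    n_simulations: int
    n_flags: int
    n_labeled: int
    n_label_failures: int
    mean_sim_time_fs: float
    dataset_size: int
    energy_threshold: float
    force_threshold: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FlagProvenance:
    """Selection audit record for one dataset addition."""

    generation: int
    simulation_index: int
    time_fs: float
    eps_energy: float
    eps_force: float
    energy_threshold: float
    force_threshold: float


@dataclass
class ALState:
    """Dataset, current committee and per-generation history."""

    dataset: list[LabeledSample] = field(default_factory=list)
    generation: int = 0
    ensemble: EnsembleModel | None = None
    history: list[GenerationRecord] = field(default_factory=list)
    provenance: list[FlagProvenance] = field(default_factory=list)

    @property
    def converged_time(self) -> float:
        return self.history[-1].mean_sim_time_fs if self.history else 0.0


def bootstrap_dataset(
    config: ALConfig, labeler: Calculator, rng: np.random.Generator
) -> list[LabeledSample]:
    """Labeled random seed-molecule cells to bootstrap the campaign.

    Draws ``bootstrap_cells`` random periodic boxes of the nine seed
    molecules (random composition, density and orientations), rattles each
    atom by ``bootstrap_jitter`` (Å, normal) so the labeled snapshots carry
    thermal-scale geometric diversity, and labels each with the reference
    calculator.  Label failures propagate: a
    bootstrap that cannot be labeled is a configuration error worth
    surfacing, not a statistic.
    """
    samples: list[LabeledSample] = []
    from dataclasses import replace as dc_replace

    for _ in range(config.bootstrap_cells):
        sep = rng.uniform(*config.bootstrap_separation_range)
        policy = dc_replace(config.builder_policy, min_separation=sep)
        cfg, _comp = random_nr_system(policy, rng)
        if config.bootstrap_jitter > 0:
            # thermal-scale rattle: labeled snapshots span the bond-length
            # neighborhoods MD will visit, not just frozen template geometry
            jitter = rng.normal(scale=config.bootstrap_jitter, size=cfg.positions.shape)
            cfg = cfg.with_positions(cfg.positions + jitter)
        results = label([cfg], labeler)
        if not results[0].ok:
            raise RuntimeError(f"bootstrap labeling failed: {results[0].error}")
        samples.append(results[0].sample)
    return samples


def _run_one_simulation(
    ensemble: EnsembleModel,
    thresholds: SelectionThresholds,
    config: ALConfig,
    rng: np.random.Generator,
):
    """Draw schedules + a matching system, run the nanoreactor, return (time, flag).

    The box is packed at the density schedule's starting value so the first
    rescale is a no-op and conditions evolve continuously from t = 0.
    """
    from .builders import BuildError, draw_composition, pack_molecules
    from .schedules import density_at

    system = None
    for _ in range(8):  # redraw deterministically on infeasible packings
        temp_sched, dens_sched = draw_schedule(
            config.schedule_policy, rng, config.t_max
        )
        comp = draw_composition(config.builder_policy, rng)
        cell = comp.cubic_cell_for_density(density_at(0.0, dens_sched))
        try:
            system = pack_molecules(
                comp, cell, config.builder_policy.min_separation, rng
            )
            break
        except BuildError:
            continue
    if system is None:
        raise BuildError("no feasible nanoreactor system in 8 draws")
    params = config.md_params
    if config.randomize_monitor:
        params = replace(params, monitor_interval=int(rng.integers(5, 51)))
    t0 = oscillating_value(0.0, temp_sched)
    state = MDState(
        configuration=system,
        velocities=maxwell_boltzmann_velocities(system.species, t0, rng),
        rng=rng,
    )
    traj, flag = run_nanoreactor(
        state, temp_sched, dens_sched, ensemble, thresholds, params, config.t_max
    )
    elapsed = flag.time if flag is not None else config.t_max
    return elapsed, flag


def al_generation(
    state: ALState, config: ALConfig, labeler: Calculator, rng: np.random.Generator
) -> ALState:
    """One sample → select → label → train generation; returns the new state.

    Trains the committee on the current dataset, runs the configured number
    of nanoreactor simulations, labels every flagged configuration (label
    failures are recorded and skipped) and appends the new samples.
    """
    if not state.dataset:
        raise ValueError("state has an empty dataset; bootstrap first")
    init_members = (
        state.ensemble.members if (config.warm_start and state.ensemble) else None
    )
    ensemble = train_ensemble(
        state.dataset,
        config.train_config,
        n_members=config.n_members,
        rng=rng,
        init_members=init_members,
    )
    thresholds = thresholds_for_generation(
        config.thresholds, state.generation, config.threshold_ramp_generations
    )
    times: list[float] = []
    flags = []
    for sim_idx in range(config.simulations_per_generation):
        elapsed, flag = _run_one_simulation(ensemble, thresholds, config, rng)
        times.append(elapsed)
        if flag is not None:
            flags.append((sim_idx, flag))

    results = label([f.configuration for _, f in flags], labeler)
    new_samples = []
    new_provenance = []
    n_failures = 0
    for (sim_idx, flag), res in zip(flags, results):
        if res.ok:
            new_samples.append(res.sample)
            new_provenance.append(
                FlagProvenance(
                    generation=state.generation,
                    simulation_index=sim_idx,
                    time_fs=flag.time,
                    eps_energy=flag.eps_energy,
                    eps_force=flag.eps_force,
                    energy_threshold=thresholds.energy_threshold,
                    force_threshold=thresholds.force_threshold,
                )
            )
        else:
            n_failures += 1

    record = GenerationRecord(
        generation=state.generation,
        n_simulations=config.simulations_per_generation,
        n_flags=len(flags),
        n_labeled=len(new_samples),
        n_label_failures=n_failures,
        mean_sim_time_fs=float(np.mean(times)),
        dataset_size=len(state.dataset) + len(new_samples),
        energy_threshold=thresholds.energy_threshold,
        force_threshold=thresholds.force_threshold,
    )
    return ALState(
        dataset=state.dataset + new_samples,
        generation=state.generation + 1,
        ensemble=ensemble,
        history=state.history + [record],
        provenance=state.provenance + new_provenance,
    )


def run_until_converged(
    state: ALState | None,
    config: ALConfig,
    labeler: Calculator,
    rng: np.random.Generator,
    max_generations: int = 50,
) -> ALState:
    """Iterate generations until the mean simulation time reaches the target
    or ``max_generations`` is exhausted; returns the final state with full
    history."""
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    if state is None:
        state = ALState(dataset=bootstrap_dataset(config, labeler, rng))
    for _ in range(max_generations):
        state = al_generation(state, config, labeler, rng)
        if state.history[-1].mean_sim_time_fs >= config.convergence_target:
            break
    return state
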