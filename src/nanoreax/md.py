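"""Langevin dynamics (BAOAB splitting), temperature programs, and the
nanoreactor driver with query-by-committee uncertainty monitoring.

The integrator is the BAOAB splitting of Langevin dynamics: half-kick,
half-drift, Ornstein–Uhlenbeck velocity update, half-drift, half-kick, with
one force evaluation per step at the new positions.  With zero friction and
zero temperature the O-step is the identity and the scheme reduces exactly
to velocity Verlet.  Friction is expressed in 1/fs (the value 0.01 from the
simulation protocols is read as 0.01 fs⁻¹, the convention of the MD
environment those protocols came from).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .schedules import ScheduleParams, density_at, oscillating_value
from .system import Cell, Configuration, Trajectory, mass_density
from .units import KB_KCAL_MOL_K, KCAL_MOL_TO_MD, MD_TO_KCAL_MOL


class MDError(RuntimeError):
    pass


class MDRunError(MDError):
    """Calculator failure mid-run; carries the partial trajectory."""

    def __init__(self, message: str, partial: Trajectory):
        super().__init__(message)
        self.partial = partial


@dataclass
class MDParams:
    """Integration parameters.

    dt in fs (0.5 fs is the sampling default), friction in 1/fs,
    record_interval/monitor_interval in steps.
    """

    dt: float = 0.5
    friction: float = 0.01
    record_interval: int = 100
    monitor_interval: int = 25

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.record_interval < 1 or self.monitor_interval < 1:
            raise ValueError("intervals must be >= 1")


@dataclass
class MDState:
    """Dynamic state: configuration, velocities (Å/fs), time (fs), RNG stream."""

    configuration: Configuration
    velocities: np.ndarray
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    forces: np.ndarray | None = None  # cached forces at `configuration`
    potential_energy: float | None = None

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.shape != (self.configuration.n_atoms, 3):
            raise ValueError("velocities shape must match atom count")


def maxwell_boltzmann_velocities(
    species: Sequence[str], temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocities with each component ~ N(0, k_B T / m_i) in internal units."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    from .units import ATOMIC_MASSES

    masses = np.array([ATOMIC_MASSES[s] for s in species])
    sigma = np.sqrt(KB_KCAL_MOL_K * temperature * KCAL_MOL_TO_MD / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def kinetic_energy(state: MDState) -> float:
    """Kinetic energy in kcal/mol."""
    m = state.configuration.masses
    return float(0.5 * (m[:, None] * state.velocities**2).sum() * MD_TO_KCAL_MOL)


def instantaneous_temperature(state: MDState) -> float:
    """Temperature from equipartition: T = 2 KE / (3 N k_B)."""
    n = state.configuration.n_atoms
    return 2.0 * kinetic_energy(state) / (3.0 * n * KB_KCAL_MOL_K)


def _check_forces(forces: np.ndarray) -> None:
    bad = ~np.isfinite(forces)
    if bad.any():
        atom = int(np.argwhere(bad.any(axis=1))[0][0])
        raise MDError(f"non-finite force on atom {atom}")


def langevin_step(
    state: MDState, calculator, T_target: float, params: MDParams
) -> MDState:
    """One BAOAB Langevin step; returns the advanced state with cached forces.

    The first half-kick reuses the cached forces at the incoming
    configuration (computing them if absent); one fresh force evaluation is
    made at the updated positions.
    """
    dt = params.dt
    config = state.configuration
    m = config.masses[:, None]
    if state.forces is None:
        energy, forces = calculator.evaluate(config)
    else:
        energy, forces = state.potential_energy, state.forces
    _check_forces(forces)
    acc = forces * KCAL_MOL_TO_MD / m  # Å/fs²
    v = state.velocities + 0.5 * dt * acc
    x = config.positions + 0.5 * dt * v
    if params.friction > 0.0 and T_target >= 0.0:
        c1 = math.exp(-params.friction * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * KB_KCAL_MOL_K * max(T_target, 0.0) * KCAL_MOL_TO_MD / m)
        v = c1 * v + c2 * state.rng.normal(size=v.shape)
    x = x + 0.5 * dt * v
    new_config = config.with_positions(x).wrapped()
    new_energy, new_forces = calculator.evaluate(new_config)
    _check_forces(new_forces)
    v = v + 0.5 * dt * new_forces * KCAL_MOL_TO_MD / m
    return MDState(
        configuration=new_config,
        velocities=v,
        time=state.time + dt,
        rng=state.rng,
        forces=new_forces,
        potential_energy=new_energy,
    )


def rescale_to_density(state: MDState, target: float) -> MDState:
    """Affinely rescale cell and positions to the target density (g/cc).

    Fractional coordinates are preserved exactly; velocities are left
    untouched (the thermostat re-equilibrates kinetic energy).  Cached
    forces are dropped since the geometry changed.
    """
    if target <= 0:
        raise ValueError("target density must be positive")
    config = state.configuration
    current = mass_density(config)
    scale = (current / target) ** (1.0 / 3.0)
    if scale == 1.0:
        return state
    cell = Cell(
        tuple(L * scale for L in config.cell.edge_lengths), config.cell.periodic_flags
    )
    new_config = Configuration(config.species, config.positions * scale, cell)
    return replace(state, configuration=new_config, forces=None, potential_energy=None)


# ---------------------------------------------------------------------------
# Temperature programs


def constant_temperature(T: float) -> Callable[[float], float]:
    return lambda t: T


def linear_ramp(T0: float, T1: float, duration: float) -> Callable[[float], float]:
    """Linear T(t) from T0 at t=0 to T1 at t=duration (held at T1 after)."""

    def program(t: float) -> float:
        if t >= duration:
            return T1
        return T0 + (T1 - T0) * t / duration

    return program


def piecewise_program(
    segments: Sequence[tuple[float, Callable[[float], float]]]
) -> Callable[[float], float]:
    """Concatenate (duration fs, program) segments; each sees its local time.

    Covers protocols of the relax → ramp → hold → cool kind.  Times beyond
    the total duration evaluate the last segment at its end point.
    """

    def program(t: float) -> float:
        local = t
        for duration, seg in segments:
            if local <= duration:
                return seg(local)
            local -= duration
        last_duration, last = segments[-1]
        return last(last_duration)

    return program


def schedule_program(p: ScheduleParams) -> Callable[[float], float]:
    return lambda t: oscillating_value(min(t, p.t_max), p)


# ---------------------------------------------------------------------------
# Drivers


def run_md(
    initial: MDState,
    calculator,
    temperature_program: float | Callable[[float], float],
    params: MDParams,
    duration: float,
    density_program: Callable[[float], float] | None = None,
) -> Trajectory:
    """Thermostatted MD for ``duration`` fs, recording every record_interval steps.

    Records the initial state plus every ``record_interval``-th step with
    time, programmed temperature, density and potential energy.  An
    optional density program rescales the box once per step before the
    force evaluation.  A calculator failure raises :class:`MDRunError`
    carrying the partial trajectory.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not callable(temperature_program):
        temperature_program = constant_temperature(float(temperature_program))
    n_steps = int(round(duration / params.dt))
    state = initial
    traj = Trajectory()

    def record(s: MDState) -> None:
        if s.potential_energy is None:
            energy, forces = calculator.evaluate(s.configuration)
            s.forces, s.potential_energy = forces, energy
        traj.append(
            s.configuration.copy(),
            s.time,
            temperature=instantaneous_temperature(s),
            density=mass_density(s.configuration),
            potential_energy=s.potential_energy,
        )

    try:
        record(state)
        for step in range(1, n_steps + 1):
            t = state.time
            if density_program is not None:
                state = rescale_to_density(state, density_program(t))
            T_target = temperature_program(t)
            state = langevin_step(state, calculator, T_target, params)
            if step % params.record_interval == 0:
                record(state)
    except (MDError, RuntimeError) as exc:
        if isinstance(exc, MDRunError):
            raise
        raise MDRunError(f"calculator failed at t={state.time} fs: {exc}", traj) from exc
    return traj


@dataclass
class FlagEvent:
    """An uncertainty exceedance: the flagged configuration and its metrics."""

    configuration: Configuration
    time: float
    eps_energy: float
    eps_force: float


def run_nanoreactor(
    initial: MDState,
    temperature_schedule: ScheduleParams,
    density_schedule: ScheduleParams,
    ensemble,
    thresholds,
    params: MDParams,
    t_max: float | None = None,
) -> tuple[Trajectory, FlagEvent | None]:
    """Oscillating-condition MD with query-by-committee monitoring.

    Temperature and density follow the drawn schedules; every
    ``monitor_interval`` steps the committee disagreement is evaluated and,
    on the first exceedance of ``thresholds``, the simulation ends and the
    flagged configuration is returned.  Otherwise the run lasts ``t_max``
    (default: the schedules' shared t_max) and no flag is raised.

    ``ensemble`` must provide ``predict_members(config) -> (energies (M,),
    forces (M,N,3))``; the driving force is the committee mean.
    """
    from .ensemble import CommitteeCalculator, qbc_from_members

    if t_max is None:
        t_max = temperature_schedule.t_max
    calc = CommitteeCalculator(ensemble)
    n_steps = int(round(t_max / params.dt))
    state = initial
    traj = Trajectory()

    def record(s: MDState) -> None:
        traj.append(
            s.configuration.copy(),
            s.time,
            temperature=instantaneous_temperature(s),
            density=mass_density(s.configuration),
            potential_energy=s.potential_energy
            if s.potential_energy is not None
            else float("nan"),
        )

    record(state)
    for step in range(1, n_steps + 1):
        t = min(state.time, t_max)
        state = rescale_to_density(state, density_at(t, density_schedule))
        T_target = oscillating_value(t, temperature_schedule)
        state = langevin_step(state, calc, T_target, params)
        if step % params.record_interval == 0:
            record(state)
        if step % params.monitor_interval == 0:
            energies, forces = calc.last_members
            eps_e, eps_f = qbc_from_members(
                energies,
                forces,
                state.configuration.n_atoms,
                getattr(ensemble, "force_aggregation", "mean"),
            )
            if thresholds.exceeded(eps_e, eps_f):
                return traj, FlagEvent(
                    state.configuration.copy(), state.time, eps_e, eps_f
                )
    return traj, None
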