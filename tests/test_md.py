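"""Langevin/Verlet integration, thermostat statistics, nanoreactor driver."""

import numpy as np
import pytest

from nanoreax.descriptors import DescriptorParams
from nanoreax.ensemble import SelectionThresholds
from nanoreax.md import (
    FlagEvent,
    MDParams,
    MDState,
    MDRunError,
    instantaneous_temperature,
    kinetic_energy,
    langevin_step,
    linear_ramp,
    maxwell_boltzmann_velocities,
    piecewise_program,
    rescale_to_density,
    run_md,
    run_nanoreactor,
)
from nanoreax.potentials import ToyReactivePotential
from nanoreax.schedules import ScheduleParams
from nanoreax.system import Cell, Configuration, mass_density, minimum_image_displacement
from nanoreax.units import KB_KCAL_MOL_K, ATOMIC_MASSES, KCAL_MOL_TO_MD


class HarmonicBond:
    """Independent two-atom harmonic calculator for integrator oracles."""

    elements = ("C", "H", "N", "O")
    cutoff = np.inf

    def __init__(self, k: float = 50.0, r0: float = 1.5):
        self.k = k
        self.r0 = r0

    def evaluate(self, config):
        d, r = minimum_image_displacement(
            config.positions[0], config.positions[1], config.cell
        )
        energy = 0.5 * self.k * (r - self.r0) ** 2
        f = self.k * (r - self.r0) * (d / r)
        forces = np.array([f, -f])
        return energy, forces


def dimer_state(r=1.6, seed=0, element="C"):
    cell = Cell.cubic(50.0)
    config = Configuration(
        (element, element),
        np.array([[25 - r / 2, 25, 25], [25 + r / 2, 25, 25]]),
        cell,
    )
    return MDState(config, np.zeros((2, 3)), rng=np.random.default_rng(seed))


class TestMaxwellBoltzmann:
    def test_zero_temperature_gives_zero_velocities(self):
        v = maxwell_boltzmann_velocities(("C", "H"), 0.0, np.random.default_rng(0))
        assert np.all(v == 0)

    def test_mean_kinetic_energy_matches_equipartition(self):
        rng = np.random.default_rng(1)
        species = ("C", "H", "O", "N") * 16  # 64 atoms
        total = 0.0
        n_draws = 1000
        masses = np.array([ATOMIC_MASSES[s] for s in species])
        for _ in range(n_draws):
            v = maxwell_boltzmann_velocities(species, 300.0, rng)
            total += 0.5 * (masses[:, None] * v**2).sum() / KCAL_MOL_TO_MD
        mean_ke = total / n_draws
        expected = 1.5 * len(species) * KB_KCAL_MOL_K * 300.0
        assert mean_ke == pytest.approx(expected, rel=0.02)

    def test_component_variance_matches_kt_over_m(self):
        rng = np.random.default_rng(2)
        draws = np.array(
            [maxwell_boltzmann_velocities(("O",), 500.0, rng)[0] for _ in range(10_000)]
        )
        var = draws.var()
        expected = KB_KCAL_MOL_K * 500.0 * KCAL_MOL_TO_MD / ATOMIC_MASSES["O"]
        assert var == pytest.approx(expected, rel=0.05)


class TestIntegrator:
    def test_free_particle_moves_uniformly(self):
        class Zero:
            def evaluate(self, config):
                return 0.0, np.zeros((config.n_atoms, 3))

        state = dimer_state()
        state.velocities = np.array([[0.01, 0.0, 0.0], [0.0, 0.02, 0.0]])
        params = MDParams(dt=0.5, friction=0.0)
        start = state.configuration.positions.copy()
        for _ in range(100):
            state = langevin_step(state, Zero(), 0.0, params)
        expected = start + 50.0 * state.velocities
        assert np.allclose(state.configuration.positions, expected, atol=1e-10)

    def test_zero_friction_matches_standalone_verlet(self):
        """With friction 0 and T 0 the stochastic step degenerates to plain
        velocity Verlet (identical half-kick/half-drift arithmetic)."""
        calc = HarmonicBond()
        state = dimer_state(r=1.7)
        params = MDParams(dt=0.5, friction=0.0)
        # standalone oracle advancing (x, v) by velocity Verlet
        x = state.configuration.positions.copy()
        v = state.velocities.copy()
        m = state.configuration.masses[:, None]
        config = state.configuration
        for _ in range(120):
            state = langevin_step(state, calc, 0.0, params)
        for _ in range(120):
            _, f = calc.evaluate(config.with_positions(x))
            a = f * KCAL_MOL_TO_MD / m
            v = v + 0.5 * 0.5 * a
            x = x + 0.5 * 0.5 * v
            x = x + 0.5 * 0.5 * v
            config = config.with_positions(x).wrapped()
            x = config.positions
            _, f = calc.evaluate(config)
            a = f * KCAL_MOL_TO_MD / m
            v = v + 0.5 * 0.5 * a
        assert np.array_equal(state.configuration.positions, x)

    def test_nve_energy_drift_is_tiny(self):
        calc = HarmonicBond(k=10.0)
        state = dimer_state(r=1.7)
        params = MDParams(dt=0.5, friction=0.0)
        e0, _ = calc.evaluate(state.configuration)
        total0 = e0 + kinetic_energy(state)
        scale = 0.5 * calc.k * (1.7 - calc.r0) ** 2  # energy scale of the motion
        worst = 0.0
        for _ in range(10_000):
            state = langevin_step(state, calc, 0.0, params)
            total = state.potential_energy + kinetic_energy(state)
            worst = max(worst, abs(total - total0))
        assert worst / scale < 1e-4

    def test_thermostat_recovers_target_temperature(self):
        calc = HarmonicBond(k=100.0)
        state = dimer_state(r=1.5, seed=5)
        params = MDParams(dt=0.5, friction=0.05)
        temps = []
        for step in range(20_000):
            state = langevin_step(state, calc, 300.0, params)
            if step > 4000:
                temps.append(instantaneous_temperature(state))
        assert np.mean(temps) == pytest.approx(300.0, rel=0.05)

    def test_nonfinite_forces_name_the_atom(self):
        class Bad:
            def evaluate(self, config):
                f = np.zeros((config.n_atoms, 3))
                f[1, 0] = np.nan
                return 0.0, f

        with pytest.raises(Exception, match="atom 1"):
            langevin_step(dimer_state(), Bad(), 0.0, MDParams())


class TestRescale:
    def test_identity_when_already_at_target(self):
        state = dimer_state()
        rho = mass_density(state.configuration)
        out = rescale_to_density(state, rho)
        assert np.array_equal(out.configuration.positions, state.configuration.positions)

    def test_fractional_coordinates_preserved(self):
        state = dimer_state()
        frac0 = state.configuration.positions / state.configuration.cell.lengths
        out = rescale_to_density(state, 2.0 * mass_density(state.configuration))
        frac1 = out.configuration.positions / out.configuration.cell.lengths
        assert np.abs(frac0 - frac1).max() < 1e-12
        assert mass_density(out.configuration) == pytest.approx(
            2.0 * mass_density(state.configuration), rel=1e-9
        )

    def test_distances_scale_as_cube_root_of_density_ratio(self):
        state = dimer_state(r=2.0)
        rho0 = mass_density(state.configuration)
        target = 1.7 * rho0
        out = rescale_to_density(state, target)
        _, r0 = minimum_image_displacement(
            state.configuration.positions[0],
            state.configuration.positions[1],
            state.configuration.cell,
        )
        _, r1 = minimum_image_displacement(
            out.configuration.positions[0],
            out.configuration.positions[1],
            out.configuration.cell,
        )
        assert r1 / r0 == pytest.approx((rho0 / target) ** (1 / 3), rel=1e-12)


class TestRunMD:
    def test_frame_counting(self, toy_potential):
        from nanoreax.builders import BuilderPolicy, random_nr_system

        config, _ = random_nr_system(
            BuilderPolicy(atom_count_range=(8, 12), density_range=(0.3, 0.5)),
            np.random.default_rng(3),
        )
        state = MDState(
            config,
            maxwell_boltzmann_velocities(config.species, 300.0, np.random.default_rng(4)),
            rng=np.random.default_rng(4),
        )
        traj = run_md(
            state,
            toy_potential,
            300.0,
            MDParams(dt=0.5, record_interval=100),
            duration=500.0,
        )
        assert len(traj) == 11  # initial frame + 10 recorded
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(500.0)
        assert "temperature" in traj.scalars and "density" in traj.scalars

    def test_linear_ramp_midpoint(self):
        program = linear_ramp(300.0, 2500.0, 100_000.0)
        assert program(50_000.0) == pytest.approx(1400.0)

    def test_piecewise_relax_ramp_hold_cool(self):
        program = piecewise_program(
            [
                (100.0, linear_ramp(0.0, 300.0, 100.0)),
                (100.0, linear_ramp(300.0, 2500.0, 100.0)),
                (4000.0, lambda t: 2500.0),
                (200.0, linear_ramp(2500.0, 300.0, 200.0)),
            ]
        )
        assert program(0.0) == 0.0
        assert program(100.0) == pytest.approx(300.0)
        assert program(200.0) == pytest.approx(2500.0)
        assert program(2000.0) == 2500.0
        assert program(4400.0) == pytest.approx(300.0)
        assert program(10_000.0) == pytest.approx(300.0)

    def test_calculator_failure_flushes_partial_trajectory(self):
        class FailsLater:
            def __init__(self):
                self.calls = 0

            def evaluate(self, config):
                self.calls += 1
                if self.calls > 120:
                    raise RuntimeError("reference engine crashed")
                return 0.0, np.zeros((config.n_atoms, 3))

        state = dimer_state()
        with pytest.raises(MDRunError) as err:
            run_md(state, FailsLater(), 300.0, MDParams(dt=0.5, record_interval=50),
                   duration=500.0)
        assert len(err.value.partial) >= 2  # initial + at least one recorded frame

    def test_center_of_mass_drift_stays_bounded(self, toy_potential):
        from nanoreax.builders import BuilderPolicy, random_nr_system

        policy = BuilderPolicy(atom_count_range=(60, 64), density_range=(0.2, 0.3))
        config, _ = random_nr_system(policy, np.random.default_rng(8))
        state = MDState(
            config,
            maxwell_boltzmann_velocities(config.species, 300.0, np.random.default_rng(9)),
            rng=np.random.default_rng(9),
        )
        m = config.masses[:, None]
        # track CoM displacement from unwrapped integration of velocities;
        # gentle conditions (dt 0.25 fs, friction 0.05/fs, dilute box) keep
        # the aggressive toy chemistry integrable over the full 10 ps
        com_shift = np.zeros(3)
        params = MDParams(dt=0.25, friction=0.05)
        for _ in range(40_000):  # 10 ps
            v_com = (m * state.velocities).sum(axis=0) / m.sum()
            com_shift += v_com * params.dt
            state = langevin_step(state, toy_potential, 300.0, params)
        assert np.linalg.norm(com_shift) < 1.0


class _ConstantOffsetEnsemble:
    """Two members that agree on forces but differ by a fixed energy offset."""

    descriptor_params = DescriptorParams()
    force_aggregation = "mean"
    n_members = 2

    def __init__(self, calculator, offset):
        self.calculator = calculator
        self.offset = offset

    def predict_members(self, config):
        e, f = self.calculator.evaluate(config)
        return np.array([e, e + self.offset]), np.stack([f, f])


class TestNanoreactorDriver:
    def _initial_state(self, seed=0):
        from nanoreax.builders import BuilderPolicy, random_nr_system

        config, _ = random_nr_system(
            BuilderPolicy(atom_count_range=(8, 12), density_range=(0.4, 0.6)),
            np.random.default_rng(seed),
        )
        return MDState(
            config,
            maxwell_boltzmann_velocities(config.species, 300.0, np.random.default_rng(seed)),
            rng=np.random.default_rng(seed),
        )

    def test_infinite_thresholds_run_to_t_max(self, toy_potential):
        ensemble = _ConstantOffsetEnsemble(toy_potential, offset=0.0)
        temp = ScheduleParams(start=300, end=400, amp=0, t_per=100, t_max=100.0)
        dens = ScheduleParams(start=0.5, end=0.5, amp=0, t_per=100, t_max=100.0)
        thresholds = SelectionThresholds(1e9, 1e9)
        traj, flag = run_nanoreactor(
            self._initial_state(),
            temp,
            dens,
            ensemble,
            thresholds,
            MDParams(dt=0.5, monitor_interval=10, record_interval=50),
        )
        assert flag is None
        assert traj.times[-1] == pytest.approx(100.0)

    def test_super_threshold_offset_flags_first_monitor(self, toy_potential):
        state = self._initial_state()
        n = state.configuration.n_atoms
        # offset chosen so eps_E = offset/(2 sqrt N) clearly exceeds 1.85
        ensemble = _ConstantOffsetEnsemble(toy_potential, offset=50.0 * np.sqrt(n))
        temp = ScheduleParams(start=300, end=400, amp=0, t_per=100, t_max=200.0)
        dens = ScheduleParams(start=0.5, end=0.5, amp=0, t_per=100, t_max=200.0)
        traj, flag = run_nanoreactor(
            state, temp, dens, ensemble, SelectionThresholds(),
            MDParams(dt=0.5, monitor_interval=20),
        )
        assert isinstance(flag, FlagEvent)
        assert flag.time == pytest.approx(20 * 0.5)
        assert flag.eps_energy > 1.85

    def test_flag_time_is_multiple_of_monitor_stride(self, toy_potential):
        state = self._initial_state(seed=3)
        n = state.configuration.n_atoms
        ensemble = _ConstantOffsetEnsemble(toy_potential, offset=50.0 * np.sqrt(n))
        temp = ScheduleParams(start=300, end=400, amp=0, t_per=100, t_max=200.0)
        dens = ScheduleParams(start=0.5, end=0.5, amp=0, t_per=100, t_max=200.0)
        params = MDParams(dt=0.5, monitor_interval=7)
        _, flag = run_nanoreactor(
            state, temp, dens, ensemble, SelectionThresholds(), params
        )
        stride = params.monitor_interval * params.dt
        assert flag is not None
        assert (flag.time / stride) == pytest.approx(round(flag.time / stride))
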