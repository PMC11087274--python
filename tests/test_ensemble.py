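"""Committee predictions, query-by-committee metrics, training behavior."""

import numpy as np
import pytest

from nanoreax.descriptors import DescriptorParams
from nanoreax.ensemble import (
    SelectionThresholds,
    TrainConfig,
    exceeds_thresholds,
    predict_member,
    qbc_from_members,
    qbc_uncertainty,
    thresholds_for_generation,
    train_ensemble,
)
from nanoreax.system import Cell, Configuration


class TestQBCMetric:
    def test_identical_members_have_zero_uncertainty(self):
        eps = qbc_from_members(np.ones(8), np.zeros((8, 5, 3)), 5)
        assert eps == (0.0, 0.0)

    def test_energy_spread_normalized_by_sqrt_n(self):
        # members {0, 2} kcal/mol on 4 atoms: population std 1, /sqrt(4) = 0.5
        eps_e, eps_f = qbc_from_members(
            np.array([0.0, 2.0]), np.zeros((2, 4, 3)), 4
        )
        assert eps_e == pytest.approx(0.5)
        assert eps_f == 0.0

    def test_force_spread_on_single_atom(self):
        # two members differing by (2δ, 0, 0) on atom k: per-component std δ
        delta = 0.7
        forces = np.zeros((2, 5, 3))
        forces[1, 2, 0] = 2 * delta
        _, eps_f = qbc_from_members(np.zeros(2), forces, 5, "max")
        assert eps_f == pytest.approx(delta)
        _, eps_f_mean = qbc_from_members(np.zeros(2), forces, 5, "mean")
        assert eps_f_mean == pytest.approx(delta / 5)

    def test_scaling_with_system_size(self):
        """Fixed member energy spread ⇒ ε_E ∝ 1/√N."""
        energies = np.array([0.0, 2.0])
        f4 = qbc_from_members(energies, np.zeros((2, 4, 3)), 4)[0]
        f16 = qbc_from_members(energies, np.zeros((2, 16, 3)), 16)[0]
        assert f4 / f16 == pytest.approx(2.0)


class TestThresholds:
    def test_zero_uncertainty_never_selected(self):
        assert not exceeds_thresholds((0.0, 0.0), SelectionThresholds())

    def test_energy_boundary_exceedance(self):
        assert exceeds_thresholds((1.86, 0.0), SelectionThresholds())
        assert exceeds_thresholds((0.0, 6.93), SelectionThresholds())

    def test_exact_threshold_values_do_not_flag(self):
        assert not exceeds_thresholds((1.85, 6.92), SelectionThresholds())

    def test_generation_ramp_from_half_to_full(self):
        final = SelectionThresholds()
        first = thresholds_for_generation(final, 0, ramp_generations=6)
        assert first.energy_threshold == pytest.approx(0.5 * 1.85)
        assert first.force_threshold == pytest.approx(0.5 * 6.92)
        last = thresholds_for_generation(final, 5, ramp_generations=6)
        assert last == final
        beyond = thresholds_for_generation(final, 40, ramp_generations=6)
        assert beyond == final


class TestPredictMember:
    def test_forces_match_finite_differences(self, dimer_ensemble):
        member = dimer_ensemble.members[0]
        params = dimer_ensemble.descriptor_params
        config = Configuration(
            ("C", "C"),
            np.array([[9.0, 10, 10], [11.0, 10, 10]]),
            Cell.cubic(20.0),
        )
        energy, analytic = predict_member(member, config, params)
        h = 1e-5
        for i in range(2):
            for c in range(3):
                p = config.positions.copy()
                p[i, c] += h
                ep, _ = predict_member(member, config.with_positions(p), params)
                p[i, c] -= 2 * h
                em, _ = predict_member(member, config.with_positions(p), params)
                numeric = -(ep - em) / (2 * h)
                assert analytic[i, c] == pytest.approx(numeric, rel=1e-5, abs=1e-6)

    def test_rigid_translation_leaves_energy_unchanged(self, dimer_ensemble):
        member = dimer_ensemble.members[0]
        params = dimer_ensemble.descriptor_params
        config = Configuration(
            ("C", "C"), np.array([[9.2, 10, 10], [10.8, 10, 10]]), Cell.cubic(20.0)
        )
        e0, _ = predict_member(member, config, params)
        e1, _ = predict_member(
            member, config.with_positions(config.positions + 2.345), params
        )
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_isolated_atoms_sum_per_element_baselines(self, dimer_ensemble):
        member = dimer_ensemble.members[0]
        params = dimer_ensemble.descriptor_params
        config = Configuration(
            ("C", "C"),
            np.array([[5.0, 5, 5], [45.0, 45, 45]]),
            Cell.cubic(60.0, periodic=False),
        )
        energy, forces = predict_member(member, config, params)
        c_index = params.elements.index("C")
        zero_G = np.zeros((1, params.n_features))
        baseline = member.atomic_energies(zero_G, np.array([c_index]))[0]
        assert energy == pytest.approx(2 * baseline, abs=1e-9)
        assert np.abs(forces).max() < 1e-9

    def test_unsupported_element_rejected(self, dimer_ensemble):
        params = DescriptorParams(elements=("H", "C"))
        config = Configuration(
            ("O", "O"), np.array([[5.0, 5, 5], [7.0, 5, 5]]), Cell.cubic(10)
        )
        with pytest.raises(ValueError, match="element"):
            predict_member(dimer_ensemble.members[0], config, params)


class TestTraining:
    def test_dimer_sweep_recovery(self, dimer_ensemble):
        """All members recover the toy dimer curve to sub-kcal/atom accuracy."""
        rmses = [
            m.history["test_energy_rmse_per_atom"] for m in dimer_ensemble.members
        ]
        assert max(rmses) < 0.5

    def test_too_small_dataset_suggests_fewer_blocks(self, dimer_sweep_dataset):
        with pytest.raises(ValueError, match="n_blocks"):
            train_ensemble(dimer_sweep_dataset[:5], TrainConfig())

    def test_single_repeated_configuration_is_interpolated(self, toy_potential):
        from nanoreax.system import LabeledSample

        cell = Cell.cubic(20.0)
        config = Configuration(
            ("C", "C"), np.array([[9.3, 10, 10], [10.7, 10, 10]]), cell
        )
        e, f = toy_potential.evaluate(config)
        dataset = [LabeledSample(config, e, f)] * 32
        ens = train_ensemble(dataset, TrainConfig(seed=1), rng=np.random.default_rng(1))
        pred, _ = ens.predict(config)
        assert pred == pytest.approx(e, abs=0.05)

    def test_extrapolation_raises_committee_variance(self, dimer_ensemble):
        """QBC energy spread far outside the trained distance range exceeds
        the spread at training distances (median over 20 probes each)."""
        cell = Cell.cubic(40.0)

        def eps_at(r):
            config = Configuration(
                ("C", "C"),
                np.array([[20 - r / 2, 20, 20], [20 + r / 2, 20, 20]]),
                cell,
            )
            return qbc_uncertainty(dimer_ensemble, config)[0]

        inside = np.median([eps_at(r) for r in np.linspace(1.4, 3.2, 20)])
        outside = np.median([eps_at(r) for r in np.linspace(5.5, 9.0, 20)])
        assert outside > inside

    def test_training_reproducible_under_fixed_seed(self, dimer_sweep_dataset):
        cfg = TrainConfig(seed=11, max_epochs=120)
        a = train_ensemble(
            dimer_sweep_dataset[:64], cfg, n_members=2, rng=np.random.default_rng(11)
        )
        b = train_ensemble(
            dimer_sweep_dataset[:64], cfg, n_members=2, rng=np.random.default_rng(11)
        )
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.weights, mb.weights)
            assert np.array_equal(ma.biases, mb.biases)
            assert abs(
                ma.history["final_val_loss"] - mb.history["final_val_loss"]
            ) < 1e-10

    def test_qbc_invariant_under_rotation_and_translation(self, dimer_ensemble):
        from scipy.spatial.transform import Rotation

        cell = Cell.cubic(60.0, periodic=False)
        config = Configuration(
            ("C", "C"), np.array([[29.1, 30, 30], [30.9, 30, 30]]), cell
        )
        base = qbc_uncertainty(dimer_ensemble, config)
        R = Rotation.random(random_state=3).as_matrix()
        center = config.positions.mean(axis=0)
        moved = config.with_positions(
            (config.positions - center) @ R.T + center + 4.2
        )
        rotated = qbc_uncertainty(dimer_ensemble, moved)
        assert rotated[0] == pytest.approx(base[0], rel=1e-6, abs=1e-9)
        assert rotated[1] == pytest.approx(base[1], rel=1e-6, abs=1e-9)
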