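import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actimetry.smd import (
    HarmonicRestraint,
    SteeringSchedule,
    next_center,
    restraint_energy_force,
    run_steering,
    stage_work_increment,
)


class GradientDescentBackend:
    """Zero-temperature backend: pure descent on the restraint energy.

    The deterministic limit of the steering loop — means coincide with
    positions once relaxed, so the center path and landing point are
    exactly predictable.
    """

    def __init__(self, labels, positions, step_size=0.002):
        self.labels = list(labels)
        self._pos = np.atleast_2d(np.asarray(positions, float)).copy()
        self.step_size = step_size

    def get_positions(self):
        return self._pos.copy()

    def run(self, n_steps, restraints, rng):
        index = {lab: i for i, lab in enumerate(self.labels)}
        for _ in range(n_steps):
            F = np.zeros_like(self._pos)
            for r in restraints:
                _, f = restraint_energy_force(self._pos[index[r.atom]], r)
                F[index[r.atom]] += f
            self._pos = self._pos + self.step_size * F


class TestNextCenter:
    def test_final_stage_returns_destination_bitwise(self):
        dest = np.array([0.3, -1.7, 2.2])
        out = next_center(np.array([0.1, 0.1, 0.1]), dest, i=20, n_stages=21)
        assert np.array_equal(out, dest)

    def test_destination_is_fixed_point(self):
        dest = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(next_center(dest, dest, 5, 21), dest)

    def test_direct_substitution(self):
        out = next_center(np.zeros(3), np.array([2.0, 0, 0]), i=1, n_stages=21)
        np.testing.assert_allclose(out, [0.1, 0, 0])

    @pytest.mark.parametrize("i", [0, 21, 25])
    def test_stage_index_bounds(self, i):
        with pytest.raises(IndexError):
            next_center(np.zeros(3), np.ones(3), i, 21)

    def test_endpoint_exact_on_random_instances(self):
        """r0^(N) = r* bitwise for any mean history (1000 random instances)."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            dest = rng.normal(size=3) * rng.uniform(0.1, 50)
            center = rng.normal(size=3) * 10
            for i in range(1, n):
                mean = center + rng.normal(size=3)  # arbitrary drifting mean
                center = next_center(mean, dest, i, n)
            assert np.array_equal(center, dest)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_contraction_identity(self, seed):
        """|r0^(i+1) - r*| = |<r> - r*| (N-i-1)/(N-i)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        i = int(rng.integers(1, n - 1))
        mean = rng.normal(size=3) * 5
        dest = rng.normal(size=3) * 5
        new = next_center(mean, dest, i, n)
        lhs = np.linalg.norm(new - dest)
        rhs = np.linalg.norm(mean - dest) * (n - i - 1) / (n - i)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestRestraint:
    def test_zero_at_center(self):
        r = HarmonicRestraint("a", np.array([1.0, 2, 3]), 500.0)
        u, f = restraint_energy_force(np.array([1.0, 2, 3]), r)
        assert u == 0.0
        np.testing.assert_array_equal(f, np.zeros(3))

    def test_protocol_constants_arithmetic(self):
        # k = 500 at 0.1 A offset -> 2.5 kcal/mol
        r = HarmonicRestraint("a", np.zeros(3), 500.0)
        u, _ = restraint_energy_force(np.array([0.1, 0, 0]), r)
        assert u == pytest.approx(2.5)

    def test_force_is_negative_gradient(self):
        rng = np.random.default_rng(12)
        r = HarmonicRestraint("a", rng.normal(size=3), 80.0)
        x = rng.normal(size=3)
        _, f = restraint_energy_force(x, r)
        h = 1e-5
        for d in range(3):
            e = np.zeros(3)
            e[d] = h
            up, _ = restraint_energy_force(x + e, r)
            dn, _ = restraint_energy_force(x - e, r)
            assert f[d] == pytest.approx(-(up - dn) / (2 * h), abs=1e-4)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            HarmonicRestraint("a", np.zeros(3), 0.0)


class TestWorkIncrement:
    def test_no_jump_no_work(self):
        c = np.random.default_rng(0).normal(size=(4, 3))
        assert stage_work_increment(c, c + 1.0, c + 1.0, 500.0) == 0.0

    def test_single_atom_at_old_center(self):
        r = np.zeros((1, 3))
        new = np.array([[0.2, 0, 0]])
        # U goes from 0 to k d^2 / 2
        assert stage_work_increment(r, r, new, 500.0) == pytest.approx(
            0.5 * 500 * 0.04
        )

    def test_matches_energy_sum_oracle(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(6, 3))
        old = rng.normal(size=(6, 3))
        new = rng.normal(size=(6, 3))
        k = 80.0
        oracle = 0.0
        for x, co, cn in zip(coords, old, new):
            uo, _ = restraint_energy_force(x, HarmonicRestraint("a", co, k))
            un, _ = restraint_energy_force(x, HarmonicRestraint("a", cn, k))
            oracle += un - uo
        assert stage_work_increment(coords, old, new, k) == pytest.approx(oracle)

    def test_additive_over_atom_groups(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(8, 3))
        old = rng.normal(size=(8, 3))
        new = rng.normal(size=(8, 3))
        whole = stage_work_increment(coords, old, new, 500.0)
        split = stage_work_increment(coords[:3], old[:3], new[:3], 500.0)
        split += stage_work_increment(coords[3:], old[3:], new[3:], 500.0)
        assert whole == pytest.approx(split, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stage_work_increment(np.zeros((2, 3)), np.zeros((3, 3)), np.zeros((3, 3)), 1.0)


class TestRunSteering:
    def test_zero_temperature_geometric_approach_and_exact_landing(self):
        start = np.zeros((1, 3))
        dest = np.array([[2.1, 0.0, 0.0]])
        backend = GradientDescentBackend(["p"], start)
        sched = SteeringSchedule(
            moved_atoms=["p"],
            destinations=dest,
            n_stages=21,
            k_pull=500.0,
            stage_steps=200,
        )
        state, trace = run_steering(backend, sched, seed=0)
        assert np.array_equal(state.centers, dest)
        np.testing.assert_allclose(backend.get_positions(), dest, atol=1e-6)
        # means coincide with centers once relaxed
        sub = trace[trace.atom == "p"]
        np.testing.assert_allclose(
            sub["mean_x"].to_numpy(), sub["center_x"].to_numpy(), atol=1e-5
        )

    def test_per_stage_shift_magnitude_for_protocol_displacement(self):
        """A 2.1 A pull over N = 21 stages advances the center by about
        0.105 A per stage when the atom tracks the restraint."""
        backend = GradientDescentBackend(["p"], np.zeros((1, 3)))
        sched = SteeringSchedule(
            moved_atoms=["p"],
            destinations=np.array([[2.1, 0.0, 0.0]]),
            n_stages=21,
            k_pull=500.0,
            stage_steps=200,
        )
        _, trace = run_steering(backend, sched, seed=0)
        shifts = trace[trace.atom == "p"]["center_x"].diff().dropna().to_numpy()
        assert shifts.shape == (20,)
        assert np.all((shifts > 0.09) & (shifts < 0.16))

    def test_core_atoms_stay_restrained_in_place(self):
        labels = ["p", "c1", "c2"]
        start = np.array([[0.0, 0, 0], [5.0, 0, 0], [0.0, 5, 0]])
        backend = GradientDescentBackend(labels, start)
        sched = SteeringSchedule(
            moved_atoms=["p"],
            destinations=np.array([[2.0, 0, 0]]),
            n_stages=5,
            k_pull=500.0,
            k_core=80.0,
            core_atoms=["c1", "c2"],
            stage_steps=200,
        )
        run_steering(backend, sched, seed=0)
        final = backend.get_positions()
        np.testing.assert_allclose(final[1], [5.0, 0, 0], atol=1e-8)
        np.testing.assert_allclose(final[2], [0.0, 5, 0], atol=1e-8)

    def test_work_additivity_over_atom_split(self):
        # pulling two independent atoms accumulates the sum of the
        # single-atom works (same seeds, deterministic backend)
        dest = np.array([[1.0, 0, 0], [0, 2.0, 0]])
        both = GradientDescentBackend(["a", "b"], np.zeros((2, 3)))
        sched = SteeringSchedule(
            moved_atoms=["a", "b"], destinations=dest, n_stages=11, stage_steps=200
        )
        w_both, _ = run_steering(both, sched, seed=0)
        total = 0.0
        for j, atom in enumerate(["a", "b"]):
            single = GradientDescentBackend([atom], np.zeros((1, 3)))
            s = SteeringSchedule(
                moved_atoms=[atom],
                destinations=dest[j : j + 1],
                n_stages=11,
                stage_steps=200,
            )
            w, _ = run_steering(single, s, seed=0)
            total += w.work
        assert w_both.work == pytest.approx(total, rel=1e-9)

    def test_unknown_atom_label_rejected(self):
        backend = GradientDescentBackend(["p"], np.zeros((1, 3)))
        sched = SteeringSchedule(
            moved_atoms=["ghost"], destinations=np.array([[1.0, 0, 0]])
        )
        with pytest.raises(KeyError, match="ghost"):
            run_steering(backend, sched, seed=0)

    def test_backend_failure_reports_stage(self):
        class Exploding(GradientDescentBackend):
            def run(self, n_steps, restraints, rng):
                raise FloatingPointError("boom")

        backend = Exploding(["p"], np.zeros((1, 3)))
        sched = SteeringSchedule(
            moved_atoms=["p"], destinations=np.array([[1.0, 0, 0]])
        )
        with pytest.raises(RuntimeError, match="stage 1"):
            run_steering(backend, sched, seed=0)


class TestScheduleValidation:
    def test_overlapping_core_and_moved_rejected(self):
        with pytest.raises(ValueError):
            SteeringSchedule(
                moved_atoms=["a"],
                destinations=np.zeros((1, 3)),
                core_atoms=["a"],
            )

    def test_minimum_two_stages(self):
        with pytest.raises(ValueError):
            SteeringSchedule(
                moved_atoms=["a"], destinations=np.zeros((1, 3)), n_stages=1
            )
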