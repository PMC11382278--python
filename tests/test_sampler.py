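"""Langevin sampler: determinism, bookkeeping, and thermostat physics."""

import numpy as np
import pytest

import evbkit as ek
from evbkit.sampler import LambdaSchedule, default_ramp, equilibrate, run_frame, run_ladder
from evbkit.systems import make_marcus_system
from evbkit.core import EVBParameters


def _well(k=100.0):
    """Single-well system (both diabats identical) for thermostat checks."""
    return make_marcus_system(k, k, 0.0, 1e-6, 0.0, EVBParameters(0.0))


def _block_sem(x, n_blocks=20):
    """Standard error from block averages (robust to autocorrelation)."""
    blocks = np.array_split(np.asarray(x), n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(len(means))


class TestLambdaSchedule:
    def test_uniform_default_has_51_frames(self):
        s = LambdaSchedule.uniform()
        assert len(s) == 51
        assert s.values[0] == 0.0 and s.values[-1] == 1.0

    @pytest.mark.parametrize(
        "values",
        [[0.0, 0.5, 0.5, 1.0], [0.1, 0.5, 1.0], [0.0, 0.5, 0.9], [1.0, 0.0]],
    )
    def test_invalid_schedules_rejected(self, values):
        with pytest.raises(ValueError):
            LambdaSchedule(np.array(values))


class TestRunFrame:
    def test_zero_steps_returns_initial_configuration_only(self):
        frame = run_frame(_well(), lam=0.0, n_steps=0, seed=1)
        assert len(frame.eps1) == 1
        assert frame.x.shape == (1, 1)
        assert frame.eps1[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_seed_gives_bit_identical_samples(self):
        a = run_frame(_well(), lam=0.3, n_steps=2000, seed=7)
        b = run_frame(_well(), lam=0.3, n_steps=2000, seed=7)
        assert np.array_equal(a.eps1, b.eps1)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.v_final, b.v_final)

    def test_saved_sample_count_contract(self):
        n, stride, burn_frac = 10_000, 10, 0.2
        frame = run_frame(_well(), 0.0, n, stride=stride, burn_in_frac=burn_frac, seed=0)
        burn = int(burn_frac * n)
        assert len(frame.eps1) == (n - burn) // stride
        double = run_frame(_well(), 0.0, 2 * n, stride=stride, burn_in_frac=burn_frac, seed=0)
        assert len(double.eps1) == 2 * len(frame.eps1)

    def test_mapping_energy_record_consistency(self):
        frame = run_frame(_well(), lam=0.4, n_steps=2000, seed=3)
        expected = 0.6 * frame.eps1 + 0.4 * frame.eps2
        np.testing.assert_allclose(frame.e_map, expected, atol=1e-8)

    def test_equipartition_variance_in_harmonic_well(self):
        """Sample variance of x matches kT/k within 3 block standard errors."""
        k_spring, temp = 100.0, 310.0
        frame = run_frame(
            _well(k_spring), 0.0, n_steps=200_000, dt=0.5, temperature=temp, seed=5, stride=5
        )
        x = frame.x[:, 0]
        var = np.var(x)
        target = ek.thermal_energy(temp) / k_spring
        sem = _block_sem((x - x.mean()) ** 2)
        assert abs(var - target) < 3 * sem

    def test_kinetic_temperature_matches_thermostat(self):
        frame = run_frame(_well(), 0.0, n_steps=50_000, temperature=310.0, seed=2)
        assert frame.kinetic_temperature == pytest.approx(310.0, rel=0.05)

    def test_diverging_frame_raises_with_diagnostic(self):
        # enormous time-step on a stiff well: the integrator blows up
        with pytest.raises(RuntimeError, match="diverged"):
            run_frame(_well(5000.0), 0.0, n_steps=5000, dt=50.0, seed=0)

    @pytest.mark.parametrize(
        "kw", [dict(n_steps=-1), dict(dt=0.0), dict(temperature=-5.0), dict(stride=0)]
    )
    def test_invalid_settings_rejected(self, kw):
        args = dict(lam=0.0, n_steps=100, seed=0)
        args.update(kw)
        with pytest.raises(ValueError):
            run_frame(_well(), **args)


class TestEquilibrate:
    def test_decreasing_ramp_rejected(self):
        ramp = [(310.0, 0.5, 2.0), (100.0, 1.0, 1.0)]
        with pytest.raises(ValueError, match="non-decreasing"):
            equilibrate(_well(), 100.0, ramp=ramp, seed=0)

    def test_ramp_must_end_at_target(self):
        with pytest.raises(ValueError, match="target"):
            equilibrate(_well(), 310.0, ramp=[(1.0, 0.1, 1.0), (200.0, 1.0, 1.0)], seed=0)

    def test_default_ramp_reaches_target_temperature(self):
        """Final-stage kinetic temperature within 20% of 310 K."""
        res = equilibrate(_well(), 310.0, seed=4, steps_per_stage=5000)
        assert abs(res.kinetic_temperature - 310.0) / 310.0 < 0.2

    def test_default_ramp_structure(self):
        ramp = default_ramp(310.0)
        temps = [s[0] for s in ramp]
        dts = [s[1] for s in ramp]
        assert temps[0] == 1.0 and temps[-1] == 310.0
        assert dts[0] == pytest.approx(0.1) and dts[-1] == pytest.approx(1.0)


class TestRunLadder:
    def test_two_frame_bookkeeping(self):
        sched = LambdaSchedule(np.array([0.0, 1.0]))
        ss = run_ladder(_well(), sched, n_replicas=1, n_steps=100, base_seed=0)
        assert sorted(ss.data["frame"].unique()) == [0, 1]
        assert ss.replicas == [0]
        ss.validate()

    def test_symmetric_system_mean_gap_vanishes_at_midpoint(self):
        """At lambda = 0.5 the sampled density of a symmetric pair is even in the gap."""
        sys_ = make_marcus_system(200.0, 200.0, -0.5, 0.5, 0.0, EVBParameters(10.0))
        frame = run_frame(sys_, 0.5, n_steps=100_000, x0=np.array([0.0]), seed=9)
        gap = frame.eps2 - frame.eps1
        assert abs(gap.mean()) < 3 * _block_sem(gap)

    def test_replicas_are_distinct_streams(self):
        sched = LambdaSchedule(np.array([0.0, 1.0]))
        ss = run_ladder(_well(), sched, n_replicas=3, n_steps=500, base_seed=0)
        means = ss.data.groupby("replica")["e_map"].mean()
        assert len(set(np.round(means, 12))) == 3

    def test_ladder_determinism(self):
        sys_ = make_marcus_system(200.0, 200.0, 0.0, 1.0, 0.0, EVBParameters(5.0))
        sched = LambdaSchedule.uniform(5)
        a = run_ladder(sys_, sched, n_replicas=2, n_steps=500, base_seed=3)
        b = run_ladder(sys_, sched, n_replicas=2, n_steps=500, base_seed=3)
        assert a.data.equals(b.data)

    def test_persistence_round_trip(self, tmp_path):
        sched = LambdaSchedule(np.array([0.0, 0.5, 1.0]))
        ss = run_ladder(_well(), sched, n_replicas=2, n_steps=300, base_seed=1)
        ss.to_dir(tmp_path)
        back = ek.SampleSet.from_dir(tmp_path)
        back.validate()
        assert back.replicas == ss.replicas
        np.testing.assert_allclose(
            back.data["e_map"].to_numpy(), ss.data["e_map"].to_numpy(), rtol=1e-12
        )

    def test_invalid_replica_count_rejected(self):
        with pytest.raises(ValueError):
            run_ladder(_well(), LambdaSchedule.uniform(3), n_replicas=0)
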