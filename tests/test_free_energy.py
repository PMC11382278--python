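"""FEP/US estimator: exponential averaging, binning, thermo extraction."""

import warnings

import numpy as np
import pandas as pd
import pytest

import evbkit as ek
from evbkit.core import EVBParameters
from evbkit.free_energy import (
    FreeEnergyProfile,
    MissingBinsError,
    NoBarrierError,
    ReactionThermo,
    analyze,
    extract_thermo,
    fep_increment,
    replica_errors,
    us_profile,
)
from evbkit.quadrature import exact_profile_quadrature
from evbkit.sampler import LambdaSchedule, SampleSet, run_frame, run_ladder
from evbkit.systems import make_marcus_system

KT = ek.thermal_energy(310.0)


def _profile(values, centers=None, counts=None, sem=None, anchor="unanchored"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    centers = np.arange(n, dtype=float) if centers is None else np.asarray(centers, float)
    w = centers[1] - centers[0]
    edges = np.append(centers - w / 2, centers[-1] + w / 2)
    counts = np.ones(n) if counts is None else np.asarray(counts, float)
    sem = np.full(n, np.nan) if sem is None else np.asarray(sem, float)
    return FreeEnergyProfile(edges, values, counts, sem, anchor)


class TestFepIncrement:
    def test_constant_shift_is_exact(self):
        e_i = np.zeros(100)
        for c in (-3.2, 0.0, 7.5):
            assert fep_increment(e_i, e_i + c, KT) == pytest.approx(c, abs=1e-12)

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fep_increment(np.array([]), np.array([]), KT)

    def test_nonpositive_kt_rejected(self):
        with pytest.raises(ValueError):
            fep_increment(np.zeros(3), np.ones(3), 0.0)

    def test_gaussian_work_second_cumulant(self):
        """For Gaussian work, dG = mu - sigma^2 / (2 kT)."""
        rng = np.random.default_rng(12)
        mu, sigma, n = 1.0, 0.5, 100_000
        w = rng.normal(mu, sigma, n)
        est = fep_increment(np.zeros(n), w, KT)
        expected = mu - sigma**2 / (2 * KT)
        # standard error of the exponential-average estimator
        se = KT * np.sqrt((np.exp(sigma**2 / KT**2) - 1) / n)
        assert abs(est - expected) < 3 * se


class TestForwardBackwardConsistency:
    def test_zwanzig_chain_closes_on_well_sampled_ladder(self, sampled_ladders):
        """Forward plus reverse one-sided sums vanish within replica error."""
        ss = sampled_ladders["symmetric"]
        closures = []
        for r in ss.replicas:
            df = ss.for_replica(r)
            frames = [
                (float(sub["lam"].iloc[0]), sub["eps1"].to_numpy(), sub["eps2"].to_numpy())
                for _, sub in df.groupby("frame")
            ]
            total = 0.0
            for (l0, e1, e2), (l1, _, _) in zip(frames, frames[1:]):
                total += fep_increment((1 - l0) * e1 + l0 * e2, (1 - l1) * e1 + l1 * e2, KT)
            for (l0, _, _), (l1, e1, e2) in zip(frames, frames[1:]):
                total += fep_increment((1 - l1) * e1 + l1 * e2, (1 - l0) * e1 + l0 * e2, KT)
            closures.append(total)
        closures = np.array(closures)
        sem = closures.std(ddof=1) / np.sqrt(len(closures))
        assert abs(closures.mean()) < 3 * sem


class TestUsProfile:
    def test_single_lambda_frame_matches_quadrature(self):
        """h = 0, lambda = 0 only: the profile is the state-1 Boltzmann profile."""
        sys_ = make_marcus_system(100.0, 100.0, 0.0, 1.0, 0.0, EVBParameters(0.0))
        rows = []
        for r in range(5):
            frame = run_frame(sys_, 0.0, n_steps=40_000, seed=100 + r)
            rows.append(
                pd.DataFrame(
                    {
                        "replica": r,
                        "frame": 0,
                        "lam": 0.0,
                        "step": frame.steps,
                        "eps1": frame.eps1,
                        "eps2": frame.eps2,
                        "e_map": frame.e_map,
                    }
                )
            )
        ss = SampleSet(pd.concat(rows, ignore_index=True), {"temperature": 310.0})
        prof = us_profile(ss, sys_.params, KT, bin_width=2.0, min_replicas=5)
        oracle = exact_profile_quadrature(sys_, KT, prof.bin_edges)
        # compare over the well-sampled core of the reactant basin
        sel = prof.populated & oracle.populated & (prof.counts >= 50) & np.isfinite(prof.sem)
        assert sel.sum() >= 5
        dev = np.abs(prof.dg[sel] - oracle.dg[sel])
        # anchor bins coincide, so deviations are purely statistical
        assert np.all(dev <= np.maximum(3 * prof.sem[sel], 0.05))

    def test_symmetric_system_reaction_free_energy_vanishes(self, sampled_ladders):
        ss = sampled_ladders["symmetric"]
        _, _, pooled = analyze(ss, EVBParameters(10.0), KT)
        assert abs(pooled.dg_rxn) < 3 * pooled.err_rxn

    def test_gauge_invariance_of_thermo(self):
        """Adding a constant to both diabats leaves dG_act and dG_rxn unchanged."""
        from evbkit import terms as t
        from evbkit.systems import DiabaticSystem

        base = make_marcus_system(200.0, 200.0, 0.0, 1.0, 0.0, EVBParameters(8.0))
        shifted = DiabaticSystem(
            dimension=1,
            state1_terms=base.state1_terms + (t.Constant(30.0),),
            state2_terms=base.state2_terms + (t.Constant(30.0),),
            masses=base.masses,
            params=base.params,
        )
        sched = LambdaSchedule.uniform(21)
        kw = dict(n_replicas=3, n_steps=4000, base_seed=5)
        _, _, a = analyze(run_ladder(base, sched, **kw), base.params, KT)
        _, _, b = analyze(run_ladder(shifted, sched, **kw), base.params, KT)
        # identical noise streams and identical forces: exactly the same thermo
        assert b.dg_act == pytest.approx(a.dg_act, abs=1e-9)
        assert b.dg_rxn == pytest.approx(a.dg_rxn, abs=1e-9)

    def test_unpopulated_bins_are_missing_not_zero(self, sampled_ladders):
        ss = sampled_ladders["symmetric"]
        edges = np.arange(-500.0, 502.0, 2.0)  # far wider than any sampled gap
        prof = us_profile(ss, EVBParameters(10.0), KT, bin_edges=edges)
        assert np.isnan(prof.dg[0]) and np.isnan(prof.dg[-1])
        assert prof.counts[0] == 0


class TestExtractThermo:
    def test_three_point_barrier(self):
        thermo = extract_thermo(_profile([0.0, 5.0, 2.0]), reactant_side="low")
        assert thermo.dg_act == pytest.approx(5.0)
        assert thermo.dg_rxn == pytest.approx(2.0)

    def test_three_point_exergonic(self):
        thermo = extract_thermo(_profile([0.0, 5.0, -10.0]), reactant_side="low")
        assert thermo.dg_act == pytest.approx(5.0)
        assert thermo.dg_rxn == pytest.approx(-10.0)

    def test_monotone_profile_has_no_barrier(self):
        with pytest.raises(NoBarrierError):
            extract_thermo(_profile([0.0, 1.0, 2.0, 3.0, 4.0]), reactant_side="low")

    def test_missing_interior_bins_invalidate(self):
        vals = [0.0, 2.0, np.nan, 4.0, 1.0, -3.0]
        counts = [5, 5, 0, 5, 5, 5]
        with pytest.raises(MissingBinsError):
            extract_thermo(_profile(vals, counts=counts), reactant_side="low")

    def test_ts_tie_breaks_toward_zero_gap(self):
        centers = np.array([-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0])
        vals = [1.0, 5.0, 3.0, 5.0, 3.0, 5.0, 0.0]
        thermo = extract_thermo(_profile(vals, centers=centers), reactant_side="low")
        assert thermo.ts_gap == pytest.approx(0.0)

    def test_high_side_reactant(self):
        thermo = extract_thermo(_profile([-7.0, 4.0, 0.0]), reactant_side="high")
        assert thermo.dg_act == pytest.approx(4.0)
        assert thermo.dg_rxn == pytest.approx(-7.0)


class TestReplicaErrors:
    def test_identical_replicas_have_zero_error(self):
        t = ReactionThermo(dg_act=3.0, dg_rxn=-1.0)
        pooled = replica_errors([t, t, t])
        assert pooled.err_act == 0.0 and pooled.err_rxn == 0.0

    def test_hand_computed_sem(self):
        ts = [ReactionThermo(dg_act=v, dg_rxn=0.0) for v in (1.0, 2.0, 3.0)]
        pooled = replica_errors(ts)
        assert pooled.dg_act == pytest.approx(2.0)
        assert pooled.err_act == pytest.approx(1.0 / np.sqrt(3), abs=1e-12)

    def test_single_replica_flagged_undefined(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            pooled = replica_errors([ReactionThermo(dg_act=1.0, dg_rxn=0.0)])
        assert np.isnan(pooled.err_act)

    def test_sem_shrinks_roughly_as_root_n(self):
        """Pooled SEM over 16 short replicas vs the first 4: ratio near 2."""
        sys_ = make_marcus_system(200.0, 200.0, 0.0, 1.0, 0.0, EVBParameters(10.0))
        ss = run_ladder(sys_, LambdaSchedule.uniform(11), n_replicas=16, n_steps=2000, base_seed=21)
        _, thermos, _ = analyze(ss, sys_.params, KT)
        few = replica_errors(thermos[:4])
        many = replica_errors(thermos)
        ratio = few.err_act / many.err_act
        assert 1.1 < ratio < 3.6


class TestProfileContainer:
    def test_tsv_round_trip(self, tmp_path):
        prof = _profile([0.0, 3.0, 1.0], sem=[0.1, 0.2, 0.1], anchor="reactant=low")
        path = tmp_path / "profile.tsv"
        prof.to_tsv(path)
        back = FreeEnergyProfile.from_tsv(path)
        np.testing.assert_allclose(back.dg, prof.dg)
        np.testing.assert_allclose(back.sem, prof.sem)
        assert back.anchor == prof.anchor

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            FreeEnergyProfile(np.array([0.0, 1.0]), np.zeros(2), np.zeros(1), np.zeros(1))
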