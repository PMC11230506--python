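"""Boost potential algebra, parameter selection, running statistics and the
Langevin integrator's sampling accuracy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from gpcrkit.constants import KB, kbt
from gpcrkit.gamd import (BoostParams, GaMDProtocol, PotentialStats,
                          RunningStats, boost_energy, boost_force_scale,
                          count_well_crossings, predicted_boost_sd,
                          run_protocol, run_stage, select_boost_params,
                          update_stats)
from gpcrkit.potentials import PotentialModel, make_double_well


class Harmonic1D(PotentialModel):
    """V = 1/2 kappa x^2 — closed-form marginal for integrator checks."""

    def __init__(self, kappa=1.0, mass=10.0):
        self.kappa = kappa
        self.ndim = 1
        self.masses = np.full(1, float(mass))
        self.default_start = np.zeros(1)

    def energy_force(self, x):
        q = x[0]
        return 0.5 * self.kappa * q * q, 0.0, np.array([-self.kappa * q]), np.zeros(1)


class TestBoostAlgebra:
    def test_boost_zero_at_and_above_threshold(self):
        p = BoostParams(e=10.0, k=0.02, k0=0.5)
        assert boost_energy(10.0, p) == 0.0
        assert boost_energy(12.0, p) == 0.0

    def test_boost_quadratic_below_threshold(self):
        p = BoostParams(e=10.0, k=0.02, k0=0.5)
        assert boost_energy(5.0, p) == pytest.approx(0.25)

    def test_force_scale_limits(self):
        stats = PotentialStats(100.0, 0.0, 50.0, 10.0, 100)
        p = select_boost_params(stats, sigma0=6.0, bound="lower")
        assert boost_force_scale(150.0, p) == 1.0
        assert boost_force_scale(0.0, p) == pytest.approx(1.0 - p.k0)
        # k0 = 1 flattens the landscape completely at Vmin
        p1 = BoostParams(e=100.0, k=0.01, k0=1.0)
        assert boost_force_scale(0.0, p1) == pytest.approx(0.0)

    @given(st.floats(-50, 99), st.floats(-50, 99))
    def test_order_preservation_and_smoothing(self, v1, v2):
        # boosted energies keep their order and come closer together
        p = BoostParams(e=100.0, k=0.005, k0=1.0)
        lo, hi = sorted((v1, v2))
        if hi - lo < 1e-9:
            return
        b_lo = lo + boost_energy(lo, p)
        b_hi = hi + boost_energy(hi, p)
        assert b_lo < b_hi
        assert (b_hi - b_lo) <= (hi - lo) + 1e-12


class TestParameterSelection:
    def test_lower_bound_example(self):
        stats = PotentialStats(100.0, 0.0, 50.0, 10.0, 100)
        p = select_boost_params(stats, 6.0, "lower")
        assert p.k0 == pytest.approx(1.0)
        assert p.k == pytest.approx(0.01)
        assert p.e == pytest.approx(100.0)

    def test_upper_bound_accepted(self):
        stats = PotentialStats(100.0, 0.0, 50.0, 12.0, 100)
        p = select_boost_params(stats, 6.0, "upper")
        assert p.bound == "upper"
        assert p.k0 == pytest.approx(1.0)
        assert p.e == pytest.approx(stats.vmin + 1.0 / p.k)
        assert p.e == pytest.approx(100.0)

    def test_upper_bound_fallback_to_lower(self):
        stats = PotentialStats(100.0, 0.0, 50.0, 6.0, 100)
        p = select_boost_params(stats, 6.0, "upper")
        assert p.bound == "lower"
        assert p.k0 == pytest.approx(1.0)
        assert p.e == pytest.approx(100.0)

    def test_degenerate_statistics_error(self):
        with pytest.raises(ValueError):
            select_boost_params(PotentialStats(5.0, 5.0, 5.0, 0.0, 10), 6.0)

    @given(st.floats(1.0, 500.0), st.floats(0.01, 0.99), st.floats(0.01, 50.0),
           st.floats(0.5, 20.0), st.sampled_from(["lower", "upper"]))
    def test_selection_invariants(self, spread, frac, sigma_v, sigma0, bound):
        # k0 in (0,1]; predicted boost SD <= sigma0; exact equality when the
        # upper-bound formula is accepted
        vavg = frac * spread
        sigma_v = min(sigma_v, 0.49 * spread)
        stats = PotentialStats(spread, 0.0, vavg, sigma_v, 1000)
        p = select_boost_params(stats, sigma0, bound)
        assert 0.0 < p.k0 <= 1.0
        sd = predicted_boost_sd(p, stats)
        assert sd <= sigma0 + 1e-9
        if p.bound == "upper":
            assert sd == pytest.approx(sigma0, abs=1e-9)
        elif p.k0 < 1.0:
            assert sd == pytest.approx(sigma0, abs=1e-9)


class TestRunningStats:
    def test_single_value(self):
        s = update_stats(None, 3.0)
        assert (s.vmax, s.vmin, s.vavg, s.sigma_v) == (3.0, 3.0, 3.0, 0.0)

    def test_stream_matches_population_formulas(self):
        s = None
        for v in (1.0, 2.0, 3.0):
            s = update_stats(s, v)
        assert s.vmax == 3.0 and s.vmin == 1.0
        assert s.vavg == pytest.approx(2.0)
        assert s.sigma_v == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-6)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_order_invariance(self, values, rnd):
        def final(vals):
            s = None
            for v in vals:
                s = update_stats(s, v)
            return s

        shuffled = list(values)
        rnd.shuffle(shuffled)
        a, b = final(values), final(shuffled)
        assert a.vmax == b.vmax and a.vmin == b.vmin
        assert a.vavg == pytest.approx(b.vavg, abs=1e-8)
        assert a.sigma_v == pytest.approx(b.sigma_v, abs=1e-6)

    def test_accumulator_matches_numpy(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 3, 1000)
        acc = RunningStats()
        acc.add_many(vals)
        s = acc.snapshot()
        assert s.vavg == pytest.approx(vals.mean(), rel=1e-12)
        assert s.sigma_v == pytest.approx(vals.std(), rel=1e-9)


class TestIntegrator:
    def test_equipartition_on_harmonic_well(self):
        model = Harmonic1D(kappa=1.0)
        protocol = GaMDProtocol(dt=0.01, save_every=10)
        rng = np.random.default_rng(42)
        v0 = np.sqrt(KB * 310.0 * 418.4 / model.masses) * rng.standard_normal(1)
        frag, *_ = run_stage(model, model.default_start, v0, None, 1_000_000,
                             protocol, rng)
        x2 = np.mean(frag.coords[:, 0] ** 2)
        expected = kbt(310.0) / model.kappa
        assert x2 == pytest.approx(expected, rel=0.05)

    def test_harmonic_marginal_is_gaussian(self):
        model = Harmonic1D(kappa=1.0)
        protocol = GaMDProtocol(dt=0.01, save_every=10)
        rng = np.random.default_rng(1)
        v0 = np.sqrt(KB * 310.0 * 418.4 / model.masses) * rng.standard_normal(1)
        frag, *_ = run_stage(model, model.default_start, v0, None, 500_000,
                             protocol, rng)
        thinned = frag.coords[::5, 0][:10_000]
        sd = np.sqrt(kbt(310.0) / model.kappa)
        assert sps.kstest(thinned, "norm", args=(0.0, sd)).pvalue > 0.01

    def test_boosted_frames_respect_threshold(self, double_well_gamd):
        _, _, traj = double_well_gamd
        prod = traj.combined_production()
        p = traj.final_params["total"]
        above = prod.v_total >= p.e
        assert np.all(prod.dv_total[above] == 0.0)
        assert np.all(prod.dv >= 0.0)

    def test_nonfinite_energy_aborts_with_frame_index(self):
        model = Harmonic1D(kappa=1.0)
        protocol = GaMDProtocol(dt=50.0)  # grossly unstable step
        rng = np.random.default_rng(0)
        with pytest.raises(FloatingPointError, match="step"):
            run_stage(model, np.array([1.0]), np.array([10.0]), None, 10_000,
                      protocol, rng)


class TestProtocol:
    def test_mode_none_reduces_to_plain_langevin(self):
        dw = make_double_well(1.0, 1.0)
        staged = GaMDProtocol(n_cmd=2_000, n_equil=3_000, n_production=5_000,
                              mode="none")
        flat = GaMDProtocol(n_cmd=10_000, n_equil=0, n_production=0, mode="none")
        a = run_protocol(dw, staged, seed=9).combined_production()
        b = run_protocol(dw, flat, seed=9).cmd
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.v_total, b.v_total)

    def test_dual_boost_params_satisfy_sigma0(self):
        from gpcrkit.potentials import make_gprotein_toy, wt_analog_spec

        toy = make_gprotein_toy(wt_analog_spec())
        protocol = GaMDProtocol(n_cmd=4_000, n_equil=8_000, n_production=2_000,
                                stats_cadence=2_000, mode="dual")
        traj = run_protocol(toy, protocol, seed=13)
        for term in ("soft", "total"):
            p = traj.final_params[term]
            assert p is not None and 0.0 < p.k0 <= 1.0

    def test_replicas_distinct_but_same_protocol(self):
        dw = make_double_well(1.0, 1.0)
        protocol = GaMDProtocol(n_cmd=2_000, n_equil=2_000, n_production=3_000,
                                mode="single", replicas=3)
        traj = run_protocol(dw, protocol, seed=21)
        assert len(traj.production) == 3
        assert not np.array_equal(traj.production[0].coords,
                                  traj.production[1].coords)
        assert traj.production[0].times.size == traj.production[2].times.size

    def test_empty_cmd_with_boost_is_configuration_error(self):
        dw = make_double_well(1.0, 1.0)
        protocol = GaMDProtocol(n_cmd=0, n_equil=1_000, n_production=1_000,
                                mode="single")
        with pytest.raises(ValueError):
            run_protocol(dw, protocol, seed=0)

    def test_boost_accelerates_barrier_crossing(self):
        # paired seeds on a 5 kcal/mol barrier: boosted runs must cross at
        # least as often, and strictly more often in most pairs (sign test)
        dw = make_double_well(1.0, 1.5)
        wins = 0
        n_pairs = 8
        for seed in range(n_pairs):
            boosted = GaMDProtocol(n_cmd=20_000, n_equil=30_000,
                                   n_production=100_000, stats_cadence=5_000,
                                   mode="single")
            plain = GaMDProtocol(n_cmd=0, n_equil=0, n_production=100_000,
                                 mode="none")
            tb = run_protocol(dw, boosted, seed=seed).combined_production()
            tu = run_protocol(dw, plain, seed=seed).combined_production()
            cb = count_well_crossings(tb.coords[:, 0], 1.5)
            cu = count_well_crossings(tu.coords[:, 0], 1.5)
            assert cb >= cu
            wins += cb > cu
        # one-sided sign test at p < 0.05
        assert sps.binomtest(wins, n_pairs, 0.5, alternative="greater").pvalue < 0.05
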