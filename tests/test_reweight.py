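"""Cumulant-expansion reweighting, the exponential-average oracle, the
anharmonicity diagnostic, basin finding and nucleotide-state labeling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gpcrkit.constants import kbt
from gpcrkit.reweight import (Basin, CVSeries, FESGrid, anharmonicity,
                              bootstrap_pmf_error, classify_gdp_state,
                              cumulant_reweight_pmf, exact_exponential_reweight,
                              find_basins, grid_anharmonicity)


def _series(values):
    return CVSeries("x", "A", values)


class TestReweightIdentities:
    def test_zero_boost_equals_unweighted_histogram(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20_000)
        fes = cumulant_reweight_pmf(_series(x), np.zeros(x.size),
                                    bin_sizes=0.25, cutoff=50)
        hist, _ = np.histogram(x, bins=fes.edges[0])
        t = kbt(310.0)
        with np.errstate(divide="ignore"):
            ref = -t * np.log(hist / hist.sum())
        ref = np.where(hist < 50, np.nan, ref)
        ref -= np.nanmin(ref)
        ok = ~fes.mask
        np.testing.assert_allclose(fes.free_energy[ok], ref[ok], atol=1e-12)

    def test_constant_boost_shift_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20_000)
        a = cumulant_reweight_pmf(_series(x), np.zeros(x.size), bin_sizes=0.25)
        b = cumulant_reweight_pmf(_series(x), np.full(x.size, 7.3), bin_sizes=0.25)
        ok = ~a.mask
        np.testing.assert_allclose(a.free_energy[ok], b.free_energy[ok], atol=1e-9)

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 10_000)
        dv = rng.gamma(2.0, 1.0, x.size)
        perm = rng.permutation(x.size)
        a = cumulant_reweight_pmf(_series(x), dv, bin_sizes=0.25)
        b = cumulant_reweight_pmf(_series(x[perm]), dv[perm], bin_sizes=0.25,
                                  edges=a.edges)
        ok = ~a.mask
        np.testing.assert_allclose(a.free_energy[ok], b.free_energy[ok], atol=1e-9)

    def test_exponential_equals_cumulant_for_zero_boost(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10_000)
        a = cumulant_reweight_pmf(_series(x), np.zeros(x.size), bin_sizes=0.5)
        b = exact_exponential_reweight(_series(x), np.zeros(x.size), bin_sizes=0.5,
                                       edges=a.edges)
        ok = ~a.mask
        np.testing.assert_allclose(a.free_energy[ok], b.free_energy[ok], atol=1e-12)

    def test_single_bin_lognormal_closed_form(self):
        # Gaussian boost in one bin: log-mean-exp == mean + var/(2 kBT)
        t = kbt(310.0)
        rng = np.random.default_rng(4)
        sigma = 2.0 * t
        dv = rng.normal(3.0, sigma, 100_000)
        x = np.zeros(dv.size)
        a = cumulant_reweight_pmf(_series(x), dv, bin_sizes=1.0, cutoff=10)
        b = exact_exponential_reweight(_series(x), dv, bin_sizes=1.0, cutoff=10,
                                       edges=a.edges)
        # both surfaces are single-bin, min-normalized to 0; compare raw corrections
        mean_corr = dv.mean() + dv.var() / (2 * t)
        from scipy.special import logsumexp

        lme_corr = t * (logsumexp(dv / t) - np.log(dv.size))
        assert abs(mean_corr - lme_corr) <= 0.05

    def test_heavy_tailed_boost_disagrees_and_is_flagged(self):
        rng = np.random.default_rng(5)
        n = 40_000
        dv = np.where(rng.random(n) < 0.5, 0.0, 4.0)  # two-point mass
        gamma = anharmonicity(dv)
        assert gamma > 0.1

    def test_all_bins_below_cutoff_is_error(self):
        with pytest.raises(ValueError):
            cumulant_reweight_pmf(_series(np.arange(10.0)), np.zeros(10),
                                  bin_sizes=1.0, cutoff=100)

    def test_negative_bin_size_rejected(self):
        with pytest.raises(ValueError):
            cumulant_reweight_pmf(_series(np.arange(100.0)), np.zeros(100),
                                  bin_sizes=-1.0)


class TestAnharmonicity:
    def test_gaussian_samples_near_zero(self):
        rng = np.random.default_rng(6)
        g = anharmonicity(rng.normal(0, 1.5, 100_000))
        assert abs(g) <= 0.02

    def test_constant_boost_zero_by_convention(self):
        assert anharmonicity(np.full(1000, 2.5)) == 0.0

    @given(st.floats(0.2, 5.0), st.integers(0, 100))
    def test_gamma_invariant_to_scale(self, scale, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 1, 5_000)
        a = anharmonicity(base)
        b = anharmonicity(scale * base)
        assert a == pytest.approx(b, abs=5e-2)


def _grid_from_values(values, edges):
    """Build a surface directly from analytic free energies (fully included)."""
    values = np.asarray(values, dtype=float)
    shape = values.shape
    big = np.full(shape, 10_000.0)
    return FESGrid([np.asarray(e) for e in edges], big, np.zeros(shape),
                   np.zeros(shape), values - values.min(),
                   np.zeros(shape, dtype=bool), 310.0, 1)


class TestBasins:
    def test_single_well_single_basin(self):
        x = np.linspace(-2, 2, 41)
        f = (x[:-1] + 0.05) ** 2
        fes = _grid_from_values(f, [x])
        basins = find_basins(fes, depth_threshold=0.5)
        assert len(basins) == 1
        assert abs(basins[0].location[0]) <= 0.2

    def test_symmetric_double_well_two_basins(self):
        x = np.linspace(-2, 2, 81)
        c = 0.5 * (x[:-1] + x[1:])
        f = (c**2 - 1.0) ** 2
        fes = _grid_from_values(f, [x])
        basins = find_basins(fes, depth_threshold=0.5)
        assert len(basins) == 2
        assert abs(basins[0].free_energy - basins[1].free_energy) <= 0.1

    def test_2d_multiwell_basins_at_quadrature_minima(self):
        from gpcrkit.potentials import make_2d_multiwell

        mw = make_2d_multiwell([(-2.0, 0.0, 3.0, 0.8), (2.0, 1.0, 2.0, 0.8)])
        edges = np.linspace(-4, 4, 33)
        f = mw.reference_pmf_2d(edges, edges, n_quad=400)
        fes = _grid_from_values(np.nan_to_num(f, nan=50.0, posinf=50.0), [edges, edges])
        basins = find_basins(fes, depth_threshold=1.0)
        bin_w = edges[1] - edges[0]
        deepest = basins[0]
        assert abs(deepest.location[0] - (-2.0)) <= bin_w
        assert abs(deepest.location[1] - 0.0) <= bin_w
        second = basins[1]
        assert abs(second.location[0] - 2.0) <= bin_w
        assert abs(second.location[1] - 1.0) <= bin_w


class TestGdpClassification:
    def test_partial_release_summary(self):
        rng = np.random.default_rng(0)
        series = np.clip(rng.uniform(0, 7.9, 500), 0, 7.9)
        series[7] = 7.9
        labels, summary = classify_gdp_state(series, (5.0, 10.0))
        assert summary["label"] == "Partially Released"
        assert summary["max_displacement"] == pytest.approx(7.9)

    def test_release_detected(self):
        series = np.array([0.0, 4.0, 11.5, 6.0])
        labels, summary = classify_gdp_state(series, (5.0, 10.0))
        assert summary["label"] == "Released"
        assert (labels == "Released").sum() == 1

    def test_all_zero_is_fully_bound(self):
        labels, summary = classify_gdp_state(np.zeros(100))
        assert summary["occupancy"]["Bound"] == 1.0

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_gdp_state(np.zeros(5), (10.0, 5.0))


class TestOnSampledTrajectories:
    def test_reweighted_double_well_matches_quadrature(self, double_well_gamd):
        model, protocol, traj = double_well_gamd
        prod = traj.combined_production()
        x = prod.coords[:, 0]
        edges = np.arange(-1.8, 1.81, 0.1)
        fes = cumulant_reweight_pmf(_series(x), prod.dv, bin_sizes=0.1,
                                    cutoff=50, edges=[edges])
        ref = model.reference_pmf(edges, 310.0)
        sel = (~fes.mask) & (ref <= 3.0)
        assert sel.sum() >= 10
        assert np.nanmax(np.abs(fes.free_energy[sel] - ref[sel])) <= 0.5

    def test_estimators_agree_where_gaussian(self):
        # controlled boost suite: per-bin Gaussian boosts of moderate width,
        # where the exponential average is itself well sampled
        rng = np.random.default_rng(12)
        n = 200_000
        x = np.concatenate([rng.normal(-1.2, 0.4, n // 2),
                            rng.normal(1.0, 0.5, n // 2)])
        mu = 2.0 + 0.8 * np.sin(x)            # bin-dependent boost mean
        sigma = 0.4 + 0.2 * np.cos(x) ** 2    # kcal/mol, ~1 kBT
        dv = mu + sigma * rng.standard_normal(x.size)
        edges = [np.arange(-2.5, 2.51, 0.25)]
        cum = cumulant_reweight_pmf(_series(x), dv, bin_sizes=0.25,
                                    cutoff=50, edges=edges)
        exp = exact_exponential_reweight(_series(x), dv, bin_sizes=0.25,
                                         cutoff=50, edges=edges)
        gamma = grid_anharmonicity(cum, _series(x), dv)
        sel = (~cum.mask) & (~exp.mask) & (np.nan_to_num(gamma, nan=1.0) <= 0.1)
        assert sel.sum() >= 10
        assert np.nanmax(np.abs(cum.free_energy[sel] - exp.free_energy[sel])) <= 0.3

    def test_boost_anharmonicity_small_on_many_dof_system(self):
        # the bead system has enough coupled terms that per-bin boosts are
        # near-Gaussian, the regime where cumulant reweighting is trusted
        from gpcrkit.gamd import GaMDProtocol, run_protocol
        from gpcrkit.potentials import ToyGProteinSpec, make_gprotein_toy

        toy = make_gprotein_toy(ToyGProteinSpec(hinge_barrier=2.0))
        protocol = GaMDProtocol(n_cmd=10_000, n_equil=20_000,
                                n_production=100_000, stats_cadence=10_000,
                                mode="dual", save_every=5)
        prod = run_protocol(toy, protocol, seed=3).combined_production()
        hinge = np.array([toy.hinge_angle(c) for c in prod.coords])
        cv = CVSeries("hinge", "deg", hinge)
        cum = cumulant_reweight_pmf(cv, prod.dv, bin_sizes=6.0, cutoff=200)
        gamma = grid_anharmonicity(cum, cv, prod.dv)
        vals = gamma[~np.isnan(gamma)]
        assert vals.size >= 5
        assert np.median(np.abs(vals)) <= 0.1

    def test_bin_refinement_within_error_bars(self, double_well_gamd):
        model, protocol, traj = double_well_gamd
        prod = traj.combined_production()
        x = prod.coords[:, 0]
        coarse_edges = np.arange(-1.6, 1.61, 0.2)
        coarse = cumulant_reweight_pmf(_series(x), prod.dv, bin_sizes=0.2,
                                       cutoff=50, edges=[coarse_edges])
        fine = cumulant_reweight_pmf(_series(x), prod.dv, bin_sizes=0.1,
                                     cutoff=25,
                                     edges=[np.arange(-1.6, 1.61, 0.1)])
        err = bootstrap_pmf_error(_series(x), prod.dv, bin_sizes=0.2,
                                  cutoff=50, edges=[coarse_edges],
                                  n_boot=50, block=200, seed=0)
        # average fine-bin pairs back onto the coarse grid
        ok = ~coarse.mask
        fine_pairs = np.nanmean(fine.free_energy.reshape(-1, 2), axis=1)
        fine_pairs -= np.nanmin(fine_pairs[ok])
        diff = np.abs(coarse.free_energy - fine_pairs)[ok]
        tol = np.maximum(3.0 * err[ok], 0.3)
        assert np.all(diff[np.isfinite(diff)] <= tol[np.isfinite(diff)])
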