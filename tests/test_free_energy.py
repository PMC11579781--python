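"""WHAM, metadynamics reconstruction, binding free energy, depth ranking."""

import numpy as np
import pytest

from sugarglass import sandbox
from sugarglass.errors import (ConsistencyError, CoverageError, GeometryError,
                               SugarglassError)
from sugarglass.free_energy import (HillsRecord, PMFProfile,
                                    UmbrellaWindowData, average_pmf,
                                    binding_free_energy, metad_fes,
                                    metad_fes_reweighted, pmf_depth_report,
                                    read_colvar, read_hills, read_pmf,
                                    wham_pmf, write_colvar, write_hills,
                                    write_pmf)
from sugarglass.synthetic import ModelPotential
from sugarglass.units import KB


class TestWham:
    def test_single_unbiased_window_is_log_histogram(self):
        """With one window at k=0 the PMF reduces to -kB T ln(histogram)."""
        rng = np.random.default_rng(0)
        samples = rng.normal(1.0, 0.1, 40_000)
        win = UmbrellaWindowData(center=1.0, k=0.0, series=samples)
        pmf = wham_pmf([win], bin_width=0.01)
        edges_lo = pmf.z - 0.005
        hist = np.histogram(samples, bins=np.append(edges_lo, pmf.z[-1] + 0.005))[0]
        direct = -KB * 298.0 * np.log(hist)
        direct -= direct[-1]
        assert np.allclose(pmf.w, direct, atol=1e-9)

    def test_double_well_recovery(self, wham_profile):
        err = sandbox.aligned_error(wham_profile, sandbox.reference_profile(),
                                    span=(0.3, 1.7))
        assert np.sqrt(np.mean(err**2)) < 0.5

    def test_harmonic_curvature_within_5pct(self):
        k_true = 80.0
        pot = ModelPotential.harmonic(k_true, 1.0)
        pmf = sandbox.umbrella_pmf(21, potential=pot)
        near = np.abs(pmf.z - 1.0) < 0.25
        coef = np.polyfit(pmf.z[near], pmf.w[near], 2)
        assert 2 * coef[0] == pytest.approx(k_true, rel=0.05)

    def test_window_order_invariance(self, umbrella_windows):
        a = wham_pmf(umbrella_windows)
        b = wham_pmf(list(reversed(umbrella_windows)))
        assert np.allclose(a.w, b.w, atol=1e-9)
        assert np.allclose(a.z, b.z)

    def test_gap_raises_coverage_error(self):
        rng = np.random.default_rng(1)
        wins = [UmbrellaWindowData(center=c, k=500.0,
                                   series=rng.normal(c, 0.02, 2000))
                for c in (0.3, 1.5)]
        with pytest.raises(CoverageError, match="overlap"):
            wham_pmf(wins)

    def test_nonconvergence_reported(self, umbrella_windows):
        from sugarglass.errors import ConvergenceError
        with pytest.raises(ConvergenceError):
            wham_pmf(umbrella_windows, max_iter=2, tolerance=1e-300)


class TestAveragePmf:
    def _profile(self, w, z=None):
        z = np.linspace(0.2, 1.8, 81) if z is None else z
        return PMFProfile(z=z, w=np.asarray(w, float))

    def test_identical_profiles_zero_sd(self):
        z = np.linspace(0.2, 1.8, 81)
        p = self._profile(np.sin(z))
        avg = average_pmf([p, p, p, p, p])
        assert np.allclose(avg.sd, 0.0)
        assert np.allclose(avg.w, avg.w)  # finite

    def test_additive_constants_removed(self):
        z = np.linspace(0.2, 1.8, 81)
        base = np.cos(z)
        shifted = [self._profile(base + c) for c in (0.0, 5.0, -3.0)]
        avg = average_pmf(shifted)
        single = average_pmf([self._profile(base)] * 2)
        assert np.allclose(avg.w, single.w, atol=1e-12)
        assert np.allclose(avg.sd, 0.0, atol=1e-12)

    def test_pointwise_mean_of_two_profiles(self):
        z = np.linspace(0.2, 1.8, 81)
        a, b = z**2, 2 * z**2
        avg = average_pmf([self._profile(a), self._profile(b)])
        tail_a = a - a[-4:].mean()
        tail_b = b - b[-4:].mean()
        assert np.allclose(avg.w, (tail_a + tail_b) / 2, atol=1e-12)

    def test_disjoint_ranges_rejected(self):
        a = self._profile(np.zeros(81))
        b = PMFProfile(z=np.linspace(3, 4, 11), w=np.zeros(11))
        with pytest.raises(ConsistencyError):
            average_pmf([a, b])


class TestMetadFes:
    def test_single_hill_closed_form(self):
        hills = HillsRecord(times=[0.0], centers=[0.5], sigmas=[0.05],
                            heights=[1.2], bias_factor=50.0)
        grid = np.linspace(0.0, 1.0, 2001)
        fes = metad_fes(hills, grid, zero="none")
        at_center = fes.w[np.argmin(np.abs(grid - 0.5))]
        assert at_center == pytest.approx(-(50.0 / 49.0) * 1.2, abs=1e-9)

    def test_empty_hills_flat(self):
        hills = HillsRecord(times=[], centers=[], sigmas=[], heights=[],
                            bias_factor=50.0)
        fes = metad_fes(hills, np.linspace(0, 1, 11))
        assert np.allclose(fes.w, 0.0)

    def test_linear_in_deposits(self):
        rng = np.random.default_rng(2)
        mk = lambda n, t0: HillsRecord(
            times=t0 + np.arange(n, dtype=float),
            centers=rng.uniform(0.2, 0.8, n), sigmas=np.full(n, 0.05),
            heights=rng.uniform(0.5, 1.2, n), bias_factor=50.0)
        a, b = mk(20, 0.0), mk(30, 100.0)
        both = HillsRecord(times=np.concatenate([a.times, b.times]),
                           centers=np.concatenate([a.centers, b.centers]),
                           sigmas=np.concatenate([a.sigmas, b.sigmas]),
                           heights=np.concatenate([a.heights, b.heights]),
                           bias_factor=50.0)
        grid = np.linspace(0, 1, 101)
        fa = metad_fes(a, grid, zero="none").w
        fb = metad_fes(b, grid, zero="none").w
        fab = metad_fes(both, grid, zero="none").w
        assert np.allclose(fab, fa + fb, atol=1e-12)

    def test_double_well_recovery_near_minima(self, metad_profile):
        err = sandbox.aligned_error(metad_profile, sandbox.reference_profile())
        grid = sandbox.FES_GRID
        near = (np.abs(grid - 0.3) <= 0.15) | (np.abs(grid - 1.7) <= 0.15)
        assert np.abs(err[near]).max() < 1.0

    def test_invalid_bias_factor(self):
        with pytest.raises(ValueError, match="bias factor"):
            HillsRecord(times=[0.0], centers=[0.5], sigmas=[0.05],
                        heights=[1.0], bias_factor=1.0)


class TestCrossMethod:
    def test_wham_and_metad_agree(self, wham_profile, metad_profile):
        """Both reconstructions of the same sandbox agree within 1 kJ/mol."""
        grid = sandbox.FES_GRID
        wa = np.interp(grid, wham_profile.z, wham_profile.w)
        d = wa - metad_profile.w
        d -= d.mean()
        assert np.abs(d).max() < 1.0


class TestBindingFreeEnergy:
    def test_flat_pmf_closed_form(self):
        z = np.linspace(0.2, 1.7, 151)
        pmf = PMFProfile(z=z, w=np.zeros_like(z))
        res = binding_free_energy(pmf, boundary=1.5, temperature=298.0)
        assert res.dg == pytest.approx(-KB * 298.0 * np.log(1.3 / 0.2),
                                       abs=1e-10)

    def test_shift_invariance(self):
        z = np.linspace(0.2, 1.7, 151)
        w = 3.0 * np.sin(z)
        a = binding_free_energy(PMFProfile(z=z, w=w), 1.5)
        b = binding_free_energy(PMFProfile(z=z, w=w + 100.0), 1.5)
        assert a.dg == pytest.approx(b.dg, abs=1e-9)

    def test_square_well_hand_quadrature(self):
        z = np.linspace(0.2, 1.7, 1501)
        w = np.where(z <= 1.5, -20.0, 0.0)
        res = binding_free_energy(PMFProfile(z=z, w=w), 1.5, 298.0)
        beta = 1.0 / (KB * 298.0)
        # trapezoid of the step integrand, boundary bin split linearly
        int_b = np.trapezoid(np.exp(-beta * w[z <= 1.5]), z[z <= 1.5])
        int_u = np.trapezoid(np.exp(-beta * w[z >= 1.5]), z[z >= 1.5])
        assert res.dg == pytest.approx(-np.log(int_b / int_u) / beta, abs=1e-6)

    def test_grid_refinement_stable(self):
        for n in (151, 301):
            z = np.linspace(0.2, 1.7, n)
            w = 5.0 * (z - 1.0) ** 2
            res = binding_free_energy(PMFProfile(z=z, w=w), 1.5)
            if n == 151:
                coarse = res.dg
        assert abs(res.dg - coarse) < 0.01

    def test_boundary_outside_grid(self):
        z = np.linspace(0.2, 1.0, 81)
        with pytest.raises(GeometryError):
            binding_free_energy(PMFProfile(z=z, w=np.zeros_like(z)), 1.5)

    def test_volume_correction_changes_result(self):
        z = np.linspace(0.2, 1.7, 151)
        pmf = PMFProfile(z=z, w=np.zeros_like(z))
        plain = binding_free_energy(pmf, 1.5).dg
        vol = binding_free_energy(pmf, 1.5, volume_correction=True).dg
        assert plain != pytest.approx(vol)


class TestDepthReport:
    def test_ordering_and_sum(self):
        z = np.linspace(0.2, 2.0, 181)

        def well(depth, z0=0.5):
            w = depth * np.exp(-((z - z0) / 0.1) ** 2)
            return PMFProfile(z=z, w=w)

        profiles = {"a": well(-1.0), "b": well(-5.0), "c": well(-3.0)}
        rep = pmf_depth_report(profiles)
        assert rep.order == ["b", "c", "a"]
        assert rep.depth_sum == pytest.approx(-9.0, abs=0.05)
        assert not rep.excluded

    def test_monotone_profile_excluded(self):
        z = np.linspace(0.2, 2.0, 181)
        profiles = {"mono": PMFProfile(z=z, w=z * 2.0),
                    "well": PMFProfile(z=z, w=-np.exp(-((z - 0.5) / 0.1) ** 2))}
        rep = pmf_depth_report(profiles)
        assert rep.excluded == ["mono"]
        assert rep.order == ["well"]

    def test_first_minimum_matches_calculus_oracle(self):
        pot = ModelPotential.double_well(10.0, (0.4, 1.4))
        z = np.linspace(0.2, 1.8, 1601)
        rep = pmf_depth_report({"dw": PMFProfile(z=z, w=pot.energy(z))})
        # derivative root: the first minimum of the quartic is at z1 = 0.4
        assert rep.minima_positions["dw"] == pytest.approx(0.4, abs=1e-3)


class TestTextIO:
    def test_hills_roundtrip(self, tmp_path, metad_run):
        path = tmp_path / "HILLS"
        write_hills(metad_run.hills, path)
        back = read_hills(path)
        assert back.n_hills == metad_run.hills.n_hills
        assert np.allclose(back.centers, metad_run.hills.centers, atol=1e-8)
        assert np.allclose(back.heights, metad_run.hills.heights, atol=1e-8)
        assert back.bias_factor == pytest.approx(50.0)

    def test_hills_nominal_height_flag(self, tmp_path):
        path = tmp_path / "HILLS"
        hills = HillsRecord(times=[0.0], centers=[0.5], sigmas=[0.05],
                            heights=[1.2], bias_factor=50.0)
        write_hills(hills, path)
        with pytest.warns(UserWarning, match="nominal"):
            back = read_hills(path, heights_prescaled=False)
        assert back.heights[0] == pytest.approx(1.2 * 49.0 / 50.0)

    def test_colvar_roundtrip(self, tmp_path):
        t = np.arange(5.0)
        v = np.sin(t)
        path = tmp_path / "COLVAR"
        write_colvar(t, v, path)
        tb, vb = read_colvar(path)
        assert np.allclose(tb, t) and np.allclose(vb, v, atol=1e-9)

    def test_pmf_roundtrip(self, tmp_path, wham_profile):
        path = tmp_path / "pmf.xvg"
        write_pmf(wham_profile, path)
        back = read_pmf(path)
        assert np.allclose(back.z, wham_profile.z, atol=1e-6)
        assert np.allclose(back.w, wham_profile.w, atol=1e-7)
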