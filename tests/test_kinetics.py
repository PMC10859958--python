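"""Kinetic simulator: IRF convolution, compartmental schemes, surfaces."""

import numpy as np
import pytest
from scipy.linalg import expm

from chromakin import (DASet, IRFModel, KineticScheme, concentrations,
                       conv_exp_gauss, make_fixture,
                       read_surface, simulate_compartmental,
                       simulate_das_surface, write_surface)
from chromakin.fixtures import FIXTURE_NAMES


def numeric_conv(t, tau, fwhm, t0=0.0, ds=1e-4):
    """Simpson-rule convolution oracle on a uniform grid ending exactly at t."""
    from scipy.integrate import simpson
    sig = fwhm / 2.3548200450309493
    out = np.empty_like(np.atleast_1d(t), dtype=float)
    for i, ti in enumerate(np.atleast_1d(t)):
        start = min(t0 - 8 * sig, ti - ds)
        s = np.linspace(start, ti, max(int(np.ceil((ti - start) / ds)), 2) + 1)
        g = np.exp(-0.5 * ((s - t0) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
        out[i] = simpson(g * np.exp(-(ti - s) / tau), x=s)
    return out


class TestConvExpGauss:
    def test_matches_numeric_convolution(self):
        t = np.linspace(-1.0, 5.0, 61)
        ana = conv_exp_gauss(t, tau=1.0, t0=0.0, fwhm=0.1)
        num = numeric_conv(t, 1.0, 0.1)
        assert np.abs(ana - num).max() < 1e-7

    def test_delta_irf_limit(self):
        t = np.linspace(0.1, 5.0, 50)
        ana = conv_exp_gauss(t, tau=1.0, t0=0.0, fwhm=1e-6)
        np.testing.assert_allclose(ana, np.exp(-t), rtol=1e-6)

    def test_causality_far_before_time_zero(self):
        assert conv_exp_gauss(-50.0, tau=1.0, t0=0.0, fwhm=0.1) == 0.0

    def test_overflow_safe_for_extreme_arguments(self):
        # fast decay, wide IRF, late times: naive erfc form overflows
        vals = conv_exp_gauss(np.array([-1e4, 0.0, 1e4]), tau=1e-3, fwhm=100.0)
        assert np.all(np.isfinite(vals))

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            conv_exp_gauss(0.0, tau=-1.0)
        with pytest.raises(ValueError):
            conv_exp_gauss(0.0, tau=1.0, fwhm=0.0)


class TestConcentrations:
    def test_single_compartment_delta_irf(self):
        sch = KineticScheme.sequential([0.5])
        t = np.linspace(0, 10, 30)
        c = concentrations(sch, None, t)
        np.testing.assert_allclose(c[0], np.exp(-0.5 * t), rtol=1e-12)

    def test_bateman_closed_form_two_compartments(self):
        k1, k2 = 2.0, 1.0
        sch = KineticScheme.sequential([k1, k2])
        t = np.linspace(0, 6, 61)
        c = concentrations(sch, None, t)
        expected = k1 / (k1 - k2) * (np.exp(-k2 * t) - np.exp(-k1 * t))
        np.testing.assert_allclose(c[1], expected, atol=1e-12)

    def test_matches_matrix_exponential_on_random_times(self, rng):
        K = np.array([[-3.0, 0.0, 0.0], [2.5, -1.0, 0.0], [0.0, 0.8, -0.3]])
        sch = KineticScheme(K)
        times = np.sort(rng.uniform(0.0, 12.0, 500))
        c = concentrations(sch, None, times)
        oracle = np.stack([expm(K * ti) @ sch.input_vector for ti in times], axis=1)
        assert np.abs(c - oracle).max() < 1e-8

    def test_loss_free_scheme_conserves_population(self):
        # terminal rate zero: the chain ends in a sink compartment
        sch = KineticScheme.sequential([2.0, 0.5, 0.0])
        irf = IRFModel.gaussian(fwhm=0.1, t0=0.0)
        t = np.linspace(5.0, 50.0, 10)   # well after the IRF has passed
        total = concentrations(sch, irf, t).sum(axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_defective_matrix_falls_back_to_ode(self):
        # repeated rates make the sequential chain non-diagonalizable
        K = np.array([[-1.0, 0.0], [1.0, -1.0]])
        sch = KineticScheme(K)
        t = np.linspace(0, 5, 40)
        with pytest.warns(UserWarning, match="defective"):
            c = concentrations(sch, None, t)
        np.testing.assert_allclose(c[1], t * np.exp(-t), atol=1e-7)

    def test_rate_matrix_validation(self):
        with pytest.raises(ValueError):
            KineticScheme(np.array([[-1.0, 0.5], [-0.2, -1.0]]))  # negative transfer
        with pytest.raises(ValueError):
            KineticScheme(np.array([[1.0]]))  # creates population


class TestSimulateDasSurface:
    def test_zero_das_gives_zero_surface(self):
        wl = np.linspace(670, 780, 12)
        das = DASet([100.0, 1000.0], np.zeros((2, 12)), wl)
        surf = simulate_das_surface(das, None, np.linspace(0, 5000, 100))
        assert np.all(surf.signal == 0.0)

    def test_delta_irf_reduces_to_plain_exponential(self):
        wl = np.linspace(670, 700, 4)
        spec = np.array([[1.0, 0.5, 0.2, 0.1]])
        das = DASet([500.0], spec, wl)
        t = np.linspace(0, 3000, 61)
        surf = simulate_das_surface(das, IRFModel.delta(), t)
        expected = np.exp(-t / 500.0)[:, None] * spec
        np.testing.assert_allclose(surf.signal, expected, rtol=1e-12)

    def test_gaussian_irf_matches_analytic_convolution_column(self):
        # one lifetime, 92 ps Gaussian IRF: surface column equals the
        # stable analytic convolution evaluated directly
        wl = np.linspace(670, 690, 3)
        das = DASet([1000.0], np.ones((1, 3)), wl)
        t = np.linspace(-300, 5000, 200)
        irf = IRFModel.gaussian(fwhm=92.0)
        surf = simulate_das_surface(das, irf, t)
        np.testing.assert_allclose(surf.signal[:, 0],
                                   conv_exp_gauss(t, 1000.0, 0.0, 92.0),
                                   rtol=1e-12)

    def test_poisson_noise_mean_calibrated(self):
        wl = np.linspace(670, 680, 2)
        das = DASet([1000.0], np.ones((1, 2)), wl)
        t = np.array([0.0, 500.0, 1000.0])
        means = []
        for seed in range(1000):
            surf = simulate_das_surface(das, IRFModel.delta(), t, wl,
                                        noise={"kind": "poisson", "peak_counts": 100},
                                        seed=seed)
            means.append(surf.signal[0, 0])
        assert 97.0 <= np.mean(means) <= 103.0

    def test_deterministic_under_fixed_seed(self):
        b1 = make_fixture("lhca4_ab_tcspc", seed=11)
        b2 = make_fixture("lhca4_ab_tcspc", seed=11)
        np.testing.assert_array_equal(b1.surface.signal, b2.surface.signal)

    def test_negative_counts_model_rejected(self):
        wl = np.linspace(670, 680, 3)
        das = DASet([1000.0], -np.ones((1, 3)), wl)
        with pytest.raises(ValueError, match="negative"):
            simulate_das_surface(das, None, np.linspace(0, 100, 10), wl,
                                 noise={"kind": "poisson", "peak_counts": 100},
                                 seed=0, modality="tcspc_counts")


class TestSimulateCompartmental:
    def test_zero_sads_gives_zero_surface(self):
        sch = KineticScheme.sequential([1.0, 0.1])
        wl = np.linspace(630, 760, 10)
        surf = simulate_compartmental(sch, np.zeros((2, 10)), None,
                                      np.linspace(0, 50, 20), wl)
        assert np.all(surf.signal == 0.0)

    def test_mixture_linearity(self, rng):
        wl = np.linspace(630, 760, 14)
        t = np.linspace(-1, 80, 60)
        irf = IRFModel.gaussian(0.1)
        s1 = KineticScheme.sequential([2.0, 0.05])
        s2 = KineticScheme.sequential([1.0, 0.5, 0.01])
        sads1 = rng.normal(size=(2, 14))
        sads2 = rng.normal(size=(3, 14))
        f = 0.3
        a = simulate_compartmental(s1, sads1, irf, t, wl).signal
        b = simulate_compartmental(s2, sads2, irf, t, wl).signal
        # one block-diagonal scheme with the input split f / (1-f) across the
        # two branch heads equals the weighted sum of separate simulations
        K = np.zeros((5, 5))
        K[:2, :2] = s1.rate_matrix
        K[2:, 2:] = s2.rate_matrix
        combined = KineticScheme(K, input_vector=np.array([f, 0, 1 - f, 0, 0]))
        sads = np.vstack([sads1, sads2])
        mixed = simulate_compartmental(combined, sads, irf, t, wl).signal
        np.testing.assert_allclose(mixed, f * a + (1 - f) * b, atol=1e-10)

    def test_four_compartment_chain_matches_ode_oracle(self):
        from scipy.integrate import solve_ivp
        rates = np.array([1 / 0.6, 1 / 4.0, 1 / 15.0, 1 / 800.0])
        sch = KineticScheme.sequential(rates)
        irf = IRFModel.gaussian(fwhm=0.1, t0=0.0)
        t = np.geomspace(0.05, 100.0, 50)
        c = concentrations(sch, irf, t)
        sig = 0.1 / 2.3548200450309493
        K = sch.rate_matrix

        def rhs(tt, y):
            pulse = np.exp(-0.5 * ((tt - 0.0) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
            return K @ y + pulse * sch.input_vector

        sol = solve_ivp(rhs, (-6 * sig, 100.0), np.zeros(4), t_eval=t,
                        rtol=1e-11, atol=1e-13, method="LSODA")
        assert np.abs(c - sol.y).max() < 1e-6 * c.max()


class TestFixturesAndIO:
    def test_tcspc_truth_mirrors_study_lifetimes_and_areas(self):
        b = make_fixture("lhca4_ab_tcspc", seed=0)
        np.testing.assert_allclose(b.truth["lifetimes_ns"],
                                   [0.012, 0.19, 0.87, 2.1, 3.8])
        assert b.truth["main_das_area_ratio"] == (0.48, 0.34, 0.18)
        areas = [np.trapezoid(b.truth["das"].spectra[i],
                              b.truth["das"].wavelengths_nm) for i in (1, 2, 3)]
        np.testing.assert_allclose(areas, [0.48, 0.34, 0.18], rtol=1e-9)
        assert b.truth["irf"].sampled_fwhm() == pytest.approx(92.0, abs=2.0)

    def test_mixture_fixture_default_fraction(self):
        b = make_fixture("lhca4_abf_ta_mixture", seed=0)
        assert b.truth["fraction_f"] == 0.67

    def test_unknown_fixture_name_raises(self):
        with pytest.raises(KeyError):
            make_fixture("lhca5_xyz")

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_all_fixtures_build(self, name):
        b = make_fixture(name, seed=1)
        assert b.surface.signal.size > 0

    def test_surface_round_trip_is_bit_exact(self, tmp_path):
        b = make_fixture("lhca4_ab_ta", seed=2)
        path = tmp_path / "surface.tsv"
        write_surface(path, b.surface)
        back = read_surface(path)
        np.testing.assert_array_equal(back.times, b.surface.times)
        np.testing.assert_array_equal(back.wavelengths_nm, b.surface.wavelengths_nm)
        np.testing.assert_array_equal(back.signal, b.surface.signal)
        assert back.modality == b.surface.modality
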