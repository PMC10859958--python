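"""Two-branch target analysis: constrained SADS solve and fraction fitting."""

import numpy as np
import pytest

from chromakin import (IRFModel, KineticScheme, TargetAnalysis, branch_signal,
                       concentrations, constrained_sads_solve, fit_target,
                       make_fixture, sads_area, simulate_compartmental)
from chromakin.targetfit import TwoBranchModel, _trapezoid_weights

RATE_INIT = 1.0 / np.array([1.0, 5.0, 25.0, 300.0])


def mixture_fit(bundle, **kw):
    kw.setdefault("rate_init", RATE_INIT)
    kw.setdefault("n_starts", 1)
    est = TargetAnalysis(fixed_scheme=bundle.truth["fixed_scheme"],
                         fixed_sads=bundle.truth["fixed_sads"],
                         n_free=4, irf=bundle.truth["irf"],
                         window_ps=(None, 100.0), seed=0, **kw)
    return est.fit(bundle.surface)


class TestConstrainedSadsSolve:
    def test_unconstrained_optimum_kept_when_feasible(self, rng):
        C = np.abs(rng.normal(1.0, 0.4, (40, 3)))
        S_true = rng.normal(size=(3, 20))
        data = C @ S_true
        wl = np.linspace(630, 760, 20)
        target = sads_area(S_true[0], wl, "abs")
        S = constrained_sads_solve(data, None, None, C, target, wavelengths_nm=wl)
        np.testing.assert_allclose(S, S_true, atol=1e-8)

    def test_zero_target_forces_zero_first_area(self, rng):
        C = np.abs(rng.normal(1.0, 0.4, (40, 3)))
        data = C @ rng.normal(size=(3, 15)) + rng.normal(0, 0.05, (40, 15))
        wl = np.linspace(630, 760, 15)
        S = constrained_sads_solve(data, None, None, C, 1e-12, wavelengths_nm=wl)
        assert sads_area(S[0], wl, "abs") == pytest.approx(1e-12, abs=1e-10)

    def test_signed_mode_matches_dense_penalty_oracle(self, rng):
        nt, nl, nc = 30, 12, 3
        C = np.abs(rng.normal(1.0, 0.5, (nt, nc)))
        data = C @ rng.normal(size=(nc, nl)) + rng.normal(0, 0.02, (nt, nl))
        wl = np.linspace(630, 760, nl)
        target = 3.0
        S = constrained_sads_solve(data, None, None, C, target,
                                   wavelengths_nm=wl, area_mode="signed")
        dl = _trapezoid_weights(wl)
        pen = 1e12
        rows = []
        rhs = []
        for l in range(nl):
            block = np.zeros((nt, nc * nl))
            block[:, l * nc:(l + 1) * nc] = C
            rows.append(block)
            rhs.append(data[:, l])
        crow = np.zeros(nc * nl)
        for l in range(nl):
            crow[l * nc] = dl[l]
        rows.append(np.sqrt(pen) * crow[None, :])
        rhs.append([np.sqrt(pen) * target])
        A = np.vstack(rows)
        b = np.concatenate([np.ravel(r) for r in rhs])
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        S_pen = sol.reshape(nl, nc).T
        assert np.abs(S - S_pen).max() < 1e-6

    def test_abs_mode_matches_slsqp_oracle(self, rng):
        from scipy.optimize import minimize
        nt, nl, nc = 25, 6, 2
        C = np.abs(rng.normal(1.0, 0.5, (nt, nc)))
        data = C @ rng.normal(size=(nc, nl)) + rng.normal(0, 0.05, (nt, nl))
        wl = np.linspace(630, 760, nl)
        dl = _trapezoid_weights(wl)
        target = 2.5
        S = constrained_sads_solve(data, None, None, C, target,
                                   wavelengths_nm=wl, area_mode="abs")
        assert sads_area(S[0], wl, "abs") == pytest.approx(target, rel=1e-12)

        def cost(x):
            return np.sum((data - C @ x.reshape(nc, nl)) ** 2)

        cons = {"type": "eq",
                "fun": lambda x: dl @ np.abs(x.reshape(nc, nl)[0]) - target}
        oracle = minimize(cost, S.ravel() + rng.normal(0, 0.01, nc * nl),
                          constraints=[cons], method="SLSQP",
                          options={"maxiter": 500, "ftol": 1e-14})
        assert cost(S.ravel()) <= oracle.fun * (1 + 1e-8)

    def test_fixed_branch_subtraction(self, rng):
        C_fix = np.abs(rng.normal(1.0, 0.3, (30, 2)))
        S_fix = rng.normal(size=(2, 10))
        C_free = np.abs(rng.normal(1.0, 0.3, (30, 2)))
        S_free = rng.normal(size=(2, 10))
        wl = np.linspace(630, 760, 10)
        data = C_fix @ S_fix + C_free @ S_free
        target = sads_area(S_free[0], wl, "abs")
        S = constrained_sads_solve(data, C_fix, S_fix, C_free, target,
                                   wavelengths_nm=wl)
        np.testing.assert_allclose(S, S_free, atol=1e-8)

    def test_rank_deficient_free_matrix_raises(self, rng):
        C = np.ones((30, 2))
        with pytest.raises(np.linalg.LinAlgError):
            constrained_sads_solve(rng.normal(size=(30, 5)), None, None, C, 1.0)


class TestBranchSignal:
    def test_zero_scale_gives_zero(self):
        sch = KineticScheme.sequential([1.0, 0.1])
        out = branch_signal(sch, np.ones((2, 5)), None, np.linspace(0, 10, 20),
                            scale=0.0)
        assert np.all(out == 0.0)

    def test_scale_additivity(self, rng):
        sch = KineticScheme.sequential([1.0, 0.1])
        sads = rng.normal(size=(2, 6))
        t = np.linspace(0, 10, 20)
        a = branch_signal(sch, sads, None, t, scale=0.3)
        b = branch_signal(sch, sads, None, t, scale=0.7)
        np.testing.assert_allclose(a + b, branch_signal(sch, sads, None, t, 1.0),
                                   rtol=1e-12)

    def test_matches_simulator_bit_for_bit(self, rng):
        sch = KineticScheme.sequential([2.0, 0.2, 0.01])
        sads = rng.normal(size=(3, 8))
        irf = IRFModel.gaussian(0.1)
        t = np.geomspace(0.05, 80.0, 40)
        wl = np.linspace(630, 760, 8)
        sim = simulate_compartmental(sch, sads, irf, t, wl).signal
        np.testing.assert_array_equal(branch_signal(sch, sads, irf, t), sim)


class TestTargetFit:
    def test_pure_fixed_population_drives_f_to_zero(self):
        b = make_fixture("lhca4_abf_ta_mixture", seed=1, fraction_f=0.0,
                         noise_frac=0.0)
        with pytest.warns(UserWarning, match="bound"):
            est = mixture_fit(b)
        assert est.fraction_f_ < 0.02

    def test_pure_free_population_drives_f_to_one(self):
        b = make_fixture("lhca4_abf_ta_mixture", seed=1, fraction_f=1.0,
                         noise_frac=0.0)
        with pytest.warns(UserWarning, match="bound"):
            est = mixture_fit(b)
        assert est.fraction_f_ > 0.98

    @pytest.mark.parametrize("f_true", [0.2, 0.5, 0.8])
    def test_noiseless_mixture_identified_exactly(self, f_true):
        b = make_fixture("lhca4_abf_ta_mixture", seed=0, fraction_f=f_true,
                         noise_frac=0.0)
        est = mixture_fit(b)
        assert est.fraction_f_ == pytest.approx(f_true, abs=1e-3)
        assert est.area_check_ < 1e-6

    def test_study_conditions_fraction_recovered(self):
        b = make_fixture("lhca4_abf_ta_mixture", seed=5)
        est = mixture_fit(b, n_starts=2)
        assert est.fraction_f_ == pytest.approx(0.67, abs=0.05)
        np.testing.assert_allclose(np.sort(est.free_lifetimes_),
                                   np.sort(b.truth["free_lifetimes_ps"]), rtol=0.15)

    def test_fraction_invariant_under_joint_rescaling(self):
        b = make_fixture("lhca4_abf_ta_mixture", seed=2)
        est = mixture_fit(b)
        scaled = type(b.surface)(b.surface.times, b.surface.wavelengths_nm,
                                 b.surface.signal * 3.7, b.surface.modality)
        est2 = TargetAnalysis(fixed_scheme=b.truth["fixed_scheme"],
                              fixed_sads=b.truth["fixed_sads"] * 3.7,
                              n_free=4, irf=b.truth["irf"],
                              window_ps=(None, 100.0), rate_init=RATE_INIT,
                              n_starts=1, seed=0).fit(scaled)
        assert est2.fraction_f_ == pytest.approx(est.fraction_f_, abs=1e-6)

    def test_two_branch_cost_never_exceeds_fixed_branch_alone(self):
        b = make_fixture("lhca4_abf_ta_mixture", seed=4)
        est = mixture_fit(b)
        surf = b.surface.window(None, 100.0)
        C_fix = concentrations(b.truth["fixed_scheme"], b.truth["irf"],
                               surf.times).T
        fixed_only = 0.5 * np.sum((surf.signal - C_fix @ b.truth["fixed_sads"]) ** 2)
        assert est.cost_ <= fixed_only

    def test_window_and_extra_compartment_stability(self):
        # a 5th free compartment on the same <=100 ps window leaves the
        # fraction essentially unchanged
        b = make_fixture("lhca4_abf_ta_mixture", seed=6)
        est4 = mixture_fit(b)
        est5 = TargetAnalysis(fixed_scheme=b.truth["fixed_scheme"],
                              fixed_sads=b.truth["fixed_sads"],
                              n_free=5, irf=b.truth["irf"],
                              window_ps=(None, 100.0),
                              rate_init=1.0 / np.array([0.8, 4.0, 20.0, 200.0, 800.0]),
                              n_starts=1, seed=0).fit(b.surface)
        assert est5.fraction_f_ == pytest.approx(est4.fraction_f_, abs=0.03)

    def test_zero_area_fixed_first_sads_is_infeasible(self):
        b = make_fixture("lhca4_abf_ta_mixture", seed=0)
        sads = b.truth["fixed_sads"].copy()
        sads[0] = 0.0
        with pytest.raises(ValueError, match="constraint"):
            fit_target(b.surface, b.truth["fixed_scheme"], sads,
                       irf=b.truth["irf"], rate_init=RATE_INIT)

    def test_two_branch_model_validation(self):
        sch = KineticScheme.sequential([1.0, 0.1])
        with pytest.raises(ValueError):
            TwoBranchModel(sch, np.ones((3, 5)))
        with pytest.raises(ValueError):
            TwoBranchModel(sch, np.ones((2, 5)), fraction_f=1.5)
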