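"""Global analysis: variable-projection fitting of time-resolved surfaces.

The model is a sum of IRF-convolved exponentials,
psi(t, lambda) = sum_i DAS_i(lambda) [exp(-t/tau_i) (x) IRF](t).
Lifetimes (and optionally the Gaussian IRF parameters) are the nonlinear
parameters; the spectra are eliminated at every step by conditionally
linear least squares (variable projection).  Lifetimes are optimized in
log space and reported ascending; the DAS sign is data-determined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .irf import IRFModel, conv_exp_gauss, convolved_decays
from .kinetics import DASet, TimeResolvedSurface

__all__ = [
    "GlobalAnalysis",
    "GlobalFitResult",
    "EADSet",
    "conv_exp_gauss",
    "fit_global",
    "variable_projection_amplitudes",
    "das_to_eads",
    "eads_to_das",
    "select_n_components",
]


@dataclass
class EADSet:
    """Evolution-associated spectra of the equivalent sequential scheme."""

    rates: np.ndarray        # strictly descending (ps^-1)
    spectra: np.ndarray      # one row per compartment
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if np.any(np.diff(self.rates) >= 0):
            raise ValueError("rates must be strictly descending")
        if self.spectra.shape[0] != self.rates.size:
            raise ValueError("one spectrum per rate required")


@dataclass
class GlobalFitResult:
    das: DASet
    irf_fit: IRFModel
    residual_matrix: np.ndarray
    cost: float
    n_iterations: int
    degenerate: bool = False
    success: bool = True
    message: str = ""


def variable_projection_amplitudes(data, concentration_matrix, weights=None):
    """Per-wavelength (weighted) least-squares amplitudes.

    Parameters
    ----------
    data : (n_times, n_wavelengths) array
    concentration_matrix : (n_times, n_components) array
    weights : optional (n_times, n_wavelengths) array of residual weights

    Returns the (n_components, n_wavelengths) amplitude matrix; the weighted
    residual is orthogonal to the weighted column space.
    """
    data = np.asarray(data, dtype=float)
    C = np.asarray(concentration_matrix, dtype=float)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise np.linalg.LinAlgError("concentration matrix is rank deficient")
    if weights is None:
        A, *_ = np.linalg.lstsq(C, data, rcond=None)
        return A
    W = np.asarray(weights, dtype=float)
    n_l = data.shape[1]
    A = np.empty((C.shape[1], n_l))
    for j in range(n_l):
        Cw = C * W[:, j, None]
        A[:, j], *_ = np.linalg.lstsq(Cw, data[:, j] * W[:, j], rcond=None)
    return A


def _default_weights(surface: TimeResolvedSurface):
    """Poisson weights for TCSPC counts, uniform (None) for TA."""
    if surface.modality == "tcspc_counts":
        return 1.0 / np.sqrt(np.clip(surface.signal, 1.0, None))
    return None


class GlobalAnalysis(BaseEstimator):
    """Variable-projection global fit of a time-resolved surface.

    Parameters
    ----------
    n_components : int
        Number of exponential components.
    irf : IRFModel or "fit-gaussian"
        Known IRF, or fit a Gaussian IRF (t0 and fwhm free).
    tau_init : sequence of float
        Initial lifetimes (ps).  Required.
    weights : "auto", None or array
        "auto" uses 1/sqrt(max(counts, 1)) for TCSPC and uniform for TA.
    fwhm_bounds : (float, float)
        Bounds (ps) for the fitted Gaussian fwhm (default 87-125 fs).
    max_iter : int
    tol : float
        Relative cost-change tolerance.

    Attributes (after fit)
    ----------------------
    lifetimes_ : ascending lifetimes (ps); das_ : DASet; irf_ : IRFModel;
    residual_matrix_, cost_, n_iter_, degenerate_, result_.
    """

    def __init__(self, n_components=1, irf="fit-gaussian", tau_init=None,
                 weights="auto", fwhm_bounds=(0.087, 0.125), t0_init=0.0,
                 max_iter=500, tol=1e-10):
        self.n_components = n_components
        self.irf = irf
        self.tau_init = tau_init
        self.weights = weights
        self.fwhm_bounds = fwhm_bounds
        self.t0_init = t0_init
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ---------------------------------------------------------
    def _unpack(self, theta):
        n = self.n_components
        taus = np.exp(theta[:n])
        if self.irf == "fit-gaussian":
            irf = IRFModel.gaussian(fwhm=np.exp(theta[n + 1]), t0=theta[n])
        else:
            irf = self.irf
        return taus, irf

    def fit(self, surface: TimeResolvedSurface):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tau_init is None:
            raise ValueError("tau_init is required")
        tau0 = np.sort(np.asarray(self.tau_init, dtype=float))
        if tau0.size != self.n_components or np.any(tau0 <= 0):
            raise ValueError("tau_init must give n_components positive lifetimes")

        data = surface.signal
        W = _default_weights(surface) if self.weights == "auto" else self.weights

        theta0 = list(np.log(tau0))
        lo = [-np.inf] * self.n_components
        hi = [np.inf] * self.n_components
        if self.irf == "fit-gaussian":
            f_lo, f_hi = self.fwhm_bounds
            theta0 += [self.t0_init, np.log(np.sqrt(f_lo * f_hi))]
            span = surface.times[-1] - surface.times[0]
            lo += [surface.times[0] - span, np.log(f_lo)]
            hi += [surface.times[-1] + span, np.log(f_hi)]

        def residual(theta):
            taus, irf = self._unpack(theta)
            C = convolved_decays(surface.times, 1.0 / taus, irf)
            A = variable_projection_amplitudes(data, C, W)
            r = data - C @ A
            if W is not None:
                r = r * W
            return r.ravel()

        sol = least_squares(residual, np.asarray(theta0), bounds=(lo, hi),
                            method="trf", max_nfev=self.max_iter * (len(theta0) + 1),
                            ftol=self.tol, xtol=1e-12, gtol=1e-12)
        taus, irf = self._unpack(sol.x)
        order = np.argsort(taus)
        taus = taus[order]
        C = convolved_decays(surface.times, 1.0 / taus, irf)
        A = variable_projection_amplitudes(data, C, W)
        resid = data - C @ A

        degenerate = bool(np.any(np.diff(taus) / taus[:-1] < 0.01))
        if degenerate:
            warnings.warn("two lifetimes within 1% of each other: degenerate fit",
                          stacklevel=2)
        if not sol.success:
            raise RuntimeError(f"global fit did not converge: {sol.message}")

        self.lifetimes_ = taus
        self.das_ = DASet(taus, A, surface.wavelengths_nm)
        self.irf_ = irf
        self.residual_matrix_ = resid
        self.cost_ = float(sol.cost)
        self.n_iter_ = int(sol.nfev)
        self.degenerate_ = degenerate
        self.weights_ = W
        self.result_ = GlobalFitResult(self.das_, irf, resid, self.cost_,
                                       self.n_iter_, degenerate, sol.success,
                                       sol.message)
        return self


def fit_global(surface, n_components, irf="fit-gaussian", tau_init=None,
               weights="auto", **kw) -> GlobalFitResult:
    """Functional wrapper around :class:`GlobalAnalysis`."""
    est = GlobalAnalysis(n_components=n_components, irf=irf, tau_init=tau_init,
                         weights=weights, **kw)
    return est.fit(surface).result_


# -- DAS <-> EADS ----------------------------------------------------------

def _bateman_matrix(rates: np.ndarray) -> np.ndarray:
    """Amplitudes of the unidirectional chain with unit input.

    Row j gives c_j(t) = sum_i A[j, i] exp(-k_i t) for descending rates k.
    """
    k = np.asarray(rates, dtype=float)
    n = k.size
    if np.any(np.abs(k[:, None] - k[None, :])[~np.eye(n, dtype=bool)] < 1e-9 * k.max()):
        raise ValueError("repeated rates: sequential scheme is degenerate")
    A = np.zeros((n, n))
    for j in range(n):
        flux = np.prod(k[:j])
        for i in range(j + 1):
            denom = np.prod([k[l] - k[i] for l in range(j + 1) if l != i])
            A[j, i] = flux / denom
    return A


def das_to_eads(das: DASet) -> EADSet:
    """Spectra of the unidirectional sequential scheme whose parallel-
    equivalent DAS equal the input (rates 1/tau, descending)."""
    rates = 1.0 / das.lifetimes            # descending, since lifetimes ascend
    A = _bateman_matrix(rates)
    # DAS = A^T @ EADS  (both indexed by descending rate)
    eads = solve_triangular(A.T, das.spectra, lower=False)
    return EADSet(rates, eads, das.wavelengths_nm)


def eads_to_das(eads: EADSet) -> DASet:
    """Inverse of :func:`das_to_eads`."""
    A = _bateman_matrix(eads.rates)
    das = A.T @ eads.spectra
    lifetimes = 1.0 / eads.rates           # ascending
    return DASet(lifetimes, das, eads.wavelengths_nm)


# -- model-order diagnostics ----------------------------------------------

def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[:-1] @ x[1:]) / denom


def select_n_components(surface, n_min, n_max, irf="fit-gaussian",
                        tau_init=None, improvement=0.02,
                        autocorr_threshold=0.5, **fit_kw):
    """Scan component counts and recommend the smallest adequate model.

    Fits every n in [n_min, n_max], reports the cost, the leading singular
    values of each residual matrix and a "shapeless" flag per DAS (lag-1
    autocorrelation below threshold, i.e. noise-like spectrum); recommends
    the smallest n beyond which the relative cost improvement drops below
    ``improvement``.
    """
    if n_min > n_max:
        raise ValueError("n_min must be <= n_max")
    t = surface.times
    t_pos = t[t > 0]
    costs, fits, shapeless, res_sv = {}, {}, {}, {}
    for n in range(n_min, n_max + 1):
        if tau_init is None:
            ti = np.geomspace(max(np.median(np.diff(t)), t_pos[0]),
                              (t[-1] - t[0]) / 3.0, n)
        else:
            ti = np.asarray(tau_init, dtype=float)[:n]
            if ti.size < n:
                ti = np.geomspace(ti.min(), (t[-1] - t[0]) / 3.0, n)
        try:
            res = fit_global(surface, n, irf=irf, tau_init=ti, **fit_kw)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"n={n} fit failed: {exc}", stacklevel=2)
            continue
        costs[n] = res.cost
        fits[n] = res
        shapeless[n] = [_lag1_autocorr(row) < autocorr_threshold
                        for row in res.das.spectra]
        res_sv[n] = np.linalg.svd(res.residual_matrix, compute_uv=False)[:5]
    ns = sorted(costs)
    recommended = ns[-1]
    for a, b in zip(ns, ns[1:]):
        if costs[a] <= 0 or (costs[a] - costs[b]) / costs[a] < improvement:
            recommended = a
            break
    return {"recommended": recommended, "costs": costs, "fits": fits,
            "shapeless": shapeless, "residual_singular_values": res_sv}
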