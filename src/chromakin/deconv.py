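"""Multi-Gaussian deconvolution of absorption bands.

Fitting is done in the wavenumber (energy) domain, where Gaussian line
shapes are the convention; fitted centers and widths can be converted back
to nm for comparison with band maxima quoted on a wavelength scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .spectra import SteadySpectrum, nm_to_wavenumber

__all__ = [
    "GaussianBand",
    "DeconvResult",
    "GaussianDeconvolution",
    "fit_gaussians",
    "band_fwhm_nm",
    "ConditioningWarning",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ConditioningWarning(UserWarning):
    """Raised when a deconvolution is poorly determined (e.g. coincident bands)."""


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian band in the energy domain."""

    center_cm1: float
    fwhm_cm1: float
    area: float

    def __post_init__(self) -> None:
        if self.fwhm_cm1 <= 0:
            raise ValueError("fwhm must be positive")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    @property
    def sigma_cm1(self) -> float:
        return self.fwhm_cm1 * _FWHM_TO_SIGMA

    @property
    def amplitude(self) -> float:
        return self.area / (self.sigma_cm1 * np.sqrt(2.0 * np.pi))

    def profile(self, nu_cm1: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((nu_cm1 - self.center_cm1) / self.sigma_cm1) ** 2)

    @property
    def center_nm(self) -> float:
        return 1e7 / self.center_cm1


@dataclass
class DeconvResult:
    bands: list[GaussianBand]          # ascending center
    residual_rms: float
    converged: bool
    cost: float = 0.0

    def model(self, nu_cm1: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(nu_cm1, float))
        for b in self.bands:
            out = out + b.profile(nu_cm1)
        return out

    def total_area(self) -> float:
        return sum(b.area for b in self.bands)


def band_fwhm_nm(band: GaussianBand) -> float:
    """Convert a band's fwhm from cm^-1 to nm at its center.

    First-order relation d(lambda) = lambda^2 d(nu) / 1e7.
    """
    if band.center_cm1 <= 0:
        raise ValueError("band center must be positive")
    lam = 1e7 / band.center_cm1
    return lam ** 2 * band.fwhm_cm1 / 1e7


class GaussianDeconvolution(BaseEstimator):
    """Nonlinear least-squares fit of a sum of Gaussians to a spectrum.

    Parameters
    ----------
    n_bands : int
    window_nm : optional (lo, hi) wavelength window to fit.
    init : optional list of GaussianBand used as starting values; if fewer
        than ``n_bands``, the remainder start at the largest residual of the
        partial model (nested initialization).
    fwhm_bounds_cm1 : (float, float), default (20, 800).
    n_starts : multi-start count with jittered initializations (seeded).
    seed : int

    Attributes (after fit)
    ----------------------
    bands_ : list of GaussianBand sorted by ascending center;
    residual_rms_, converged_, result_.
    """

    def __init__(self, n_bands=1, window_nm=None, init=None,
                 fwhm_bounds_cm1=(20.0, 800.0), n_starts=5, seed=0,
                 max_iter=400):
        self.n_bands = n_bands
        self.window_nm = window_nm
        self.init = init
        self.fwhm_bounds_cm1 = fwhm_bounds_cm1
        self.n_starts = n_starts
        self.seed = seed
        self.max_iter = max_iter

    def _next_band(self, nu, y, bands, f_lo, f_hi):
        """A new band at the largest residual of the current partial model."""
        fwhm0 = np.clip((nu[-1] - nu[0]) / (3.0 * self.n_bands), f_lo * 1.5, f_hi / 1.5)
        partial = DeconvResult(bands, 0.0, True).model(nu) if bands else np.zeros_like(y)
        resid = y - partial
        c = float(nu[int(np.argmax(resid))])
        amp = max(float(resid.max()), 1e-12 * max(y.max(), 1.0))
        return GaussianBand(c, fwhm0, amp * fwhm0 * _FWHM_TO_SIGMA * np.sqrt(2 * np.pi))

    def fit(self, spec: SteadySpectrum):
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        wl, vals = spec.wavelengths_nm, spec.values
        if self.window_nm is not None:
            lo, hi = self.window_nm
            m = (wl >= lo) & (wl <= hi)
            wl, vals = wl[m], vals[m]
        if wl.size < 3 * self.n_bands:
            warnings.warn("n_bands exceeds the data support", ConditioningWarning,
                          stacklevel=2)
        # energy domain, ascending
        nu = nm_to_wavenumber(wl)[::-1].copy()
        y = vals[::-1].copy()

        f_lo, f_hi = self.fwhm_bounds_cm1
        lo_b = np.tile([nu[0], np.log(f_lo), 0.0], self.n_bands)
        hi_b = np.tile([nu[-1], np.log(f_hi), np.inf], self.n_bands)

        def pack(bands):
            return np.concatenate([[b.center_cm1, np.log(b.fwhm_cm1), b.amplitude]
                                   for b in bands])

        def unpack(theta):
            out = []
            for i in range(self.n_bands):
                c, lf, a = theta[3 * i: 3 * i + 3]
                fw = float(np.exp(lf))
                out.append(GaussianBand(float(c), fw,
                                        max(a, 0.0) * fw * _FWHM_TO_SIGMA * np.sqrt(2 * np.pi)))
            return out

        def residual(theta):
            model = np.zeros_like(y)
            for i in range(self.n_bands):
                c, lf, a = theta[3 * i: 3 * i + 3]
                sig = np.exp(lf) * _FWHM_TO_SIGMA
                model += a * np.exp(-0.5 * ((nu - c) / sig) ** 2)
            return model - y

        def solve_n(bands, n):
            """Least-squares solve for the first n bands only."""
            th = np.concatenate([[b.center_cm1, np.log(b.fwhm_cm1), b.amplitude]
                                 for b in bands])
            th = np.clip(th, lo_b[: 3 * n] + 1e-12, hi_b[: 3 * n] - 1e-12)

            def res_n(theta):
                model = np.zeros_like(y)
                for i in range(n):
                    c, lf, a = theta[3 * i: 3 * i + 3]
                    sig = np.exp(lf) * _FWHM_TO_SIGMA
                    model += a * np.exp(-0.5 * ((nu - c) / sig) ** 2)
                return model - y

            return least_squares(res_n, th, bounds=(lo_b[: 3 * n], hi_b[: 3 * n]),
                                 method="trf", max_nfev=self.max_iter * (th.size + 1))

        # greedy build-up: add one band at the current residual maximum and
        # refit at every order; robust against bands swallowing each other
        f_lo, f_hi = self.fwhm_bounds_cm1
        bands = list(self.init or [])[: self.n_bands]
        while len(bands) < self.n_bands:
            bands.append(self._next_band(nu, y, bands, f_lo, f_hi))
            n = len(bands)
            sol = solve_n(bands, n)
            bands = [GaussianBand(sol.x[3 * i],
                                  float(np.exp(sol.x[3 * i + 1])),
                                  max(sol.x[3 * i + 2], 1e-300)
                                  * np.exp(sol.x[3 * i + 1]) * _FWHM_TO_SIGMA * np.sqrt(2 * np.pi))
                     for i in range(n)]
        theta0 = np.clip(pack(bands), lo_b + 1e-12, hi_b - 1e-12)
        rng = np.random.default_rng(self.seed)
        best = None
        span = nu[-1] - nu[0]
        for start in range(self.n_starts):
            th = theta0.copy()
            if start > 0:
                th[0::3] = np.clip(th[0::3] + rng.normal(0, 0.05 * span, self.n_bands),
                                   lo_b[0::3], hi_b[0::3])
                th[1::3] = np.clip(th[1::3] + rng.normal(0, 0.2, self.n_bands),
                                   lo_b[1::3], hi_b[1::3])
            sol = least_squares(residual, th, bounds=(lo_b, hi_b), method="trf",
                                max_nfev=self.max_iter * (th.size + 1))
            if best is None or sol.cost < best.cost:
                best = sol

        bands = sorted(unpack(best.x), key=lambda b: b.center_cm1)
        rms = float(np.sqrt(np.mean(residual(best.x) ** 2)))
        converged = bool(best.status > 0)
        if not converged:
            warnings.warn("deconvolution hit the iteration cap", stacklevel=2)
        centers = np.array([b.center_cm1 for b in bands])
        fwhms = np.array([b.fwhm_cm1 for b in bands])
        areas = np.array([b.area for b in bands])
        if self.n_bands > 1:
            gap = np.diff(centers)
            coincide = np.any(gap < 0.25 * (fwhms[:-1] + fwhms[1:]) / 2.0)
            unused = np.any(areas < 1e-6 * max(areas.max(), 1e-300))
            if coincide or unused:
                warnings.warn("deconvolution is poorly determined: fitted bands "
                              "coincide or carry no area", ConditioningWarning,
                              stacklevel=2)
        self.bands_ = bands
        self.residual_rms_ = rms
        self.converged_ = converged
        self.result_ = DeconvResult(bands, rms, converged, float(best.cost))
        return self


def fit_gaussians(spec: SteadySpectrum, n_bands: int, init=None,
                  window_nm=None, **kw) -> DeconvResult:
    """Functional wrapper around :class:`GaussianDeconvolution`."""
    est = GaussianDeconvolution(n_bands=n_bands, init=init, window_nm=window_nm, **kw)
    return est.fit(spec).result_
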