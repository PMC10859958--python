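"""Pigment-extract spectral unmixing and stoichiometry arithmetic.

An 80%-acetone extract absorption spectrum is decomposed into per-pigment
contributions by non-negative least squares against reference pigment
spectra (per-unit-concentration scale); the chlorophyll coefficients are
then normalized to a fixed Chl total per complex (default 12 for a
monomeric antenna) and the standard pigment ratios are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .spectra import SteadySpectrum, read_spectrum

__all__ = [
    "CHLOROPHYLLS",
    "PigmentBasis",
    "Stoichiometry",
    "RatioReport",
    "PigmentUnmixer",
    "unmix",
    "to_stoichiometry",
    "ratios",
    "relative_oscillator_strengths",
    "synthetic_pigment_basis",
]

CHLOROPHYLLS = ("chl_a", "chl_b", "chl_d", "chl_f")


@dataclass
class PigmentBasis:
    """Reference pigment spectra on a common grid, per-unit-concentration."""

    names: list[str]
    spectra: list[SteadySpectrum]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.spectra):
            raise ValueError("one spectrum per pigment name required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("pigment names must be unique")
        grid = self.spectra[0].wavelengths_nm
        for s in self.spectra[1:]:
            if not np.array_equal(s.wavelengths_nm, grid):
                raise ValueError("basis spectra must share one wavelength grid")
        for name, s in zip(self.names, self.spectra):
            if np.any(s.values < 0):
                raise ValueError(f"basis spectrum {name!r} has negative values")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm

    def matrix(self) -> np.ndarray:
        """(n_wavelengths, n_pigments) design matrix."""
        return np.column_stack([s.values for s in self.spectra])

    @classmethod
    def from_directory(cls, directory) -> "PigmentBasis":
        """Load ``chl_a.txt`` etc. from a directory of two-column spectra."""
        directory = Path(directory)
        files = sorted(directory.glob("*.txt"))
        if not files:
            raise FileNotFoundError(f"no .txt basis spectra in {directory}")
        names = [f.stem for f in files]
        return cls(names, [read_spectrum(f) for f in files])


@dataclass
class Stoichiometry:
    """Per-pigment counts per complex, chlorophylls normalized to a total."""

    counts: dict[str, float]
    total_chl: float = 12.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        s = sum(v for k, v in self.counts.items() if k in CHLOROPHYLLS)
        if abs(s - self.total_chl) > 1e-9 * self.total_chl:
            raise ValueError("chlorophyll counts must sum to total_chl")

    def chlorophyll_counts(self) -> dict[str, float]:
        return {k: v for k, v in self.counts.items() if k in CHLOROPHYLLS}


@dataclass(frozen=True)
class RatioReport:
    """The printed pigment ratios; fields are None when undefined."""

    a_b: float | None = None
    a_plus_d_b: float | None = None
    a_plus_f_b: float | None = None
    a_d: float | None = None
    a_f: float | None = None
    chl_car: float | None = None


class PigmentUnmixer(BaseEstimator):
    """Non-negative least-squares unmixing of an extract spectrum.

    Parameters
    ----------
    fit_window_nm : (float, float)
        Wavelength window of the fit (default 600-750 nm, the Qy region of
        an acetone extract).  Extend into the blue to constrain carotenoids.
    total_chl : float
        Chlorophyll total used for the stoichiometry normalization.

    Attributes (after fit)
    ----------------------
    coefficients_ : dict pigment -> concentration-scale coefficient;
    residual_norm_ ; stoichiometry_ : Stoichiometry ; ratios_ : RatioReport.
    """

    def __init__(self, fit_window_nm=(600.0, 750.0), total_chl=12.0):
        self.fit_window_nm = fit_window_nm
        self.total_chl = total_chl

    def fit(self, extract: SteadySpectrum, basis: PigmentBasis):
        lo, hi = self.fit_window_nm
        grid = basis.wavelengths_nm
        mask = (grid >= lo) & (grid <= hi)
        if (extract.wavelengths_nm[0] > lo) or (extract.wavelengths_nm[-1] < hi):
            raise ValueError("extract spectrum does not cover the fit window")
        if mask.sum() < len(basis.names):
            raise ValueError("fit window contains too few grid points")
        A = basis.matrix()[mask]
        self._check_conditioning(A, basis.names)
        y = extract.interp(grid[mask])
        coef, rnorm = nnls(A, y)
        self.coefficients_ = dict(zip(basis.names, coef))
        self.residual_norm_ = float(rnorm)
        if any(self.coefficients_.get(p, 0.0) > 0 for p in CHLOROPHYLLS):
            self.stoichiometry_ = to_stoichiometry(self.coefficients_, self.total_chl)
            self.ratios_ = ratios(self.stoichiometry_)
        else:
            self.stoichiometry_ = None
            self.ratios_ = None
        return self

    @staticmethod
    def _check_conditioning(A: np.ndarray, names: list[str]) -> None:
        norms = np.linalg.norm(A, axis=0)
        weak = norms < 1e-12 * max(norms.max(), 1e-300)
        if np.any(weak):
            bad = [n for n, w in zip(names, weak) if w]
            raise np.linalg.LinAlgError(
                f"basis component(s) {bad} have no support in the fit window")
        An = A / norms
        gram = An.T @ An
        n = len(names)
        for i in range(n):
            for j in range(i + 1, n):
                if gram[i, j] > 1.0 - 1e-10:
                    raise np.linalg.LinAlgError(
                        f"basis is rank deficient on the window: "
                        f"{names[i]!r} and {names[j]!r} are collinear")


def unmix(extract: SteadySpectrum, basis: PigmentBasis,
          fit_window_nm=(600.0, 750.0)) -> dict[str, float]:
    """NNLS coefficients per pigment (functional wrapper)."""
    est = PigmentUnmixer(fit_window_nm=fit_window_nm).fit(extract, basis)
    return est.coefficients_


def to_stoichiometry(coefficients: dict[str, float], total_chl: float = 12.0) -> Stoichiometry:
    """Scale coefficients so the chlorophylls sum to ``total_chl``.

    The carotenoid coefficient is scaled by the same factor, preserving all
    ratios.
    """
    chl_sum = sum(v for k, v in coefficients.items() if k in CHLOROPHYLLS)
    if chl_sum <= 0:
        raise ValueError("no positive chlorophyll coefficient to normalize")
    factor = total_chl / chl_sum
    return Stoichiometry({k: v * factor for k, v in coefficients.items()}, total_chl)


def ratios(stoich: Stoichiometry) -> RatioReport:
    """Plain quotients of the stoichiometric counts (None for 0 denominators)."""
    c = stoich.counts
    a, b = c.get("chl_a", 0.0), c.get("chl_b", 0.0)
    d, f, car = c.get("chl_d", 0.0), c.get("chl_f", 0.0), c.get("car", 0.0)
    # counts below a millionth of the Chl total are numerical zeros
    tol = 1e-6 * stoich.total_chl
    q = lambda num, den: num / den if den > tol else None
    return RatioReport(
        a_b=q(a, b),
        a_plus_d_b=q(a + d, b),
        a_plus_f_b=q(a + f, b),
        a_d=q(a, d),
        a_f=q(a, f),
        chl_car=q(a + b + d + f, car),
    )


def relative_oscillator_strengths(basis: PigmentBasis,
                                  window_nm=(630.0, 800.0),
                                  reference: str = "chl_a") -> dict[str, float]:
    """Qy-window integral of each pigment relative to the reference pigment."""
    if reference not in basis.names:
        raise KeyError(f"reference pigment {reference!r} not in basis")
    lo = max(window_nm[0], basis.wavelengths_nm[0])
    hi = min(window_nm[1], basis.wavelengths_nm[-1])
    areas = {n: s.band_area((lo, hi)) for n, s in zip(basis.names, basis.spectra)}
    ref = areas[reference]
    if ref <= 0:
        raise ValueError("reference pigment has no area in the window")
    return {n: a / ref for n, a in areas.items()}


# -- synthetic basis -------------------------------------------------------

def _gauss_nm(wl: np.ndarray, center: float, fwhm: float, amp: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def synthetic_pigment_basis(wavelengths_nm=None) -> PigmentBasis:
    """Gaussian-band stand-in for in-solvent pigment reference spectra.

    Synthetic: sums of 2-3 Gaussians per pigment with Qy maxima in the
    80%-acetone style (Chl a 663, b 646, d 688, f 707 nm) plus Soret bands;
    the carotenoid component only absorbs in the blue.  Shapes are fixture
    choices, not measured spectra.  Each chlorophyll is scaled so the Qy
    (630 nm - red edge) areas sit in the relative oscillator-strength ratio
    a:b:d:f = 1.0:0.67:1.20:1.34.
    """
    wl = np.arange(400.0, 781.0, 1.0) if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    bands = {
        "chl_a": [(663, 22, 1.00), (613, 30, 0.15), (430, 35, 1.25)],
        "chl_b": [(646, 20, 0.74), (600, 28, 0.10), (460, 38, 1.60)],
        "chl_d": [(688, 24, 1.10), (620, 32, 0.14), (445, 36, 1.05)],
        "chl_f": [(707, 26, 1.13), (625, 34, 0.12), (440, 36, 0.95)],
        "car":   [(455, 30, 1.20), (485, 28, 1.05)],
    }
    osc = {"chl_a": 1.0, "chl_b": 0.67, "chl_d": 1.20, "chl_f": 1.34}
    names = list(bands)
    spectra = []
    raw = {}
    for name in names:
        v = np.zeros_like(wl)
        for c, fw, a in bands[name]:
            v += _gauss_nm(wl, c, fw, a)
        raw[name] = v
    qy = (630.0, float(wl[-1]))
    area = {n: SteadySpectrum(wl, raw[n], "absorption").band_area(qy)
            for n in CHLOROPHYLLS}
    for name in names:
        v = raw[name]
        if name in osc:
            v = v * (osc[name] * area["chl_a"] / area[name])
        spectra.append(SteadySpectrum(wl, v, "absorption", label=name))
    return PigmentBasis(names, spectra)
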