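"""Steady-state spectra: containers, I/O and spectral-form arithmetic.

Wavelength grids are in nm, energies in vacuum wavenumbers (cm^-1); no
air/vacuum correction is applied.  Band areas use the trapezoidal rule and
all interpolation is linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "KB_CM1_PER_K",
    "SteadySpectrum",
    "QCRecord",
    "TransitionEstimate",
    "nm_to_wavenumber",
    "normalize_qy_area",
    "difference_spectrum",
    "estimate_00_transition",
    "stokes_shift",
    "thermal_gap",
    "excitation_density",
    "read_spectrum",
    "write_spectrum",
]

#: Boltzmann constant in spectroscopic units.
KB_CM1_PER_K = 0.6950

QY_WINDOW_NM = (630.0, 800.0)


@dataclass
class SteadySpectrum:
    """A wavelength-indexed steady-state spectrum.

    Parameters
    ----------
    wavelengths_nm : array
        Strictly increasing wavelength grid (nm), length >= 3.
    values : array
        Signal on the grid (OD for absorption, arbitrary units for emission).
    kind : {"absorption", "emission"}
    temperature_K : float or None
        Sample temperature; ``None`` when unknown.
    label : str
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "absorption"
    temperature_K: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size < 3:
            raise ValueError("wavelength grid must be 1-D with length >= 3")
        if self.values.shape != self.wavelengths_nm.shape:
            raise ValueError("values and wavelengths must have equal length")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not (np.all(np.isfinite(self.wavelengths_nm)) and np.all(np.isfinite(self.values))):
            raise ValueError("spectrum contains non-finite values")
        if self.kind not in ("absorption", "emission"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.temperature_K is not None and self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    # -- convenience -------------------------------------------------------
    def interp(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linearly interpolate the spectrum onto a new grid (no extrapolation)."""
        w = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if np.any(w < lo) or np.any(w > hi):
            raise ValueError("requested grid extends outside the spectrum")
        return np.interp(w, self.wavelengths_nm, self.values)

    def peak_nm(self) -> float:
        """Wavelength of the maximum value."""
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def scaled(self, factor: float, label: str | None = None) -> "SteadySpectrum":
        return SteadySpectrum(
            self.wavelengths_nm.copy(), self.values * factor, self.kind,
            self.temperature_K, self.label if label is None else label,
        )

    def unit_max(self) -> "SteadySpectrum":
        """Spectrum normalized to unit maximum."""
        m = float(np.max(self.values))
        if m <= 0:
            raise ValueError("cannot max-normalize a non-positive spectrum")
        return self.scaled(1.0 / m)

    def band_area(self, window_nm: tuple[float, float]) -> float:
        """Trapezoidal integral over ``window_nm`` (endpoints interpolated)."""
        lo, hi = float(window_nm[0]), float(window_nm[1])
        w = self.wavelengths_nm
        if lo < w[0] or hi > w[-1]:
            raise ValueError(f"window [{lo}, {hi}] outside spectral grid [{w[0]}, {w[-1]}]")
        inside = w[(w > lo) & (w < hi)]
        grid = np.concatenate([[lo], inside, [hi]])
        return float(np.trapezoid(self.interp(grid), grid))


@dataclass(frozen=True)
class QCRecord:
    """Inputs of the excitation-density estimate for a pump-probe measurement."""

    n_chl: int
    delta_od_max: float
    od_max: float

    def __post_init__(self) -> None:
        if self.n_chl <= 0:
            raise ValueError("n_chl must be a positive integer")
        if self.delta_od_max < 0:
            raise ValueError("delta_od_max must be >= 0")
        if self.od_max <= 0:
            raise ValueError("od_max must be > 0")


@dataclass(frozen=True)
class TransitionEstimate:
    """A 0-0 transition estimated from the absorption/emission crossing."""

    lambda00_nm: float
    energy00_cm1: float = field(default=0.0)
    method: str = "abs-emi intersection"

    def __post_init__(self) -> None:
        if self.energy00_cm1 == 0.0:
            object.__setattr__(self, "energy00_cm1", nm_to_wavenumber(self.lambda00_nm))
        rel = abs(self.energy00_cm1 - 1e7 / self.lambda00_nm) / self.energy00_cm1
        if rel > 1e-9:
            raise ValueError("energy00_cm1 inconsistent with lambda00_nm")


def nm_to_wavenumber(lambda_nm):
    """Convert a vacuum wavelength (nm) to a wavenumber (cm^-1)."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = 1e7 / lam
    return float(out) if np.isscalar(lambda_nm) or out.ndim == 0 else out


def normalize_qy_area(
    spec: SteadySpectrum,
    stoich=None,
    osc: Mapping[str, float] | None = None,
    window_nm: tuple[float, float] = QY_WINDOW_NM,
    target_area: float | None = None,
) -> SteadySpectrum:
    """Scale a spectrum so its Qy-window area matches the complex's Chl content.

    The target area is ``sum_p count_p * osc_p`` over the chlorophylls of
    ``stoich`` (weights default to 1), mirroring absorption spectra scaled to
    pigment content weighted by relative oscillator strength.  Alternatively
    pass ``target_area`` directly.
    """
    if target_area is None:
        if stoich is None:
            raise ValueError("provide either a stoichiometry or target_area")
        counts = stoich.chlorophyll_counts() if hasattr(stoich, "chlorophyll_counts") else dict(stoich)
        osc = dict(osc or {})
        target_area = sum(c * osc.get(name, 1.0) for name, c in counts.items())
    if target_area <= 0:
        raise ValueError("target area must be positive")
    area = spec.band_area(window_nm)
    if area <= 0:
        raise ValueError("spectrum has non-positive area in the window")
    return spec.scaled(target_area / area)


def difference_spectrum(a: SteadySpectrum, b: SteadySpectrum) -> SteadySpectrum:
    """a - b on their overlapping grid (b interpolated onto a's grid)."""
    lo = max(a.wavelengths_nm[0], b.wavelengths_nm[0])
    hi = min(a.wavelengths_nm[-1], b.wavelengths_nm[-1])
    mask = (a.wavelengths_nm >= lo) & (a.wavelengths_nm <= hi)
    if mask.sum() < 3:
        raise ValueError("spectra do not overlap (or overlap covers < 3 points)")
    w = a.wavelengths_nm[mask]
    diff = a.values[mask] - b.interp(w)
    return SteadySpectrum(w, diff, a.kind, a.temperature_K,
                          label=f"{a.label} - {b.label}".strip(" -"))


def estimate_00_transition(
    absorption: SteadySpectrum, emission: SteadySpectrum
) -> TransitionEstimate:
    """Estimate the 0-0 transition as the absorption/emission crossing point.

    Both spectra are normalized to unit maximum; the crossing is searched
    between the absorption maximum and the emission maximum and located by
    linear interpolation between the bracketing grid points.
    """
    a = absorption.unit_max()
    e = emission.unit_max()
    lam_a, lam_e = a.peak_nm(), e.peak_nm()
    if lam_a == lam_e:
        raise ValueError("no crossing: absorption and emission maxima coincide")
    if lam_a > lam_e:
        raise ValueError("absorption maximum must be blue of the emission maximum")
    grid = np.unique(np.concatenate([a.wavelengths_nm, e.wavelengths_nm]))
    grid = grid[(grid >= max(lam_a, a.wavelengths_nm[0], e.wavelengths_nm[0]))
                & (grid <= min(lam_e, a.wavelengths_nm[-1], e.wavelengths_nm[-1]))]
    if grid.size < 2:
        raise ValueError("no crossing: search interval is empty")
    d = a.interp(grid) - e.interp(grid)
    crossings = [float(grid[i]) for i in np.nonzero(d == 0)[0]]
    for i in np.nonzero(d[:-1] * d[1:] < 0)[0]:
        x0, x1, y0, y1 = grid[i], grid[i + 1], d[i], d[i + 1]
        crossings.append(float(x0 - y0 * (x1 - x0) / (y1 - y0)))
    if not crossings:
        raise ValueError("no crossing: absorption - emission does not change sign")
    crossings.sort()
    if len(crossings) > 1:
        warnings.warn("multiple abs/emi crossings; returning the bluest", stacklevel=2)
    return TransitionEstimate(crossings[0])


def stokes_shift(abs_max_nm: float, emi_max_nm: float) -> float:
    """Stokes shift in nm (emission maximum minus absorption maximum)."""
    if emi_max_nm < abs_max_nm:
        raise ValueError("emission maximum must not be blue of absorption maximum")
    return float(emi_max_nm - abs_max_nm)


def thermal_gap(e1_cm1: float, e2_cm1: float, temperature_K: float = 298.0) -> float:
    """Energy gap |e1 - e2| expressed in units of kB*T."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return abs(e1_cm1 - e2_cm1) / (KB_CM1_PER_K * temperature_K)


def excitation_density(qc: QCRecord) -> float:
    """Fraction of excited Chls per pulse: N_Chl * 1/2 * dOD_max / OD_max."""
    return qc.n_chl * 0.5 * qc.delta_od_max / qc.od_max


# -- I/O -------------------------------------------------------------------

def read_spectrum(path) -> SteadySpectrum:
    """Read a two-column (wavelength_nm, value) text spectrum.

    Whitespace- or comma-delimited; ``#``-prefixed headers may carry
    ``kind:``, ``temperature_K:`` and ``label:`` metadata.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip().lower()] = v.strip()
            continue
        rows.append([float(x) for x in line.replace(",", " ").split()[:2]])
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two numeric columns")
    temp = meta.get("temperature_k")
    return SteadySpectrum(
        arr[:, 0], arr[:, 1],
        kind=meta.get("kind", "absorption"),
        temperature_K=float(temp) if temp else None,
        label=meta.get("label", path.stem),
    )


def write_spectrum(path, spec: SteadySpectrum) -> None:
    """Write a spectrum in the two-column text dialect of :func:`read_spectrum`."""
    path = Path(path)
    lines = [f"# kind: {spec.kind}"]
    if spec.temperature_K is not None:
        lines.append(f"# temperature_K: {spec.temperature_K:g}")
    if spec.label:
        lines.append(f"# label: {spec.label}")
    for w, v in zip(spec.wavelengths_nm, spec.values):
        lines.append(f"{w:.17g}\t{v:.17g}")
    path.write_text("\n".join(lines) + "\n")
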