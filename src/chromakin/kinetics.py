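"""Compartmental kinetics and synthetic time-resolved surfaces.

Time is in picoseconds, wavelengths in nm.  Surfaces carry a modality tag:
``tcspc_counts`` (non-negative Poisson photon counts) or ``ta_delta_od``
(signed differential absorbance with Gaussian noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .irf import IRFModel, convolved_decays

__all__ = [
    "DASet",
    "KineticScheme",
    "TimeResolvedSurface",
    "simulate_das_surface",
    "concentrations",
    "simulate_compartmental",
    "read_surface",
    "write_surface",
]


@dataclass
class DASet:
    """Lifetimes paired with their decay-associated spectra.

    ``lifetimes`` are strictly ascending (ps); ``spectra`` has one row per
    lifetime over ``wavelengths_nm``.
    """

    lifetimes: np.ndarray
    spectra: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(np.diff(self.lifetimes) <= 0):
            raise ValueError("lifetimes must be strictly ascending")
        if self.spectra.shape != (self.lifetimes.size, self.wavelengths_nm.size):
            raise ValueError("spectra must be (n_lifetimes, n_wavelengths)")

    @property
    def n_components(self) -> int:
        return int(self.lifetimes.size)

    def rates(self) -> np.ndarray:
        return 1.0 / self.lifetimes


@dataclass
class KineticScheme:
    """A first-order compartmental scheme dc/dt = K c + IRF(t) * input.

    Off-diagonal K[j, i] >= 0 is the i -> j transfer rate; diagonal entries
    are minus the column sums minus any loss rate, so total population is
    non-increasing.  ``input_vector`` is non-negative with unit sum.
    """

    rate_matrix: np.ndarray
    input_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        K = np.atleast_2d(np.asarray(self.rate_matrix, dtype=float))
        if K.shape[0] != K.shape[1]:
            raise ValueError("rate matrix must be square")
        off = K - np.diag(np.diag(K))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal transfer rates must be >= 0")
        colsum = K.sum(axis=0)
        if np.any(colsum > 1e-9 * max(1.0, np.abs(K).max())):
            raise ValueError("rate matrix must not create population (column sums <= 0)")
        self.rate_matrix = K
        n = K.shape[0]
        if self.input_vector is None:
            x = np.zeros(n)
            x[0] = 1.0
        else:
            x = np.asarray(self.input_vector, dtype=float)
            if x.shape != (n,) or np.any(x < 0) or not np.isclose(x.sum(), 1.0):
                raise ValueError("input vector must be non-negative with unit sum")
        self.input_vector = x

    @property
    def n_compartments(self) -> int:
        return int(self.rate_matrix.shape[0])

    @classmethod
    def sequential(cls, rates) -> "KineticScheme":
        """Unidirectional chain 1 -> 2 -> ... -> n; the last rate is the
        terminal decay to the ground state."""
        rates = np.asarray(rates, dtype=float)
        if np.any(rates < 0):
            raise ValueError("rates must be >= 0")
        n = rates.size
        K = np.zeros((n, n))
        for i in range(n):
            K[i, i] = -rates[i]
            if i + 1 < n:
                K[i + 1, i] = rates[i]
        return cls(K)


@dataclass
class TimeResolvedSurface:
    """A signal matrix over a time grid x wavelength grid."""

    times: np.ndarray
    wavelengths_nm: np.ndarray
    signal: np.ndarray
    modality: str = "ta_delta_od"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("time and wavelength grids must be strictly ascending")
        if self.signal.shape != (self.times.size, self.wavelengths_nm.size):
            raise ValueError("signal must be (n_times, n_wavelengths)")
        if self.modality not in ("tcspc_counts", "ta_delta_od"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "tcspc_counts":
            if np.any(self.signal < 0):
                raise ValueError("TCSPC counts must be non-negative")

    def window(self, t_min: float | None = None, t_max: float | None = None) -> "TimeResolvedSurface":
        """Restrict the surface to a time window (inclusive)."""
        lo = -np.inf if t_min is None else t_min
        hi = np.inf if t_max is None else t_max
        m = (self.times >= lo) & (self.times <= hi)
        return TimeResolvedSurface(self.times[m], self.wavelengths_nm,
                                   self.signal[m], self.modality, dict(self.meta))


def _apply_noise(model: np.ndarray, modality: str, noise, rng: np.random.Generator):
    """Return (noisy signal, modality-consistent dtype)."""
    if noise is None:
        return model
    kind = noise.get("kind")
    if kind == "poisson":
        if modality != "tcspc_counts":
            raise ValueError("poisson noise applies to tcspc_counts surfaces")
        peak = float(noise.get("peak_counts", 1e4))
        scale = np.abs(model).max()
        if model.min() < -1e-9 * max(scale, 1e-300):
            raise ValueError("negative expected counts in TCSPC simulation")
        if model.max() <= 0:
            return np.zeros_like(model)
        scaled = np.clip(model * (peak / model.max()), 0, None)
        return rng.poisson(scaled).astype(float)
    if kind == "gaussian":
        sigma = noise.get("sigma")
        if sigma is None:
            sigma = float(noise.get("sigma_frac", 0.003)) * np.abs(model).max()
        return model + rng.normal(0.0, sigma, size=model.shape)
    raise ValueError(f"unknown noise kind {kind!r}")


def simulate_das_surface(
    das: DASet,
    irf: IRFModel | None,
    times,
    wavelengths_nm=None,
    noise: dict | None = None,
    seed: int | None = None,
    modality: str | None = None,
) -> TimeResolvedSurface:
    """Simulate psi(t, lambda) = sum_i DAS_i(lambda) [exp(-t/tau_i) (x) IRF](t).

    ``noise={"kind": "poisson", "peak_counts": ...}`` rescales the surface to
    the requested peak before drawing counts; ``{"kind": "gaussian",
    "sigma": ...}`` (or ``sigma_frac`` of the peak) adds Gaussian noise.
    """
    times = np.asarray(times, dtype=float)
    wl = das.wavelengths_nm if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    spectra = das.spectra if wavelengths_nm is None else np.stack(
        [np.interp(wl, das.wavelengths_nm, row) for row in das.spectra])
    C = convolved_decays(times, das.rates(), irf)
    model = C @ spectra
    if modality is None:
        modality = "tcspc_counts" if (noise or {}).get("kind") == "poisson" else "ta_delta_od"
    rng = np.random.default_rng(seed)
    sig = _apply_noise(model, modality, noise, rng)
    if modality == "tcspc_counts" and noise is None:
        sig = np.clip(sig, 0.0, None)
    return TimeResolvedSurface(times, wl, sig, modality)


def concentrations(scheme: KineticScheme, irf: IRFModel | None, times) -> np.ndarray:
    """Compartment populations over time, shape (n_compartments, n_times).

    Solves dc/dt = K c + IRF(t) x by eigen-decomposition (each eigenmode is
    an IRF-convolved exponential); falls back to dense ODE integration for
    defective or complex-spectrum rate matrices (flagged with a warning).
    """
    times = np.asarray(times, dtype=float)
    K = scheme.rate_matrix
    x = scheme.input_vector
    lam, V = np.linalg.eig(K)
    separable = (
        np.all(np.abs(lam.imag) < 1e-12 * max(1.0, np.abs(lam).max()))
        and np.linalg.cond(V) < 1e10
    )
    if separable:
        lam = lam.real
        V = V.real
        beta = np.linalg.solve(V, x)
        G = convolved_decays(times, -lam, irf)  # (nt, n)
        return (V * beta) @ G.T
    warnings.warn("rate matrix is defective or complex; using ODE fallback", stacklevel=2)
    from scipy.integrate import solve_ivp

    if irf is None or irf.kind == "delta":
        t0 = irf.t0 if irf is not None else 0.0

        def pulse(t):
            return 0.0
        c0 = x.copy()
        t_start = t0
    else:
        sig = irf.fwhm / 2.3548200450309493 if irf.kind == "gaussian" else None
        if irf.kind == "gaussian":
            def pulse(t):
                return np.exp(-0.5 * ((t - irf.t0) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
            t_start = irf.t0 - 6 * sig
        else:
            def pulse(t):
                return np.interp(t, irf.times + irf.t0, irf.trace, left=0.0, right=0.0)
            t_start = irf.times[0] + irf.t0
        c0 = np.zeros_like(x)

    def rhs(t, c):
        return K @ c + pulse(t) * x

    t_eval = times[times >= t_start]
    sol = solve_ivp(rhs, (t_start, max(times[-1], t_start + 1e-9)), c0,
                    t_eval=t_eval, rtol=1e-10, atol=1e-12, method="LSODA")
    out = np.zeros((K.shape[0], times.size))
    out[:, times >= t_start] = sol.y
    return out


def simulate_compartmental(
    scheme: KineticScheme,
    sads: np.ndarray,
    irf: IRFModel | None,
    times,
    wavelengths_nm,
    noise: dict | None = None,
    seed: int | None = None,
    modality: str = "ta_delta_od",
) -> TimeResolvedSurface:
    """Simulate signal = concentrations(scheme)^T . SADS (+ optional noise)."""
    sads = np.atleast_2d(np.asarray(sads, dtype=float))
    if sads.shape[0] != scheme.n_compartments:
        raise ValueError("sads must have one row per compartment")
    wl = np.asarray(wavelengths_nm, dtype=float)
    if sads.shape[1] != wl.size:
        raise ValueError("sads columns must match the wavelength grid")
    times = np.asarray(times, dtype=float)
    C = concentrations(scheme, irf, times)
    model = C.T @ sads
    rng = np.random.default_rng(seed)
    sig = _apply_noise(model, modality, noise, rng)
    return TimeResolvedSurface(times, wl, sig, modality)


# -- surface I/O -----------------------------------------------------------

def write_surface(path, surface: TimeResolvedSurface) -> None:
    """Write a surface as delimited text: first row wavelengths, first column
    times, ``#`` headers for modality/metadata.  Exact decimal round-trip."""
    path = Path(path)
    lines = [f"# modality: {surface.modality}"]
    for k, v in surface.meta.items():
        lines.append(f"# {k}: {v}")
    lines.append("\t".join(["time_ps"] + [f"{w:.17g}" for w in surface.wavelengths_nm]))
    for t, row in zip(surface.times, surface.signal):
        lines.append("\t".join([f"{t:.17g}"] + [f"{v:.17g}" for v in row]))
    path.write_text("\n".join(lines) + "\n")


def read_surface(path) -> TimeResolvedSurface:
    """Read a surface written by :func:`write_surface`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header: list[float] | None = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        parts = line.replace(",", "\t").split()
        if header is None:
            header = [float(x) for x in parts[1:]]
            continue
        rows.append([float(x) for x in parts])
    if header is None or not rows:
        raise ValueError(f"{path}: not a surface file")
    arr = np.asarray(rows, dtype=float)
    modality = meta.pop("modality", "ta_delta_od")
    return TimeResolvedSurface(arr[:, 0], np.asarray(header), arr[:, 1:], modality, meta)
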