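"""Instrument response functions and IRF-convolved exponential decays.

Time is in picoseconds throughout.  The Gaussian case uses the analytic
exp(x)*erfcx form, which is overflow-safe for all arguments; a measured IRF
is a sampled, unit-area trace and the convolution is a discrete quadrature
on that trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, erfcx

__all__ = ["IRFModel", "conv_exp_gauss", "convolved_decays"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class IRFModel:
    """An instrument response: analytic Gaussian or measured trace.

    ``gaussian``: parameters ``t0`` (center, ps) and ``fwhm`` (ps > 0).
    ``measured``: a non-negative ``trace`` on a uniform ``times`` grid,
    normalized to unit area; ``t0`` shifts the trace.
    ``delta``: idealized zero-width response at ``t0``.
    """

    kind: str = "gaussian"
    t0: float = 0.0
    fwhm: float | None = None
    times: np.ndarray | None = None
    trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "gaussian":
            if self.fwhm is None or self.fwhm <= 0:
                raise ValueError("gaussian IRF requires fwhm > 0")
        elif self.kind == "measured":
            if self.times is None or self.trace is None:
                raise ValueError("measured IRF requires times and trace")
            self.times = np.asarray(self.times, dtype=float)
            self.trace = np.asarray(self.trace, dtype=float)
            if self.trace.shape != self.times.shape or self.times.size < 2:
                raise ValueError("IRF trace/times mismatch")
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-8):
                raise ValueError("measured IRF grid must be uniform")
            if np.any(self.trace < 0):
                raise ValueError("measured IRF trace must be non-negative")
            area = float(np.sum(self.trace) * dt[0])
            if area <= 0:
                raise ValueError("measured IRF trace must have positive area")
            self.trace = self.trace / area
        elif self.kind != "delta":
            raise ValueError(f"unknown IRF kind {self.kind!r}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def gaussian(cls, fwhm: float, t0: float = 0.0) -> "IRFModel":
        return cls(kind="gaussian", t0=t0, fwhm=fwhm)

    @classmethod
    def measured(cls, times, trace, t0: float = 0.0) -> "IRFModel":
        return cls(kind="measured", t0=t0, times=times, trace=trace)

    @classmethod
    def delta(cls, t0: float = 0.0) -> "IRFModel":
        return cls(kind="delta", t0=t0)

    def sampled_fwhm(self) -> float:
        """Full width at half maximum of the IRF profile (ps)."""
        if self.kind == "gaussian":
            return float(self.fwhm)
        if self.kind == "delta":
            return 0.0
        t, y = self.times, self.trace
        half = np.max(y) / 2.0
        above = np.nonzero(y >= half)[0]
        return float(t[above[-1]] - t[above[0]])


def _conv_decay_gauss(t, rate, t0, fwhm):
    """Convolution of exp(-rate*(t-t0))*H(t-t0) with a unit-area Gaussian.

    Valid for rate >= 0; overflow-safe (two-branch erfcx form).
    """
    t = np.asarray(t, dtype=float)
    sigma = fwhm * _FWHM_TO_SIGMA
    x = (t - t0) / sigma
    z = (rate * sigma - x) / np.sqrt(2.0)
    out = np.empty_like(x)
    pos = z >= 0
    # z >= 0: 0.5 exp(-x^2/2) erfcx(z); exponent <= 0
    out[pos] = 0.5 * np.exp(-0.5 * x[pos] ** 2) * erfcx(z[pos])
    # z < 0: plain form; exponent rate^2 sigma^2/2 - rate (t-t0) < 0 there
    neg = ~pos
    out[neg] = 0.5 * np.exp(0.5 * (rate * sigma) ** 2 - rate * (t[neg] - t0)) * erfc(z[neg])
    return out


def conv_exp_gauss(t, tau: float, t0: float = 0.0, fwhm: float = 0.1):
    """Analytic convolution of a causal exponential decay with a Gaussian IRF.

    The exponential has unit amplitude at its onset (value exp(-(t-t0)/tau)
    in the zero-width IRF limit); the Gaussian has unit area, center ``t0``
    and width ``fwhm``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    out = _conv_decay_gauss(t, 1.0 / tau, t0, fwhm)
    return float(out) if np.ndim(t) == 0 else out


def _conv_decay_measured(t, rate, irf: IRFModel):
    """Discrete convolution of exp(-rate*t)*H(t) with a sampled IRF trace.

    out(t) = exp(-rate*t) * sum_{s_j <= t} irf_j * exp(rate*s_j) * ds, using a
    cumulative sum over the (uniform) IRF grid.  Exact for the sampled trace
    up to the rectangle-rule quadrature.
    """
    t = np.asarray(t, dtype=float)
    s = irf.times + irf.t0
    ds = s[1] - s[0]
    if rate * (s[-1] - s[0]) < 500.0:
        w = irf.trace * np.exp(rate * (s - s[0])) * ds
        csum = np.concatenate([[0.0], np.cumsum(w)])
        idx = np.searchsorted(s, t, side="right")
        return csum[idx] * np.exp(-rate * (t - s[0]))
    # very fast decay relative to the IRF support: direct masked quadrature
    dtm = t[:, None] - s[None, :]
    kernel = np.where(dtm >= 0, np.exp(-rate * np.clip(dtm, 0, None)), 0.0)
    return kernel @ (irf.trace * ds)


def convolved_decays(times, rates, irf: IRFModel | None) -> np.ndarray:
    """Matrix of IRF-convolved decays, one column per rate.

    ``irf=None`` (or a delta IRF) yields plain causal exponentials.
    rate == 0 gives the IRF's cumulative integral (a conserved compartment).
    """
    times = np.asarray(times, dtype=float)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    cols = []
    for k in rates:
        if irf is None or irf.kind == "delta":
            t0 = 0.0 if irf is None else irf.t0
            dt = times - t0
            cols.append(np.where(dt >= 0, np.exp(-k * np.clip(dt, 0, None)), 0.0))
        elif irf.kind == "gaussian":
            cols.append(_conv_decay_gauss(times, k, irf.t0, irf.fwhm))
        else:
            cols.append(_conv_decay_measured(times, k, irf))
    return np.column_stack(cols)
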