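"""Named synthetic fixtures emulating the study's measurement conditions.

Each fixture bundles a simulated surface with its generation truth so that
recovery of lifetimes, spectra and mixture fractions can be tested against
known ground truth.  Spectral shapes are Gaussian bands at the band maxima
reported for these complexes; widths are fixture choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .globalfit import das_to_eads
from .irf import IRFModel
from .kinetics import (DASet, KineticScheme, TimeResolvedSurface,
                       simulate_compartmental, simulate_das_surface)
from .targetfit import sads_area

__all__ = ["FixtureBundle", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "lhca4_ab_tcspc",
    "lhca4_abd_tcspc",
    "lhca4_abf_tcspc",
    "lhca4_ab_ta",
    "lhca4_abf_ta_mixture",
)

#: TCSPC instrument constants: 92 ps fwhm response, 466 nm excitation.
TCSPC_IRF_FWHM_PS = 92.0
#: TA Gaussian IRF width (fitted values fall in 87-125 fs).
TA_IRF_FWHM_PS = 0.1


@dataclass
class FixtureBundle:
    name: str
    surface: TimeResolvedSurface
    truth: dict = field(default_factory=dict)


def _gauss(wl, center, fwhm, amp=1.0):
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _unit_area_gauss(wl, center, fwhm):
    g = _gauss(wl, center, fwhm)
    return g / np.trapezoid(g, wl)


def tcspc_irf(fwhm_ps: float = TCSPC_IRF_FWHM_PS) -> IRFModel:
    """Measured-style TCSPC response: a slightly asymmetric peak of the
    requested fwhm, sampled at 2 ps and normalized to unit area."""
    t = np.arange(-300.0, 402.0, 2.0)
    s_l = 0.85 * fwhm_ps / 2.3548200450309493
    s_r = 1.15 * fwhm_ps / 2.3548200450309493
    trace = np.where(t < 0, np.exp(-0.5 * (t / s_l) ** 2), np.exp(-0.5 * (t / s_r) ** 2))
    return IRFModel.measured(t, trace)


def _tcspc_fixture(name, seed, peak_counts, lifetimes_ps, band_defs, main_areas):
    """Common machinery of the TCSPC fixtures.

    ``band_defs`` maps component index -> list of (center, fwhm, weight)
    unit-area Gaussians; ``main_areas`` are the target DAS areas of the three
    main decay components (indices 1..3).
    """
    wl = np.arange(670.0, 781.0, 5.0)
    times = np.arange(-400.0, 13000.0 + 4.0, 4.0)
    das = np.zeros((len(lifetimes_ps), wl.size))
    for i, bands in band_defs.items():
        for c, fw, w in bands:
            das[i] += w * _unit_area_gauss(wl, c, fw)
    # scale the three main decay components to the printed area ratio
    for j, a in zip((1, 2, 3), main_areas):
        das[j] *= a / np.trapezoid(das[j], wl)
    # fluorescence is non-negative: the DAS sum bounds the surface from below
    # because the negative transfer component has the fastest decay
    if das.sum(axis=0).min() < 0:
        raise ValueError(f"{name}: DAS sum negative at some wavelength")
    dset = DASet(np.asarray(lifetimes_ps, float), das, wl)
    irf = tcspc_irf()
    surface = simulate_das_surface(
        dset, irf, times, noise={"kind": "poisson", "peak_counts": peak_counts},
        seed=seed, modality="tcspc_counts")
    truth = {
        "lifetimes_ps": np.asarray(lifetimes_ps, float),
        "lifetimes_ns": np.asarray(lifetimes_ps, float) / 1e3,
        "das": dset,
        "main_das_area_ratio": tuple(main_areas),
        "irf": irf,
        "peak_counts": peak_counts,
    }
    return FixtureBundle(name, surface, truth)


def _ta_dads(wl):
    """Six-component DADS of an ab-type complex: three energy-transfer
    components with the -/+ donor/acceptor pattern, three decay components
    (negative Qy bleach, far-red amplitude growing with lifetime)."""
    return np.array([
        -1.00 * _gauss(wl, 646, 12) + 0.80 * _gauss(wl, 677, 12),
        -0.55 * _gauss(wl, 652, 11) - 0.35 * _gauss(wl, 672, 11) + 0.80 * _gauss(wl, 694, 15),
        -0.30 * _gauss(wl, 644, 11) - 0.40 * _gauss(wl, 675, 11) + 0.62 * _gauss(wl, 706, 17),
        -0.55 * _gauss(wl, 680, 14) - 0.18 * _gauss(wl, 705, 18),
        -0.45 * _gauss(wl, 682, 14) - 0.33 * _gauss(wl, 710, 20),
        -0.40 * _gauss(wl, 683, 14) - 0.48 * _gauss(wl, 715, 22),
    ])


def _ta_times(t_max=3500.0, t_lin=1.0, dt_lin=0.04, n_log=90):
    lin = np.arange(-1.0, t_lin, dt_lin)
    log = np.geomspace(t_lin, t_max, n_log)
    return np.unique(np.concatenate([lin, log]))


def make_fixture(name: str, seed: int = 0, **overrides) -> FixtureBundle:
    """Build a named fixture; see :data:`FIXTURE_NAMES`.

    Overrides: ``peak_counts`` (TCSPC), ``fraction_f`` and ``noise_frac``
    (TA mixture).
    """
    if name == "lhca4_ab_tcspc":
        # 12 ps transfer (+/- DAS), main decays 0.19/0.87/2.1 ns with area
        # ratio 48:34:18, small 3.8 ns disconnected-Chl component
        return _tcspc_fixture(
            name, seed, overrides.get("peak_counts", 2e4),
            [12.0, 190.0, 870.0, 2100.0, 3800.0],
            {
                0: [(676, 20, 0.45), (718, 26, -0.12)],
                1: [(690, 26, 1.0)],
                2: [(700, 28, 1.0)],
                3: [(715, 32, 1.0)],
                4: [(680, 22, 0.04)],
            },
            (0.48, 0.34, 0.18),
        )
    if name == "lhca4_abd_tcspc":
        return _tcspc_fixture(
            name, seed, overrides.get("peak_counts", 2e4),
            [11.0, 200.0, 900.0, 2100.0, 3500.0],
            {
                0: [(680, 20, 0.45), (705, 24, -0.07), (735, 24, -0.05)],
                1: [(702, 26, 1.0)],
                2: [(712, 28, 1.0)],
                3: [(728, 36, 1.0)],
                4: [(678, 22, 0.04)],
            },
            (0.50, 0.33, 0.17),
        )
    if name == "lhca4_abf_tcspc":
        return _tcspc_fixture(
            name, seed, overrides.get("peak_counts", 2e4),
            [12.0, 190.0, 870.0, 2000.0, 3800.0],
            {
                0: [(676, 20, 0.45), (722, 24, -0.12)],
                1: [(692, 26, 0.85), (722, 20, 0.15)],
                2: [(702, 28, 0.85), (724, 20, 0.15)],
                3: [(716, 32, 1.0)],
                4: [(680, 22, 0.04)],
            },
            (0.47, 0.34, 0.18),
        )
    if name == "lhca4_ab_ta":
        wl = np.arange(630.0, 762.0, 2.0)
        times = _ta_times()
        lifetimes = np.array([0.525, 2.19, 6.67, 43.4, 671.0, 2530.0])
        dads = _ta_dads(wl)
        dset = DASet(lifetimes, dads, wl)
        irf = IRFModel.gaussian(TA_IRF_FWHM_PS)
        noise = {"kind": "gaussian",
                 "sigma_frac": overrides.get("noise_frac", 0.003)}
        surface = simulate_das_surface(dset, irf, times, noise=noise, seed=seed,
                                       modality="ta_delta_od")
        return FixtureBundle(name, surface, {
            "lifetimes_ps": lifetimes, "das": dset, "irf": irf,
            "eads": das_to_eads(dset),
        })
    if name == "lhca4_abf_ta_mixture":
        wl = np.arange(630.0, 762.0, 2.0)
        times = _ta_times(t_max=300.0, dt_lin=0.02, n_log=70)
        f = overrides.get("fraction_f", 0.67)
        irf = IRFModel.gaussian(TA_IRF_FWHM_PS)
        # fixed branch: the sequential-scheme equivalent of the ab complex
        ab = DASet(np.array([0.525, 2.19, 6.67, 43.4, 671.0, 2530.0]),
                   _ta_dads(wl), wl)
        eads = das_to_eads(ab)
        fixed_scheme = KineticScheme.sequential(eads.rates)
        fixed_sads = eads.spectra
        # free branch: four-compartment chain of the Chl-f population
        free_lifetimes = np.array([0.605, 4.17, 18.7, 500.0])
        free_scheme = KineticScheme.sequential(1.0 / free_lifetimes)
        free_sads = np.array([
            -1.00 * _gauss(wl, 646, 12) - 0.40 * _gauss(wl, 678, 12),
            -0.50 * _gauss(wl, 653, 11) - 0.80 * _gauss(wl, 678, 12) - 0.30 * _gauss(wl, 725, 14),
            -0.30 * _gauss(wl, 678, 12) - 0.80 * _gauss(wl, 725, 14),
            -0.15 * _gauss(wl, 680, 12) - 0.85 * _gauss(wl, 725, 14),
        ])
        # the equal-area constraint of the target model is a property of the
        # ensemble (equal time-zero oscillator strength per complex): enforce
        # it in the generation truth
        a_fix = sads_area(fixed_sads[0], wl, "abs")
        free_sads *= a_fix / sads_area(free_sads[0], wl, "abs")
        clean = (1.0 - f) * simulate_compartmental(
            fixed_scheme, fixed_sads, irf, times, wl).signal
        clean = clean + f * simulate_compartmental(
            free_scheme, free_sads, irf, times, wl).signal
        rng = np.random.default_rng(seed)
        sigma = overrides.get("noise_frac", 0.003) * np.abs(clean).max()
        surface = TimeResolvedSurface(times, wl, clean + rng.normal(0, sigma, clean.shape),
                                      "ta_delta_od")
        return FixtureBundle(name, surface, {
            "fraction_f": f,
            "fixed_scheme": fixed_scheme, "fixed_sads": fixed_sads,
            "free_scheme": free_scheme, "free_sads": free_sads,
            "free_lifetimes_ps": free_lifetimes,
            "irf": irf, "noise_sigma": sigma,
        })
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
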