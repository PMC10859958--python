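# Methods

`chromakin` models and analyses time-resolved optical spectroscopy of
pigment–protein complexes — specifically ensembles of the plant antenna
protein Lhca4 reconstituted with far-red chlorophylls (Chl d, Chl f)
alongside the canonical Chl a/b — together with the steady-state analyses
that accompany such experiments: pigment-extract unmixing, Gaussian band
deconvolution, and 0–0 transition estimation. This note records the models,
the defaults and why they were chosen, and what the synthetic data do and
do not represent.

## Kinetic model and IRF convolution

All time-resolved signals are modeled as first-order compartmental
kinetics driven by an instrument response function (IRF):

    dc/dt = K c + IRF(t) x,     psi(t, lambda) = c(t)^T S(lambda)

where `K` is the rate matrix (off-diagonal transfer rates >= 0, diagonal =
−column sums − loss rates, so total population never grows), `x` the
excitation input vector, and `S` the compartment spectra. Two special cases
cover the analyses:

* **Parallel (global) model.** `K` diagonal; the spectra are
  decay-associated spectra (DAS for fluorescence, DADS for transient
  absorption) and psi is a sum of IRF-convolved exponentials.
* **Sequential model.** A unidirectional chain with rates sorted fastest
  first; its spectra are evolution-associated spectra (EADS). The linear
  map between DAS and EADS is the Bateman amplitude matrix of the chain,
  implemented as a triangular solve, so `das_to_eads`/`eads_to_das` are an
  exact inverse pair (verified by resimulation to <1e-9).

Concentrations are computed by eigen-decomposition of `K`: each eigenmode
is an IRF-convolved exponential. Defective or complex-spectrum rate
matrices (e.g. repeated rates in a chain) fall back to LSODA integration
of the driven ODE, with a warning. Time is picoseconds everywhere
internally (the problems span ~100 fs IRFs to ~4 ns decays without
exponent extremes); nanoseconds appear only in reporting.

The exponential ⊗ Gaussian convolution uses the analytic form

    c(t) = 1/2 · exp(−x²/2) · erfcx(z),   x = (t−t0)/σ,  z = (kσ − x)/√2

with a second branch `1/2·exp(k²σ²/2 − k(t−t0))·erfc(z)` for z < 0, where
the exponent is provably negative. This is overflow-safe for every (t, k,
σ); it matches adaptive quadrature at machine precision and Simpson-rule
convolution below 1e-7. A *measured* IRF is a non-negative, unit-area trace
on a uniform grid; its convolution with an exponential is the discrete
quadrature `exp(−kt)·cumsum(irf·exp(ks))·ds`, evaluated with a cumulative
sum (O(n) per rate, with a direct masked-sum fallback when `k·span > 500`
would overflow the cumulant). Generator and fitter share this operator, so
the sampled trace *is* the model, not an approximation of one. No
dispersion ("chirp") of time zero across wavelength is simulated or
fitted; this is a known limitation for sub-100-fs analyses of broadband
data.

## Global analysis (variable projection)

`GlobalAnalysis` fits lifetimes (and, for transient absorption, a Gaussian
IRF's t0 and fwhm) by trust-region least squares; at every step the
spectra are eliminated by per-wavelength (weighted) linear least squares —
variable projection. Choices that matter:

* **Weights.** TCSPC photon counts are Poisson distributed, so residuals
  are weighted 1/sqrt(max(counts, 1)); ΔOD surfaces are fitted unweighted.
* **Lifetimes are optimized in log space**, which enforces positivity and
  equalizes step sizes across the fs–ns range. They are reported
  ascending; DAS signs are data-determined, no convention is imposed.
* **Fitted IRF width** is bounded to a configurable interval, default
  87–125 fs — the plausible range for the ~0.1 ps pump–probe response
  being emulated.
* Convergence: relative cost tolerance 1e-10, iteration cap 500 × (n+1)
  function evaluations. Two lifetimes within 1% of each other flag the fit
  as degenerate.

Model-order scanning (`select_n_components`) refits at each n, reports
costs and residual singular values, flags "shapeless" spectra (lag-1
autocorrelation below 0.5, i.e. noise-like), and recommends the smallest n
past which the relative cost improvement drops below 2% (configurable).

## Two-branch target analysis

Ensembles reconstituted with Chl f are heterogeneous: a fraction f of
complexes binds Chl f, the rest behaves like the Chl a/b-only complex. The
target model is therefore two *independent* sequential schemes sharing one
IRF:

    model = (1 − f) · [fixed branch] + f · [free branch]

The fixed branch's rates and spectra are pinned to the sequential-scheme
equivalent (EADS) of a prior global fit of the Chl-f-free complex. The
free branch is a four-compartment chain fitted on a window up to 100 ps —
long enough for all energy-transfer steps, short enough that a single
terminal decay suffices. The two branches' *time-zero spectra* (first
SADS) are constrained to equal integrated area, which breaks the f ↔
spectral-amplitude degeneracy and makes f identifiable.

"Area" is interpreted as the wavelength integral of the **absolute value**
(difference spectra are bleach-dominated and negative); a signed-integral
mode is available. The absolute-value equality admits an exact KKT
solution: the constrained first SADS is a soft-threshold shrinkage of the
unconstrained solution, with the scalar multiplier located analytically on
the piecewise-linear, monotone area-vs-multiplier curve. The constraint is
satisfied to machine precision at every function evaluation; the
remaining nonlinear parameters (logit f, log free rates) are optimized by
bounded least squares with seeded multi-starts (3 by default).

Identifiability hinges on the generation-side assumption that both
subpopulations have equal time-zero oscillator strength — the synthetic
mixture enforces it, mirroring the physical argument that each complex
bleaches the same number of pigments at t = 0. On noiseless mixtures the
fraction is recovered to <1e-3; at 0.3% rms noise the free branch can
absorb a little noise, so a fitted f of ~0.01–0.02 on a pure fixed-branch
surface is the expected noise floor, not a bug.

## Synthetic data and fixtures

The generator (`kinetics` + `fixtures`) emulates the study conditions:

* **TCSPC fixtures** (`lhca4_ab_tcspc` and abd/abf variants): 670–780 nm
  in 5 nm steps, 4 ps channels from −0.4 to 13 ns, a measured-style
  slightly asymmetric IRF of 92 ps fwhm, peak 2×10⁴ counts, Poisson noise.
  The ab truth lifetimes are {0.012, 0.19, 0.87, 2.1, 3.8} ns with the
  three main decay DAS areas in the ratio 48:34:18; the 12 ps component
  carries the +/− donor/acceptor transfer signature and the small 3.8 ns
  component represents disconnected chlorophylls. The wavelength grid and
  peak counts are package choices (they are not dictated by the physics);
  DAS band positions/widths are Gaussian fixture choices at the reported
  band maxima.
* **TA fixtures**: 630–760 nm in 2 nm steps, linear-then-logarithmic delay
  grid (delay-stage practice), Gaussian IRF 0.1 ps, Gaussian ΔOD noise of
  0.3% of peak. Six DADS with lifetimes {0.525, 2.19, 6.67, 43.4, 671,
  2530} ps; the three transfer components have the −/+ sign structure, the
  three decay components are negative with far-red amplitude growing with
  lifetime. The mixture fixture combines this branch's EADS (fraction
  1 − f) with a four-compartment Chl-f branch ({0.605, 4.17, 18.7, 500}
  ps) at f = 0.67, first-SADS areas equalized as described above.

What the fixtures deliberately do **not** reproduce: detector
afterpulsing and background, annihilation, polarization/anisotropy,
coherent artifacts around time zero, wavelength-dependent chirp, and
scattering contamination. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise models, not
robustness to every artifact of real data.

## Pigment unmixing

An 80%-acetone extract spectrum is decomposed against per-pigment
reference spectra by **non-negative** least squares (concentrations cannot
be negative; the constraint also regularizes the overlapping Qy bands).
The default fit window is 600–750 nm, where the chlorophyll Qy structure
discriminates the species; carotenoids absorb only in the blue, so any fit
that should determine the Chl/Car ratio must extend the window below
~520 nm — with a Qy-only window the carotenoid column has no support and
the fit raises a conditioning error naming it. Chlorophyll coefficients
are normalized to 12 Chls per complex (the binding capacity of a
monomeric antenna), carotenoids scaled by the same factor; ratios are
plain quotients, reported at one decimal (two for a/d, matching the
conventional precision). The bundled synthetic basis uses 2–3 Gaussians
per pigment with in-solvent Qy maxima (a 663, b 646, d 688, f 707 nm) and
Qy areas locked to the relative oscillator strengths 1.0:0.67:1.20:1.34;
it is a labelled synthetic stand-in, not measured data. No baseline/offset
term is included (extracts are assumed scatter-corrected upstream); this
is configurable territory left out deliberately.

## Gaussian deconvolution

Absorption bands are fitted as sums of Gaussians **in the wavenumber
domain**, where electronic line shapes are conventionally Gaussian;
centers and widths are converted to nm via Δλ = λ²Δν/10⁷ for comparison
with wavelength-scale reports. Initialization is greedy: bands are added
one at a time at the largest residual of the partial model, refitting at
every order — this also guarantees that the residual never increases with
n under nested initialization. Five jittered multi-starts (seeded) guard
against remaining local minima. Bounds: centers inside the fit window,
fwhm in [20, 800] cm⁻¹. Fits whose bands coincide (centers closer than a
quarter of their mean fwhm) or carry no area raise a `ConditioningWarning`
rather than an exception; non-convergence is flagged on the result.

## Steady-state conventions

* Wavelengths are vacuum nm; wavenumbers 1e7/λ cm⁻¹; no air/vacuum
  correction (none is warranted at the quoted precision).
* kB = 0.6950 cm⁻¹ K⁻¹; "room temperature" defaults to 298 K.
* The 0–0 transition is the crossing of the **unit-maximum-normalized**
  absorption and emission spectra, searched between the two band maxima
  and located by linear interpolation between bracketing grid points.
  Max-normalization is a package decision (it makes the crossing
  independent of acquisition units); an area-normalized convention would
  shift the crossing slightly and is not offered, to keep one documented
  convention. Multiple crossings return the bluest with a warning.
* All band areas are trapezoidal; all interpolation linear (no spline
  overshoot at band edges).
* Excitation density is N_Chl × 1/2 × ΔOD_max/OD_max, the standard
  singlet-excitation estimate for a pump–probe measurement on an N_Chl
  pigment complex.

## Problem sizes and determinism

Recovery statements in the test suite use 25-seed ensembles for the TCSPC
lifetime and Chl-f fraction checks, 200 draws for unmixing and 100 runs
for deconvolution — sizes chosen to make medians stable while keeping the
whole suite around a quarter of a minute. Every stochastic path takes an
explicit seed (fixtures, multi-starts, noise draws); identical seeds give
bit-identical surfaces and byte-identical pipeline reports.

## Known limitations

* No error bars on fitted lifetimes or f beyond seed-ensemble spread; the
  full covariance of the variable-projection problem is not propagated.
* Target models are restricted to two unidirectional chains — no
  back-transfer, equilibria or general graph schemes.
* The measured-IRF convolution assumes a uniform IRF grid.
* Gaussian (not Voigt/skewed) line shapes only, in deconvolution and in
  all synthetic spectra.
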