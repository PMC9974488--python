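# Methods

This note records the models the package implements, the defaults and why,
what the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Binding models

**Ratiometric isotherm.** The sensor's emission ratio follows a strictly
hyperbolic response `R(c) = R_min + (R_max − R_min)/(1 + c50/c)`; c50 is the
concentration of half-maximal ratio change, an operational constant of the
tethered-ligand competition, not a thermodynamic Kd.  No Hill-coefficient
extension is offered: the competition mechanism predicts a hyperbola and the
model is kept as stated.  Zero-concentration points are retained and
evaluated through the c → 0 limit (R = R_min) rather than dropped.

Fits are unweighted nonlinear least squares (Levenberg–Marquardt) on pooled
replicate points; optional per-point weights are accepted.  Replicate-s.d.
weighting is deliberately not the default because plate-reader titrations in
this package's scope carry few replicates (default 3) and the noise is
signal-proportional, making pooled unweighted fitting the more robust
choice.  Starting values are deterministic and data-driven: R_min/R_max from
the 5th/95th percentiles of the observed ratios oriented by the response
direction, c50 from the concentration whose ratio is nearest the midpoint.
c50 (and Kd, below) are log-parameterized internally, which enforces
positivity without active bounds, and reported on the linear scale with
delta-method standard errors from the Jacobian-based covariance at the
optimum (no bootstrap).  A fitted c50 more than 10× outside the sampled
concentration range raises an "extrapolated" warning; a flat response is
flagged unidentifiable instead of failing.

**Fluorescence polarization.** FP = (I∥ − G·I⊥)/(I∥ + G·I⊥) with grating
factor G.  Direct binding of a labeled tracer at total concentration [L]
(default 0.05 µM) uses the exact ligand-depletion quadratic: the bound
fraction solves the mass balance at total tracer and protein, so the fit is
valid even when [L] is comparable to Kd.  When [L]/Kd ≤ 0.01 the quadratic
reduces to the non-depleting hyperbola (verified as a closed-form limit
test).  Competition series are fitted with the same hyperbola in the
competitor concentration for (FP0, FPs, c50); no correction for incomplete
tracer binding at the working protein concentration is applied — the model
is used exactly as stated.

## Sensitized-emission imaging

Per pixel, `netFRET = (I_F − BT_d·I_D − BT_a·I_A)/√(I_D·I_A)`.  Bleedthrough
factors are the median FRET-to-source channel intensity ratio over pixels
whose background-corrected source intensity exceeds the floor; the median
resists hot pixels, and an additive camera background would otherwise bias
the ratio upward, so the per-channel background (image median — valid while
cells cover well under half the field) is subtracted first.  Constant
(intensity-independent) bleedthrough factors are assumed throughout.

Invalid pixels — where the donor·acceptor product does not clear the floor —
are masked and excluded from ROI means, never clipped or set to NaN.  The
default floor in the FOV workflow is three Poisson standard deviations of
the estimated background.  Background subtraction in the net-FRET
computation itself is available (`background=` argument) and is used by the
FOV workflow; the low-level function defaults to off so the formula can be
applied verbatim.

Cells are segmented on the donor channel with an Otsu threshold and
8-connected components, dropping components under 50 pixels.  Normalization:
`normalized FRET = netFRET_control/netFRET_probe × 100%` with the fully-open
control probe in the numerator is the default orientation; the inverted
ratio (probe normalized against the open control) is available behind an
explicit flag, since both formulations circulate and they are reciprocal.
With the default orientation, rising analyte (falling sensitized emission)
raises the normalized value.

The statistical unit is the field of view: condition comparisons take
FOV-level means (≥2 per group), report 100·(mean_cond − mean_ctrl)/mean_ctrl
with a first-order (delta-method) s.e.m., and use the two-tailed unpaired
Student t-test.  Degenerate (zero-variance) groups yield p = NaN with a
warning rather than an error.

## FLIM

TCSPC histograms (default 256 uniform bins over a 25 ns window, i.e. one
40 MHz pulse period) are fitted with `I(t) = Σ Aᵢ exp(−t/τᵢ) + B` by Poisson
maximum likelihood — correct at low counts, where Gaussian weighting is
biased; Neyman-weighted least squares is available as an option.  The model
is evaluated at bin centers on absolute time.  Without an instrument
response function the fit is a tail fit starting at the peak bin; a measured
IRF on the same bins can be convolved numerically (reconvolution).  The
non-negative offset B is fitted by default but can be disabled when the
acquisition is known to be background-free.  Optimization runs L-BFGS-B on
log-amplitudes and log-lifetimes, followed by a Nelder–Mead polish; on
noiseless data the generating parameters are recovered to better than 1e-4
relative.  Components whose lifetimes collapse within a factor 1.2 are
merged with a warning (they are not separately identifiable).  Fit quality
is the reduced Pearson chi-square; the quality bound used throughout is
χ²_red < 1.2.

The amplitude-weighted mean lifetime is τ = Σαᵢτᵢ/Σαᵢ — the normalized form,
bounded by the component lifetimes and invariant to rescaling all
amplitudes.  (The unnormalized variant sometimes written without the sum in
the denominator is dimensionally inconsistent and is treated as a slip, not
implemented.)  All fitted components enter the mean; no assignment of
individual components to FRET/non-FRET populations is attempted.

FRET efficiency is E = 1 − τ_FRET/τ_D against the donor-only (unquenched)
lifetime; negative values are reported, not clipped, so systematic
calibration errors stay visible.  The calibration fits
`E(c) = E_min + (E_max − E_min)/(1 + c50/c)` to per-concentration
efficiencies from an in vitro lifetime titration (≥5 concentrations spanning
c50), and concentrations invert algebraically as
`c = c50·(E − E_min)/(E_max − E)`.  Because the inverse diverges at E_max,
estimates at or beyond the calibrated range are flagged (below-range → 0,
saturated → no value) instead of extrapolated.  A caveat inherent to the
approach: an in vitro calibration is transferred to cells, so any
intracellular shift of c50 propagates directly into the absolute values;
alternative calibrations can be supplied as data.

## Labeling efficiency

`LE(%) = 100·(1 − (S_A488/S_SiR)/(C_A488/C_SiR))` from background-corrected
band intensities (background correction happens upstream in gel
densitometry, outside this package's scope).  Noise can push LE outside
[0, 100]; such values are flagged, not clamped.  Time-course plateaus are
detected as the earliest point after which all consecutive relative changes
stay below 2%.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the experimental designs the pipeline targets, with
the truth injected, never mechanistically simulated:

* Titrations: 12 log-spaced concentrations from 0.0128 to 1000 µM, 3
  replicates, multiplicative Gaussian ratio noise of 1% — plate-reader noise
  is signal-proportional.  Sensor variants (R_min = 1, R_max = 2.8, c50 =
  13.9 / 58.9 / 957 / 2.4 µM for G41 / G41S / G41N / V97T) span the
  micromolar-to-millimolar response range.
* FP: tracer 0.05 µM, Kd 1.2 µM, FP 0.05 (free) to 0.30 (bound), Gaussian
  noise of 0.002 FP (2 mFP), competitor ladder 0.064–5000 µM.
* Imaging: 512×512 FOVs (pixel 0.379 µm), 55 non-overlapping disc cells of
  radius 5–9 px, per-cell acceptor amplitude U(200, 400) counts, donor set
  through the variant's emission-ratio isotherm, FRET channel composed as
  true sensitized emission (net-FRET level interpolating 0.8 closed → 0.2
  open along the binding hyperbola) plus bleedthrough 0.15/0.10, constant
  background 20 counts, Poisson shot noise in every channel.
* Decays: multinomial sampling of the binned model at 10³–10⁶ photons; FRET
  samples are a two-population mixture (quenched 0.8 ns, unquenched 2.6 ns)
  whose amplitude-weighted lifetime follows the calibration hyperbola
  (E_min = 0.05, E_max = 0.45) — matching the direction of the
  concentration-inversion formula, in which efficiency rises with analyte.

Real data differ in ways the generators deliberately ignore: cells are not
discs and overlap, illumination is not flat, bleedthrough can be
intensity-dependent, decays carry an instrument response and afterpulsing
background, and biology supplies no ground truth.  Passing tests therefore
demonstrate that the *computational chain* is correct and unbiased under its
stated noise models — not that any particular biological measurement is
accurate.

The disc placement uses bounded rejection sampling; identical scenario and
seed reproduce outputs exactly.

## Benchmark designs and problem sizes

The recovery benchmarks run at the sizes the workflows target: 500-replicate
titration ensembles, 100-replicate FP and decay ensembles, 6 FOVs per
imaging condition, 10⁶ photons per quantified decay.  The test suite runs
its end-to-end imaging check on 256×256 FOVs with 25 cells — the statistics
are per-cell and per-FOV, so the FOV raster size only sets the cell count —
while the analysis drivers and the acceptance script use the full 512×512 /
55-cell geometry.  The two-component decay benchmark (0.8/3.0 ns) assigns
equal photon fractions to both components (pre-exponential amplitudes
proportional to 1/τ), the balanced design for an identifiability benchmark,
and fits the matched no-offset model; its estimator tracks the Cramér–Rao
bound (≈1.4% relative s.d. for the short lifetime at 10⁵ photons).

## Known limitations

* No spectral unmixing beyond the two constant bleedthrough terms; no
  flat-field correction; no cell tracking.
* ROI-summed decays only — no pixel-wise lifetime maps, no phasor analysis.
* The competition c50 is an operational quantity; converting it to a true
  affinity would require the tethered-ligand equilibrium model, which is out
  of scope.
* CSV/TIFF interchange only; vendor microscope formats are not read.
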