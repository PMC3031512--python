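# Methods

## The model

The package analyses the nuclear accumulation of a hormone-inducible
reporter (a glucocorticoid-receptor–GFP fusion) in embryonic tissue
explants stimulated with dexamethasone (DEX) delivered through a laminar
co-flow microchannel. The measured quantity per cell is the
nuclear-to-cytoplasm fluorescence intensity ratio R(t); normalized to its
pre-stimulus value and shifted to the origin it becomes the *normalized
intensity-ratio differential*

    y(t) = R(t)/R(0) − 1,

which is modelled as a single first-order stage

    τ · dy/dt + y = K · C(t),      y(0) = 0,

with C(t) the DEX concentration seen by the cell's region (µM), τ the
transport time constant (min) and K the steady-state gain (per µM). The
assumptions inherited from this formulation:

* **Symmetric transport.** One τ governs both the rise under stimulation
  and the relaxation after wash-out. Real reporter export is far slower
  than import (half-times of hours), so simulated wash-out decays are a
  model idealization; an optional distinct export time constant is
  accepted by `TranslocationModel(tau_export=...)` but defaults to τ.
* **No photobleaching term.**
* **Linearity.** The response to a·C(t) is a times the response to C(t),
  and the steady state under a fast square wave equals the duty-weighted
  mean input — the source of the "50% duty cycle looks like 50%
  concentration" behaviour.

In the frequency domain the model is the low-pass filter
G(s) = K/(τs + 1). Two corner-frequency labellings are computed side by
side rather than silently choosing one: the standard −3 dB frequency
1/(2πτ) cycle/min, and a convention that reads ω_c = 1/τ directly in
cycle/min (0.060 cycle/min, i.e. 16.6 min/cycle, at τ = 16.6 min), with a
matching transfer-magnitude mode that uses fτ in place of 2πfτ. The
`transfer_magnitude` and `corner_frequency` APIs take an explicit
`convention` argument.

## Simulation

Stimulation profiles are piecewise constant (square waves defined by
period, duty cycle and amplitude; intervals are right-open, profiles start
in the ON phase). Because the input is piecewise constant the ODE has an
exact per-interval solution,

    y(t₀+Δ) = K·C_i + (y(t₀) − K·C_i)·e^(−Δ/τ),

and `simulate()` uses only this exponential update: results are
deterministic and step-size free. A fixed-step RK4 integrator exists in
the test suite as an independent oracle (agreement to 1e−6 relative is
asserted); it is never used by library code. The closed-form limit-cycle
ripple of a square-wave response,
K·C₀(1−e^(−dT/τ))(1−e^(−(1−d)T/τ))/(1−e^(−T/τ)), is exposed as
`steady_state_ripple` and checked against long simulations.

## Fitting

The two-step estimator mirrors the classical continuous-stimulation
procedure:

1. **Gain**: K̂ = max(y)/C. On a noiseless record truncated at t_max this
   is biased low by the factor (1 − e^(−t_max/τ)); on noisy records the
   max inflates it slightly. Both effects are documented rather than
   corrected, since the estimator is part of the procedure being
   reproduced.
2. **Time constant**: the linearized response z(t) = −ln(1 − y/(K̂C)) is
   regressed on t through the origin; τ̂ = 1/slope. Points at or above the
   estimated steady state (1 − y/(K̂C) ≤ 0) are excluded, not clipped —
   clipping biases the slope.

**Weighting.** The log transform amplifies additive noise without bound as
y approaches the steady state: noise of variance s² on y becomes variance
s²/(1 − y/(K̂C))² on z. The default regression therefore uses
inverse-variance weights (1 − y/(K̂C))², the delta-method weighting that
restores homoscedasticity; the reported R² (0–100 scale) is the weighted
R² of that regression. An unweighted mode (`weighted=False`) is provided.
On noiseless data the linearization is exact, so any weighting recovers
the generating parameters to machine precision — the weighting matters
only for noisy records, where simulation shows the unweighted
through-origin slope is dominated by the ill-conditioned near-saturation
points and substantially overestimates τ. A second R² on the original y
scale is emitted alongside (`r_squared_original`).

Cells are pooled by averaging y per time point before fitting (one curve
per cohort); per-cell fits remain possible by fitting traces
individually. `fit_nonlinear` cross-checks the two-step procedure with a
direct Levenberg–Marquardt fit of (τ, K) in log-parameter space against
the exact simulation under an arbitrary profile — this also demonstrates
that (τ, K) are identifiable from periodic-stimulation data alone.

## Quantification and statistics

`project_stack` collapses a confocal z-stack by per-pixel maximum (a mean
mode is available behind a flag); maxima preserve in-focus nuclear signal
against defocused planes. `intensity_ratio` is the ratio of mean
intensity over a nuclear mask to mean intensity over a cytoplasmic mask —
a ratio of means, invariant to global illumination scaling. Masks are
inputs: segmentation is out of scope, and the synthetic renderer emits
ground-truth masks. Whether one should use mean or integrated intensities
per compartment is a convention; mean is used here.

Region comparisons use the two-sided Mann-Whitney U test: exact null
enumeration when both samples have ≤ 8 observations and no ties,
otherwise the tie-corrected normal approximation, significance flagged at
α = 0.01. Region summaries report the sample SD (n−1 denominator) and
flag n = 1 groups with SD = 0.

## Synthetic data

The generator emulates the live-imaging study design — 3 explants × 10
cells, 10-min sampling, defaults over 120 min (the four-profile
experiment in `pipeline` defaults to 60 min, since both durations occur
in practice), 25 µM amplitude — with:

* log-normal per-cell heterogeneity in τ (mean 16.6 min, CV 20%),
  steady-state response amplitude (mean 1.0, CV 20%) and baseline ratio
  (mean 1.0, CV 5%) — log-normal being the minimal positive-support
  choice when only SD error bars are known; the CVs are free parameters,
  not claims about real tissue;
* additive Gaussian measurement noise on R (SD = 5% of the population
  steady-state response) at the trace level;
* a 5% fraction of "spontaneous translocators": cells constitutively
  nuclear from t = 0, independent of the stimulus (elevated baseline, not
  stimulus leakage). After per-cell normalization these contribute flat
  traces, diluting cohort amplitude but not the fitted time constant.

With variability, noise and spontaneous cells switched off, the generator
reduces exactly to the model — it contains no structure the model cannot
represent, which is what makes noiseless round-trip recovery to 1e−6 a
meaningful consistency check and what limits what passing tests say about
real tissue: the generator does not emulate cell movement, division,
explant spreading, photobleaching, asymmetric export kinetics, or
segmentation error, so recovery results bound estimator behaviour only
under the stated noise model.

The image renderer lays cells out as discs with concentric disc nuclei,
renders a z-stack with distance-proportional Gaussian defocus on
off-centre slices and Poisson–Gaussian pixel noise (shot noise at a
configurable photon gain). The emitted cytoplasmic masks keep a 3-pixel
guard ring off the nuclear envelope — the usual translocation-assay
precaution against defocus spill-over into the denominator; without it,
max-projection quantification underestimates high ratios by several
percent.

## Microchannel characterization

Closed-form, empty-channel approximations stand in for finite-element
flow simulation: mean velocity Q/(wh); Reynolds number on the hydraulic
diameter 4wh/2(w+h); Peclet number with the channel width as the default
characteristic length (the scale governing cross-stream interface
integrity; height or hydraulic diameter can be passed instead); bottom-wall
shear 6Q/(wh²) (parallel-plate form, adequate at w/h = 5);
rectangular-duct resistance 12µL/(wh³(1 − 0.63h/w)), within ~13% of the
exact series even in the worst (square) case; and interface blurring from
the 1D depth-averaged solution C(y) = ½·erfc(y/(2√(Dx/U))), reported as
the full width between the 10%-mass-fraction crossings. The 1D
depth-averaged width is wider than a mid-plane 3D value because it
averages the slow near-wall fluid, and the explant's obstruction of the
channel is not modelled; these numbers bound the regime, they do not
replace a 3D solver. Defaults: water (ρ = 1000 kg/m³, µ = 1.0e−3 Pa·s),
D = 2.2e−10 m²/s, main channel 1500 × 300 µm × 10 mm, 30 µl/min.

## Numerical choices and degenerate inputs

* Interval convention: right-open [tᵢ, tᵢ₊₁); sampling at the total
  duration returns the final level. Duty 0 or 1 degenerates to a constant
  profile.
* Nonlinear fit: deterministic, initialized from the log-linear estimate
  (no random restarts); non-convergence raises a distinct error carrying
  solver diagnostics.
* Degenerate data raise typed signals rather than returning NaN: all-zero
  traces (degenerate fit), saturated traces (insufficient data after
  exclusion), zero-variance series (undefined statistic), empty masks or
  overlapping masks (invalid argument).
* All generator randomness flows from one integer seed
  (`numpy.random.default_rng`); the pipeline spawns per-cohort seeds from
  the top-level seed via `SeedSequence`, so reports regenerate
  bit-for-bit.

## Problem sizes

The recovery experiment reported by `scripts/acceptance.py` uses 200
seeded cohorts of 30 cells at 13 time points; the renderer round-trip
tests use 100 cells across 5 frames; rank-test enumeration covers sample
pairs up to 10 pooled observations. These sizes give stable medians while
keeping the whole suite fast on a single CPU.

## Known limitations

* The half-time reported from a fitted τ is τ·ln 2 (≈ 11.5 min at
  τ = 16.6), a definitional quantity; observational half-time estimates
  on real data can differ and no reconciliation is attempted.
* The max-based gain estimator is not consistent on finite noisy records;
  it is retained because it is the procedure under study, with the
  nonlinear route as the corrective cross-check.
* The 2 kPa-class inlet-pressure prediction of a full device requires the
  tubing network, which is not modelled; `series_resistance` covers only
  stated channel segments.
* CS-region interface repositioning transients are idealized away:
  profiles are perfect square waves.
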