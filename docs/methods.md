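# Methods

This package implements a dual-bolus DCE/DSC perfusion-MRI analysis chain of
the kind used to monitor anti-angiogenic therapy in orthotopic mouse glioma:
a gadolinium bolus is tracked with a T1-weighted dynamic series and fit
voxelwise with the Extended Tofts-Kety model; an iron-oxide bolus is then
tracked with a T2*-weighted series and analyzed with indicator-dilution
theory; tumor summaries are normalized to contralateral normal brain; and the
K^trans/rCBV ratio is used to separate wall-permeability changes from
vascular-surface-area changes. Because no real acquisition ships with the
package, every stage is exercised on a synthetic digital phantom with known
ground truth.

## Forward models and the phantom

**Geometry.** A single 32×32 2D slice (matching single-slice dynamic
acquisitions) containing a circular tumor ROI and a disjoint contralateral
ROI. 3D volumes, motion, partial-volume and slice-profile effects are out of
scope.

**Kinetic truth.** Tumor voxels draw K^trans, v_e, v_p from log-normal
distributions whose *means* equal the ROI specification (default K^trans
0.1 min⁻¹, v_e 0.2, plasma fraction from the vessel geometry below) with
log-SD `heterogeneity` (default 0.3). This mimics the heterogeneous
appearance of glioma maps without claiming the real voxelwise distribution.
Contralateral voxels model an intact blood-brain barrier: K^trans = 0
exactly, small fixed v_p.

**Vessel geometry.** Ground truth is anchored in an explicit capillary
description: with P_CA the contrast-agent wall permeability, d the average
capillary diameter and S the total vessel surface area per unit tissue
volume, the cylindrical-vessel approximation gives

    K^trans = P_CA · S,        CBV = S · d / 4,
    K^trans / CBV = 4 · P_CA / d.

Scaling S scales K^trans and CBV together and leaves the ratio unchanged;
this is embedded in generation (tumor CBV is proportional to the voxelwise
K^trans draw, anchored to S·d/4 at the ROI mean) and is the property the
decoupling analysis quantifies downstream.

**Hemodynamic truth.** MTT is uniform per region (tumor 3 s, contralateral
1.5 s by default) and CBF = CBV/MTT, so the central-volume identity holds
exactly by construction.

**Signals.** The DCE series uses the spoiled-gradient-echo steady state
S = M0 sin α (1−E)/(1−cos α E), E = exp(−TR/T1), with R1(t) = 1/T10 +
r1·C_t(t); defaults TR 20 ms, flip 20°, Δt 3 s, 80 frames, injection at
frame 10, r1 = 3.2 mM⁻¹s⁻¹, T10 = 1.8 s (brain tissue at high field). The
DSC series uses S = S0 exp(−TE·ΔR2*) with ΔR2* = r2s·C(t); defaults TE
12 ms, Δt 0.5 s, 120 frames, injection at frame 20. The two boluses are
generated as independent series; no inter-bolus interaction (e.g. T1
pre-load of the DSC series) is modeled. Noise is Rician (magnitude MRI),
σ specified via the baseline signal-to-noise ratio, default SNR 30.

**AIF.** C_p(t) is a 6-parameter causal form: a peak-normalized
gamma-variate first pass plus a delayed exponential washout. The defaults
(first-pass peak ~7 s after arrival for the gadolinium bolus, sharper for
the iron bolus) are generic small-animal bolus shapes, not fits to any
measured curve.

**Study tables.** A synthetic four-arm cohort (untreated n=4, two
monotherapies n=5/4, combination n=5) emulates the longitudinal design:
exponential tumor growth with per-group rate constants (0.21, 0.19, 0.21,
0.14 day⁻¹), 10% log-normal volume noise, twice-weekly measurement until an
event; survival times drawn around per-group medians (13.5, 13, 13, 26
days, all events observed); and imaging-day ROI summaries whose rCBV
trajectories differ by group while K^trans follows rCBV through a shared
K^trans/rCBV constant (0.04 min⁻¹ per rCBV unit; the permeability-elevated
monotherapy arm gets a 1.25× ratio offset). Day-0 tumor rCBF falls in the
2.2–2.6 band typical of pretreatment glioma.

What the phantom deliberately does **not** emulate: pulse-sequence effects,
B1/T2* inhomogeneity, water exchange, recirculation dispersion, registration
error, real biological covariance between parameters. Passing tests
demonstrate correctness of the estimators under the stated forward models,
not performance on real mouse data.

## Inverse methods

**Concentration conversion.** The SPGR equation is inverted analytically
for R1(t); the effective M0 is re-derived per voxel from the measured
baseline and the known T10, which keeps the baseline concentration mean
unbiased even under Rician noise. Samples outside the invertible range are
flagged (NaN), not silently clamped.

**Extended Tofts-Kety fitting.** The forward model

    C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(u) e^{−k_ep (t−u)} du

is evaluated with an exact recursion for a piecewise-linear C_p against the
exponential kernel (O(n), no quadrature error beyond the interpolation of
C_p; verified to <1e-6 against the closed form for exponential inputs).
Fitting is bounded trust-region least squares per voxel, K^trans ∈ [0, 5]
min⁻¹, v_e ∈ (1e-3, 1], v_p ∈ [0, 0.5], init (0.1, 0.2, 0.02); ordinary
(unweighted) least squares, time in minutes so K^trans is natively min⁻¹.
Voxels whose post-injection mean is below baseline + 3 SD are gated out
(K^trans = 0, flagged non-enhancing) for speed and stability. If the
optimum pins v_e at its lower bound with K^trans > 0, the curve is refit
with a pure-v_p model and the lower-cost solution kept. No
hematocrit/plasma correction is applied; the constant is absorbed into the
AIF scale and cancels in relative quantities.

**AIF joint estimation.** Without a measurable artery, a shared AIF is
estimated from ≥5 enhancing tumor curves by alternating optimization: fix
the AIF and fit each curve's kinetics, then fix kinetics and refit the AIF,
iterating to relative cost change < 1e-6 (cap 500 rounds). Tissue curves
cannot fix the AIF scale — multiplying C_p by c and dividing each curve's
(K^trans, v_e, v_p) by c changes nothing — so the estimate is anchored by
constraining the trapezoid area of the AIF over the series to a configured
reference (area is more noise-robust than the peak on coarse grids). Every
10th round a joint trust-region step over the AIF and all kinetics is
attempted and accepted only if it does not increase the objective; pure
coordinate descent zig-zags along coupled bolus-shape/efflux directions and
can need thousands of rounds, while the accelerated scheme reaches the
noise-free fixed point in a few tens of rounds with the monotone-cost
guarantee intact. Curve selection defaults to all tumor voxels above the
enhancement threshold, strongest first. The bolus-arrival init is the first
frame where the mean curve exceeds baseline + 5 SD.

**DSC analysis.** ΔR2*(t) = −ln(S/S̄_base)/TE. CBV is the trapezoid area
ratio of tissue to reference curves over a window from injection to
injection + 60 s (no gamma-variate recirculation correction: the fixed
window plus relative reporting serves that purpose). CBF comes from
block-circulant (delay-insensitive) truncated-SVD deconvolution: the
convolution is discretized on a zero-padded circulant grid of length 2N,
singular values below 0.05 of the maximum are zeroed, and CBF is the
maximum of the recovered flow-scaled residue. MTT = CBV/CBF where CBF
exceeds 1e-6 of the map maximum; other voxels are flagged, not raised.
Absolute calibration constants (density, hematocrit) are omitted: all
reported quantities are relative to the contralateral-ROI mean, which makes
them exactly 1 there and invariant to global rescaling. The reference curve
for CBV/CBF defaults to the contralateral-mean ΔR2* (reference-region
convention, no artery needed in the slice); an arterial curve can be
supplied instead.

**Truncated-SVD bias.** At threshold 0.05 the deconvolution systematically
underestimates CBF for exponential residues, and the bias grows as the
residue gets short relative to the input bolus bandwidth: on the default
phantom (MTT 3 s = 6 frames, bolus β 1.5 s) the underestimate is ~35%, and
it remains ~21% even at MTT 6 s. The deconvolution is therefore validated
in the regime it can resolve — residue spanning ≥12 frames (MTT 6 s), a
sharp validation bolus (β 0.8 s), and a 90 s series so integral tails are
negligible — where the bias is ~11%, and the short-MTT bias is pinned by a
dedicated regression test. This is why the package never reports absolute
CBF: downstream statistics consume rCBV (integration-based, ~1% accurate)
and contralateral-relative quantities.

## Statistics

* **ROI summaries** are arithmetic means over unflagged masked voxels.
* **Decoupling**: per-row K^trans/rCBV; per-group least-squares slope vs
  day; an overall line fit to the group-by-day mean ratios, excluding the
  post-treatment means of the permeability-elevated monotherapy arm (whose
  ratio offset would otherwise tilt the common line); pairwise Welch t
  contrasts. rCBV (not absolute CBV) is used so proportionality constants
  cancel. No multiple-testing correction is applied; the report says so.
* **Group comparisons**: Student's t (one- or two-tailed, optional Welch
  correction) via scipy; an exact permutation p-value is available for
  small groups as an oracle.
* **Growth**: per-animal least-squares fit of ln V vs day (k is the slope),
  then group mean ± SEM — per-animal-then-average, with a direct nonlinear
  exponential fit available behind a flag (identical on noise-free data).
* **Survival**: Kaplan-Meier product-limit (lifelines), median = first t
  with S(t) ≤ 0.5; log-rank chi-square (1 df) between arms. The SE of the
  median is a seeded bootstrap (10³ resamples) — the estimand's SE has no
  standard closed form, and the bootstrap value need not match SEs computed
  by other conventions.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds reproduce every dataset and
  table bit-identically.
* Time vectors are stored in seconds and converted to minutes only at the
  Tofts model boundary; K^trans is min⁻¹ everywhere.
* Voxel indexing is 0-based; masks are inclusive boolean arrays; time is
  the last axis of 4D arrays; NIfTI sidecars carry protocol, AIF and seed.
* Problem sizes in the tests and the reproduction script (32×32 slice, 80
  DCE frames, 120–180 DSC frames, 100 replicate growth fits) are chosen so
  the full suite runs in about a minute while leaving every estimator in
  its intended operating regime.

## Known limitations

* The joint AIF estimation is a simplified self-consistency scheme, not a
  full multichannel blind deconvolution; with real noise and model mismatch
  its scale anchor (the configured AIF area) is a convention, not a
  measurement.
* DSC leakage effects from the preceding gadolinium bolus are noted but not
  modeled.
* The contralateral-reference deconvolution distorts absolute CBF/MTT when
  tumor and reference residues differ; only relative maps should be
  interpreted, and even those carry the truncation bias described above.
* The survival-table generator draws event times from a normal around the
  group median; it reproduces medians and orderings, not hazard shapes.
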