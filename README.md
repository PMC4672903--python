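# dualbolus

Dual-bolus DCE/DSC perfusion-MRI analysis for preclinical brain-tumor
studies, exercised end-to-end on synthetic digital phantoms with known
ground truth.

Anti-angiogenic therapy trials in orthotopic glioma models monitor the
tumor vasculature with two successive contrast boluses in one session: a
gadolinium bolus tracked by a T1-weighted dynamic series (DCE-MRI), which
quantifies contrast extravasation, and an iron-oxide bolus tracked by a
T2\*-weighted series (DSC-MRI), which quantifies hemodynamics. This package
implements the full analysis chain for that design:

* **Kinetic mapping** — voxelwise Extended Tofts-Kety fits,
  `C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(u) e^{−k_ep(t−u)} du` with
  `k_ep = K^trans/v_e`, on concentrations obtained by inverting the SPGR
  signal equation with an M0-derived precontrast T1.
* **AIF estimation** — a 6-parameter gamma-variate + washout plasma curve
  `C_p(t)`, estimated jointly with per-curve kinetics from measured tumor
  curves by monotone alternating least squares; the inherent scale
  degeneracy is broken by constraining the AIF area.
* **Hemodynamic mapping** — ΔR2\* conversion, CBV by first-pass
  integration, CBF by block-circulant truncated-SVD deconvolution,
  MTT = CBV/CBF, all reported relative to a contralateral normal-brain ROI
  (rCBF, rCBV, rMTT).
* **Permeability/surface-area decoupling** — under the cylindrical-vessel
  approximation `K^trans = P_CA·S` and `CBV = S·d/4`, so
  `K^trans/CBV = 4·P_CA/d`: a ratio that is flat while K^trans moves
  indicates vascularization (S) changes rather than wall-permeability
  changes. The package computes per-animal-day ratios, group trends and
  contrasts.
* **Longitudinal statistics** — exponential tumor-growth rate constants
  (log-linear fits, per animal then group mean ± SEM), Kaplan-Meier
  survival with log-rank tests, and one/two-tailed t tests with optional
  Welch correction.
* **Synthetic phantom** — a first-class generator producing paired DCE+DSC
  series over a 2D slab with a heterogeneous tumor and a contralateral ROI,
  Rician noise, and complete kinetic/hemodynamic/vessel-geometry ground
  truth, plus synthetic four-arm longitudinal study tables.

See `docs/methods.md` for models, defaults, numerical choices and known
limitations (in particular the truncated-SVD CBF bias and why only relative
hemodynamics are reported).

## Worked example

Run the whole chain — phantom, AIF estimation, kinetic and hemodynamic
maps, ROI table, study statistics — into a run directory:

```bash
dualbolus run all --seed 5 --out run/
```

which prints the phantom's tumor-ROI summary:

```json
{
  "mean_ktrans_per_min": 0.09321954872315064,
  "rcbf": 1.7646589582595644,
  "rcbv": 2.633226515030843,
  "rmtt": 1.466574612471874,
  "contra_rcbf": 1.0,
  "contra_rcbv": 1.0000000000000002,
  "contra_rmtt": 0.9999999999999998
}
```

Reading: the fitted tumor K^trans mean, 0.093 min⁻¹, sits within ~5% of the
phantom's generating mean (0.1 min⁻¹) despite SNR-30 Rician noise and a
blindly estimated AIF; tumor blood volume is 2.6× contralateral; the
contralateral means of every relative map are exactly 1 by construction.
The run directory contains the NIfTI series and maps, the protocol/AIF JSON
sidecar, tidy CSV tables (ROI summary, growth, survival, decoupling
ratios), and `report.json` with group growth rates (untreated
0.216 ± 0.003 day⁻¹ vs combination 0.139 ± 0.002 day⁻¹ on the synthetic
cohort), Kaplan-Meier medians (13.2 vs 26.2 days), log-rank p-values, and
the K^trans/rCBV trend (overall slope ≈ −1.3×10⁻⁴ day⁻¹, i.e. essentially
flat — the decoupling signature of surface-area-driven K^trans variation).

The same stages are available piecewise (`dualbolus phantom make`,
`dualbolus aif fit`, `dualbolus dce fit`, `dualbolus dsc run`,
`dualbolus stats roi`, `dualbolus study growth|survival`) and as a Python
API:

```python
from dualbolus import make_phantom, fit_extended_tofts
ds = make_phantom(snr=30.0, seed=42)
```

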