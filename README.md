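# h2opet

Quantitative tumour perfusion from dynamic [¹⁵O]water PET, for imaging
scientists studying the pharmacodynamics of antiangiogenic therapy. The
package implements the full analysis chain of a water-PET perfusion study —
kinetic modelling of dynamic tumour data with an image-derived arterial input
function, FDG-based volume-of-interest (VOI) machinery, metabolic response
criteria, and the cohort statistics — together with a synthetic-data module
that generates every input the chain needs (bolus input functions,
time-activity curves, 4-D phantoms with a tumour and a descending aorta, and
simulated cohorts), plus a packaged seven-patient study table.

## The model

The activity measured in a tumour VOI during a ¹⁵O-water scan is described by
a one-tissue compartment model with an explicit vascular term:

```
M(t) = V₀ · Cₐ(t − Δ) + Mₑ(t),      dMₑ/dt = K₁ Cₐ(t − Δ) − k₂ Mₑ(t)
```

where `Cₐ(t)` is the arterial input (kBq/mL, taken from an aorta VOI),
`K₁` (mL/g/min) is blood perfusion into tissue, `k₂` (1/min) the washout
rate, `V₀` (mL/g) the vascular volume fraction and `Δ` the input delay.
The analytic solution of the tissue state is an exponential convolution,
`Mₑ(t) = K₁ (Cₐ ⊗ e^{−k₂ t})(t)`.

Two estimators are provided:

* **Spectral analysis** — the linearised form
  `M(t) ≈ Σᵢ αᵢ (Cₐ ⊗ e^{−βᵢ t})(t) + V₀ Cₐ(t)` on a fixed grid of rates
  `βᵢ ≥ 0` (including β = 0), solved by non-negative least squares. Perfusion
  is read off as the sum of the spectrum; the weights at fast rates
  (default β ≥ 2/min) are reported separately as vascular-like.
* **Nonlinear fitting** — weighted least squares directly over (K₁, k₂, V₀),
  with inverse-frame-noise weights.

Response assessment uses lean-mass-corrected SUV (SUL): a ≥ 20 % reduction in
all baseline lesions with no new lesions is an overall (partial metabolic)
response, a ≥ 15 % increase in any lesion or any new lesion is progression,
and both kinds coexisting is a mixed response. Cohort comparisons use a
one-sided unequal-variance (Welch) t-test, a one-sample z-test against a
50 ng/mL drug-trough reference, and Pearson correlation with Fisher-z 95 % CIs.

## Worked example

`examples/02_phantom_pipeline.py` simulates a phantom patient (48³ voxels of
4 mm; tumour sphere with K₁ = 0.8 mL/g/min, k₂ = 0.4/min, V₀ = 0.05; aorta
cylinder carrying the bolus; matched FDG volume rigidly shifted by
(2, −1, 0) voxels) and runs the whole chain:

```
registration shift (vox) : [-2, 1, 0]  truth: [-2, 1, 0]
tumour VOI voxels        : 123  truth: 123
estimated delay          : 0 s
spectral tissue perfusion: 0.778 mL/g/min (truth 0.8)
nonlinear K1             : 0.784 mL/g/min
```

The attenuation-based co-registration recovers the constructed inter-study
shift exactly, the 75 %-max FDG threshold reproduces the true lesion, and
both kinetic routes land within a few percent of the generating perfusion at
the default noise level (peak-frame SNR ≈ 10).

`examples/03_cohort_statistics.py` summarises the packaged patient table:

```
perfusion decrease range : 20-85 %
FDG-SUV decrease range   : 29-67 %
metabolic responders     : 6/7
stable disease           : 4 patients, up to 12 cycles
Welch one-sided t-test   : t = -1.926, df = 4.56, p = 0.0588
benefit trough z-test    : z = 4.08, p = 2.3e-05
```

Every patient shows a perfusion drop at week 2; the drop is larger in the
patients with subsequent clinical benefit (p ≈ 0.06, one-sided Welch), and
drug exposure in that group sits clearly above the 50 ng/mL reference.

A thin CLI wraps the same functions (`h2opet simulate | perfusion |
cohort-stats | fixture`); see `h2opet --help`.

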