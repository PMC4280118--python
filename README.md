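# petidif

Image-derived input functions (IDIFs) for dynamic brain PET quantification.

Kinetic quantification of a radioligand such as [18F]-FEPPA, a tracer for
the 18 kDa translocator protein (TSPO, a neuroinflammation marker), needs
the metabolite-corrected arterial plasma concentration Cp(t) — the *input
function*. The gold standard is continuous arterial sampling, which is
invasive, costly, and clinically impractical. `petidif` implements and
compares two ways of reading the whole-blood curve off the dynamic image
instead:

* **CS** — carotid-signal extraction: threshold the early-frame mean image
  at 0.48 x its maximum within the lowest axial planes and average the ten
  hottest pixels per plane, per frame;
* **ICA** — blind unmixing of the whole cranial blood pool: model the
  thresholded blood-pool voxels as a spatial mixture of arterial and venous
  signal, and estimate the demixing by maximum likelihood with an
  **asymmetric Laplace distribution (ALD)** source prior — a sharply
  peaked, skewable density matching blood-ROI voxel histograms.

Both curves are calibrated with a single manual blood sample at 15 min,
repaired for an occasional inversion point near 1.5 min, and
metabolite-corrected via a bi-exponential whole-blood-to-plasma ratio and a
Hill parent-fraction model:

    Cp_parent(t) = C_wb(t) / r(t) * pf(t),    pf(t) = 1 - A t^s/(t^s + h^s).

Regional time-activity curves are then fitted with the two-tissue
compartment model (weighted nonlinear least squares, trues-based frame
weighting, 5% blood volume) to estimate the total distribution volume

    V_T = K1/k2 (1 + k3/k4),

and the two IDIF pipelines are compared against a ground-truth input
function with AUC ratios, linear regression (r², slope, intercept, slope
t-test) and Bland–Altman limits of agreement.

Because no real scan data ship with the package, a synthetic dynamic-PET
phantom (HRRT-like frame schedule, sub-voxel vascular tree with graded
partial volume, 2-TCM tissue, PSF blur, count-scaled noise) provides exact
ground truth for every stage; see `docs/methods.md` for the model details
and known limitations.

## Worked example

```python
import numpy as np
from petidif import (PhantomSpec, generate_phantom, run_pipeline_data,
                     TimeActivityCurve, auc_ratio)

spec = PhantomSpec(seed=42)                      # one synthetic subject
img, truth = generate_phantom(spec)
samples = truth.manual_samples()                 # bedside blood samples
region_tacs = {
    label: TimeActivityCurve(truth.schedule.mid_times,
                             img.voxels[truth.region_masks[label], :].mean(axis=0),
                             label)
    for label in truth.region_params if label != "background"}

result = run_pipeline_data(img, samples, region_tacs, method="ICA")
peak, tail = auc_ratio(result.input_function, truth.input_function)
print(f"peak AUC ratio vs truth: {peak:.3f}   tail: {tail:.3f}")
for label, vt in result.vt.items():
    print(f"{label:11s} V_T = {vt:6.2f}  (truth {truth.region_params[label].vt:6.2f})")
print(result.fits["frontal"].summary())
```

prints

```
peak AUC ratio vs truth: 0.881   tail: 0.986
frontal     V_T =  10.73  (truth  10.62)
temporal    V_T =   6.77  (truth   6.52)
striatum    V_T =   9.49  (truth   9.33)
thalamus    V_T =  13.99  (truth  14.00)
cerebellum  V_T =   6.08  (truth   5.83)
Two-tissue compartment model fit
========================================
frames: 40   weighted SSE: 0.0426108   converged: True
 param     estimate      std err
    K1      0.29132     0.002782
    k2     0.097092     0.002621
    k3     0.059241     0.001478
    k4        0.023    0.0001665
    vb         0.05      (fixed)
V_T = K1/k2 (1 + k3/k4) = 10.73 mL/cm^3
```

The ICA input function matches the truth closely in the tail (ratio 0.99
after one-point calibration) and slightly underestimates the first-pass
peak (0.88, residual venous/tissue spill); the fitted V_T values agree with
the generating kinetics to a few percent.

The same workflow is available from the shell:

```bash
petidif simulate --out sim/ --seed 42
petidif extract-cs  --pet sim/phantom.nii.gz --out cs.tsv
petidif extract-ica --pet sim/phantom.nii.gz --seed 42 --out ica/
petidif build-if --blood cs.tsv --samples sim/samples.tsv --dispersion-tau 0 --out if.tsv
petidif fit-2tcm --tac sim/region_tacs.tsv --if if.tsv --blood cs.tsv --out vt.json
petidif study --subjects 10 --seed 0 --out study.tsv
```

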