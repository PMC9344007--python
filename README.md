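# sersquant

Chemometrics for quantifying pesticide residues (the fungicide thiram on
fruit surfaces) from surface-enhanced Raman spectroscopy (SERS). SERS
readouts are sensitive but messy: fluorescence background, substrate
variability, interfering matrix bands, and a sensing response that is not
always linear in concentration. `sersquant` implements the full desk-side
workflow a spectroscopist needs to turn raw spectra into a validated
calibration:

* **Simulation** — synthetic SERS spectra built from pseudo-Voigt bands,

  `V(ν) = θ·α·exp[−4ln2·(ν−ω)²/γ²] + (1−θ)·α·γ²/((ν−ω)²+γ²)`,

  on a 550–1550 cm⁻¹ axis with a fluorescence baseline and multiplicative
  intensity noise. The default thiram library places bands at 562, 929,
  1146, 1379 and 1514 cm⁻¹ and pins the 1379 cm⁻¹ quantitation band to the
  response `I = 11644·N + 4536.5` (N in μg·mL⁻¹). R6G (substrate
  uniformity) and fruit-epidermis libraries are included.
* **Preprocessing** — replicate averaging, Savitzky–Golay smoothing,
  iterative-polynomial (modpoly) or asymmetric-least-squares baseline
  subtraction, SG derivatives, and feature-range extraction.
* **Sampling** — the deterministic max–min (Kennard–Stone-like)
  calibration/prediction split.
* **Kernel PCA** — RBF kernel `k(x,y) = exp(−‖x−y‖²/2σ²)`, the
  double-centering Gram-matrix correction, Schölkopf-normalised
  eigenvectors (`λ_k·(α_k·α_k) = 1`), out-of-sample projection, explained
  variance, a σ-sweep over RMSECV, and a linear-kernel mode that reduces
  exactly to classical PCA.
* **Regression** — NIPALS PLS1 and MLR, leave-one-out / k-fold RMSECV,
  the peak-height calibration curve with r², limit of detection
  (blank mean + 3·SD via the calibration line) and relative standard
  deviation, plus characteristic-peak detection.

## Worked example

```python
import numpy as np
import sersquant as sq

cfg = sq.thiram_config(seed=1)                      # 1.5% intensity noise
concs = np.geomspace(0.1, 5.0, 20)                  # ug/mL
study = sq.generate_study(cfg, concs, replicates=1)
pre = sq.preprocess_set(study)                      # smooth + baseline
heights = [s.intensity_at(1379.0) for s in pre]
curve = sq.fit_calibration(heights, study.concentrations)
print(curve.slope, curve.intercept, curve.r_squared)
```

prints

```
11444.941802807845 4483.9787030138505 0.9999377600005169
```

i.e. the calibration slope and intercept are recovered to about 1% of the
generating line `I = 11644·N + 4536.5`, with r² ≈ 0.9999 — the noise floor
of a 20-sample series at 1.5% intensity RSD.

The same pipeline runs from the shell. With `pipeline.yaml`

```yaml
library: thiram
generator: {seed: 11}
concentrations: [0.1, 0.5, 1.0, 2.5, 5.0]
replicates: 4
sigma: 8000.0
n_components: 5
method: pls
n_latent: 3
```

`sersquant run --config pipeline.yaml --out-dir out` simulates 20 spectra,
preprocesses them, selects a 15-sample calibration set by max–min,
extracts RBF-KPCA scores at σ = 8000 and cross-validates a 3-LV PLS model,
printing

```json
{
  "rmsecv": 0.2852890373200821,
  "calibration_slope": 11484.322125288925,
  "calibration_intercept": 4491.182981635986,
  "r_squared": 0.9999013990987454,
  "n_calibration": 15,
  "n_prediction": 5
}
```

(RMSECV in μg·mL⁻¹ over the 0.1–5.0 μg·mL⁻¹ range). Individual stages are
also available as `sersquant simulate | preprocess | split | kpca |
regress`.

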