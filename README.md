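# ctqa — quantitative image quality for low-dose lung CT

`ctqa` measures lung-CT image quality from first principles:

- **Edge sharpness** — HU line density profiles are extracted along
  Bresenham-rasterized measurement lines crossing lung-to-pleura
  interfaces; a four-parameter logistic transition is fitted to each
  profile and its steepness `|θ1·(θend−θbegin)/4|` (HU/mm, the slope at
  the inflection point) is pooled to a per-scan median over a default
  grid of 39 interfaces × 12 replicate placements = 468 measurements.
- **SNR / CNR** — circular-ROI statistics (≥ 5000 pixels) in trachea,
  liver and air, with the air SD as the noise estimate.
- **Dosimetry** — mAs, DLP, effective diameter, SSDE and effective dose
  via an editable conversion-factor table.
- **Quality assessment** — 4-point Likert reader ratings, a diagnostic
  rule (mean five-item sum > 14 and every reader's overall ≥ 3),
  ICC(3,k) inter-reader reliability with F-based CIs, polynomial
  dose-response fits, and the lowest-diagnostic-dose / sharpness cut-off
  analysis.
- **Synthetic phantom** — a chest-like compartment phantom (air, soft
  tissue, lungs, trachea, liver) with Gaussian edge blur, seeded noise
  scaling as 1/√mAs, and numerically exact ground-truth edge steepness,
  so the whole pipeline is testable without scanner data.

## CLI

```bash
# 13-level synthetic dose series (NIfTI volumes + ground-truth JSON + grid)
ctqa simulate --out series/ --phantom paediatric --seed 3

# median edge steepness of a scan (packaged 468-line grid by default)
ctqa sharpness series/level_12_70kVp_10mA.nii --grid series/grid.csv --out meas.csv

# ROI statistics, SNR and CNR
ctqa roi series/level_12_70kVp_10mA.nii

# dose estimates from a scan-settings CSV
ctqa dose settings.csv --out doses.csv

# diagnostic decisions + ICC(3,k) from reader ratings
ctqa assess ratings.csv --out decisions.csv
```

Measurement grids, ROI definitions, scan settings and ratings are plain
CSV; see `src/ctqa/data/` for the packaged scan-settings protocol and
conversion-factor table (both editable/replaceable).

## Library sketch

```python
from ctqa import (PhantomSpec, default_grid, generate_phantom_stack,
                  measure_scan)

spec = PhantomSpec(seed=0)
stack, truth = generate_phantom_stack(spec, noise_sd=10.0)
result = measure_scan(stack, default_grid(spec))
print(result.median_steepness, result.n_total, result.n_included)
```
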