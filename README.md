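# mlczones

Decompose IMRT/VMAT treatment-plan apertures into the transmission zones of a
RayStation-style MLC model, compute **grid point fraction (GPF)** metrics, and
correlate them with delivery-QA results.

## The problem

IMRT/VMAT quality assurance traditionally measures every plan on a phantom —
labor the clinic would rather spend elsewhere. The accuracy of the dose
calculation these measurements are checking depends heavily on how the
treatment planning system (TPS) models transmission through the multileaf
collimator (MLC). `mlczones` analyses a plan *in the context of the TPS model
that created it*: each control point's jaw-bounded aperture plane (sampled at
0.1 mm in the isocenter plane) is partitioned into seven zones of the
zero-height MLC transmission model —

| zone | transmission | meaning |
|---|---|---|
| open | 1 | inside the aperture |
| calibration | 1 | opened only by the leaf-position calibration polynomial `shift(p) = offset + gain·p + curvature·p²` |
| tip | √T | within the rounded-tip width of a calibrated leaf end |
| body | T | under the leaf proper |
| paired | T | tongue-and-groove strip, both neighboring rows covered |
| exposed | √T | strip, one row open / other row body |
| neglected | 1 | strip, one row open / other row tip |

The fraction of grid points in each zone is the control point's GPF vector
`f_i`; plan-level metrics are the MU-weighted averages

```
AverageGPF     = Σ_i f_i·m_i / Σ_i m_i
NormAverageGPF = Σ_i (f_i/o_i)·m_i / Σ_i m_i      (o_i = open fraction)
```

Regressing measured QA quantities — gamma pass % and the median dose
difference `MDD = median[(Meas − Calc)/Meas]` over points above half the dose
maximum — on these averages identifies which regions of the MLC model drive
dose-calculation inaccuracy, and predicts which plans are likely to need a
measurement. The audience is medical physicists doing plan QA and beam-model
commissioning.

## Worked example

Classify the 10 × 10 cm² validation beam (30 × 30 cm² jaws, the 20 innermost
0.5 cm leaf pairs retracted to ±5 cm) and cross-check against the independent
interval-counting oracle:

```python
import numpy as np
from mlczones import (DEFAULT_PARAMETERS, ApertureSpec, ZONE_NAMES,
                      analytic_gpf_oracle, classify_control_point,
                      gpf_from_grid, make_validation_plan)

plan = make_validation_plan()
beam = next(b for b in plan.beams if b.name == "square-10x10")
cp = beam.control_points[0]
grid = classify_control_point(cp, plan.geometry, DEFAULT_PARAMETERS, spacing=0.01)
g = gpf_from_grid(grid, m=100.0)
for name, val in zip(ZONE_NAMES, g.f):
    print(f"{name:12s} {val:.6f}")
oracle = analytic_gpf_oracle(ApertureSpec.from_control_point(cp, plan.geometry),
                             DEFAULT_PARAMETERS, 0.01)
print("max |tool - oracle| =", np.abs(g.f - oracle).max())
```

prints

```
open         0.110228
calibration  0.001995
tip          0.020800
body         0.750800
paired       0.114400
exposed      0.001650
neglected    0.000128
max |tool - oracle| = 0.0
```

The 3000 × 3000-point grid is 11 % open (the 10 × 10 aperture plus the
0.026 cm calibration retraction of each leaf end, of 900 cm² of jaw area),
75 % leaf body, 11.4 % tongue-and-groove strip with both rows covered, and
about 2 % rounded leaf tip; the fractions sum to 1 and agree with the
closed-form interval count exactly.

The same pipeline runs from the shell:

```bash
mlczones generate vmat --seed 1 --out plan.dcm   # synthetic RT-Plan
mlczones decompose plan.dcm --out out/           # per-CP + aggregate GPF CSV
mlczones correlate cohort_gpf.csv dqa.csv        # zone-by-zone OLS report
mlczones validate                                # classifier vs oracle check
```

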