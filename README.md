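# laaecap

Deep-learning surrogates that map **left atrial appendage (LAA) surface
geometry** to per-vertex **ECAP** thrombosis-risk maps, skipping the CFD
solve at prediction time.

In atrial fibrillation most intracardiac thrombi form in the LAA, a
lobed pouch off the left atrium. Patient-specific CFD can quantify the
local risk through wall-shear-stress indices — in particular the
endothelial cell activation potential

    ECAP = OSI / TAWSS        [1/Pa]

where TAWSS = (1/T)∫|τ|dt is the time-averaged wall shear stress and
OSI = ½(1 − |∫τ dt| / ∫|τ|dt) ∈ [0, ½] measures shear-direction
reversal. High ECAP flags low, oscillatory shear — the signature of
blood stasis. CFD takes hours per anatomy; a trained surrogate answers
in milliseconds from the mesh alone.

The package implements the full pipeline around three surrogate
families, plus everything needed to evaluate them end to end:

- `laaecap.hemo` — TAWSS / OSI / ECAP from wall-shear vector time
  series, with the log1p target transform for skewed maps;
- `laaecap.mesh`, `laaecap.io` — triangle-surface data model
  (VTK/VTP/PLY/STL/OBJ), normals, cotangent mean curvature, cotangent
  Laplacian + lumped mass, and mesh→graph conversion with Cartesian
  pseudo-coordinates;
- `laaecap.flatten` — heat-method geodesic depth from the ostium,
  isoline extraction, centroid-pivot angular mapping anchored at the
  circumflex landmark, Cartesian-grid / bull's-eye rasterization with a
  validity mask, and exact back-transport to the mesh;
- `laaecap.ssm` + `laaecap.fcn` — truncated-PCA statistical shape model
  over corresponded meshes (α_i = W_iᵀ(Y−X̄)/λ_i) and a widening dense
  regressor (32 → 128 → … → 2048 → 2466; 7,846,178 parameters);
- `laaecap.unet` — masked-L1 encoder-decoder over flattened 3-channel
  xyz maps;
- `laaecap.geometric` — the strongest model: 12 B-spline-kernel graph
  convolutions (k = 5, degree 1) with a PointNet-style 1,024-dim
  max-pooled global vector (1,686,097 parameters in the canonical
  configuration), curvature + normal input features;
- `laaecap.metrics` / `laaecap.adapters` — vertex-pooled MAE, TPR at
  the 90th-percentile threshold, k-fold and sequential-scaling
  protocols over any of the architectures;
- `laaecap.synthetic` — corresponded lobed-tube LAA anatomies with a
  closed-form geometry→(TAWSS, OSI, ECAP) oracle and an exactly
  invertible two-phase WSS series (clinical data are not deposited).

All networks run on a small numpy reverse-mode autodiff engine shipped
in `laaecap.nn`; no GPU or deep-learning framework is required.

## Worked example

Train the geometric surrogate on synthetic anatomies and evaluate on
held-out cases:

```python
import numpy as np
from laaecap.synthetic import make_dataset
from laaecap.adapters import GeometricAdapter
from laaecap.geometric import GeoNetConfig
from laaecap.metrics import mae, tpr_at_percentile

data = make_dataset(60, seed=7)                      # 60 corresponded LAA + oracle ECAP
train, val, test = data.cases[:45], data.cases[45:50], data.cases[50:]

adapter = GeometricAdapter(GeoNetConfig.reduced(epochs=30))
adapter.fit(train, val, seed=0)

preds = [adapter.predict(c) for c in test]
gts = [c.ecap for c in test]
print(f"test MAE  : {mae(preds, gts):.4f} 1/Pa")
tpr, tau = tpr_at_percentile(preds, gts, 90)
print(f"TPR@P90   : {tpr:.1f}%  (threshold {tau:.3f} 1/Pa)")
mu = np.mean(np.concatenate([c.ecap for c in train]))
print(f"baseline  : {mae([np.full_like(g, mu) for g in gts], gts):.4f} 1/Pa (train-mean)")
```

Output (a few minutes on one CPU):

```
test MAE  : 0.1091 1/Pa
TPR@P90   : 67.9%  (threshold 0.893 1/Pa)
baseline  : 0.3007 1/Pa (train-mean)
```

The surrogate's error is about a third of the train-mean constant
predictor, and two thirds of the truly high-risk vertices (above the
population's 90th-percentile ECAP) are recovered. A `laaecap` console
script exposes the same steps from the shell (`laaecap synth`,
`laaecap flatten`, `laaecap indices`, `laaecap evaluate`,
`laaecap predict`).

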