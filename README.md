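# ectoloc

Noninvasive localization of the origin of a focal (ectopic or paced)
heartbeat from body-surface potential maps (BSPMs), for researchers working
on the inverse problem of electrocardiography.

## The method

A focal beat starting at heart-surface node *f* spreads along the
triangulated surface at a global conduction velocity (CV, 0.8 m/s by
default; wall-crossing edges at half speed). Its activation times τ are the
fastest-route (graph shortest-path) travel times from *f*. With an
equivalent-dipole-layer source, the body-surface potentials are

    y(t) = Σₙ A[:, n] · areaₙ · H(t − τₙ),

where A is the lead-field (transfer) matrix assembled from exact triangle
solid angles and H is the Heaviside step. The inverse search tries **every**
node as the focus, simulates its map, time-scales it to the reference
duration, normalizes both maps column-wise, and scores the match either by

* the global Pearson correlation (`fra_cc`, the classic full search), or
* the reciprocal total cost 1/c\* of a multichannel dynamic time warping
  alignment (`fra_dtw`), where c\* minimizes Σₗ‖Ỹ(:,nₗ) − Y(:,mₗ)‖₂ over all
  monotone, boundary-anchored warping paths, solved by dynamic programming.

Warping absorbs local conduction delays (e.g. from scar tissue) that a
uniform-CV candidate cannot represent, which makes `fra_dtw` robust where
`fra_cc` is displaced away from slow-conducting regions.

The package also provides synthetic heart/torso generation, strict
OFF/PLY/VTK mesh I/O, a boundary-element bounded-torso correction, and the
evaluation statistics used to compare the two searches (geodesic errors,
epi/endo surface classification, BCa bootstrap confidence intervals,
Wilcoxon signed-rank test).

## Worked example

```python
import numpy as np
from ectoloc import (
    generate_heart, generate_torso, solid_angle_transfer,
    build_conduction_graph, compute_times_matrix,
    simulate_reference, localize, RegionSpec,
)

heart = generate_heart(n_subdiv=3, seed=0)            # ~750-node ventricle
torso = generate_torso(heart, n_electrodes=64, standoff=40.0, seed=0)
A = solid_angle_transfer(heart, torso)                # 64 x 746 lead field
times = compute_times_matrix(build_conduction_graph(heart))

# simulate a beat from node 37 with a slow patch 60 mm away (CV / 3)
center = heart.mesh.vertices[200]
patched = compute_times_matrix(build_conduction_graph(
    heart, regions=[RegionSpec(center=tuple(center), radius=20.0,
                               cv_factor=1/3)]))
ref, _ = simulate_reference(heart, A, patched, focus=37)

for method in ("fra_cc", "fra_dtw"):
    smap, res = localize(heart, A, times, ref, method, true_node=37)
    print(method, res.estimated_node, round(res.geodesic_error, 1))
```

prints (for this seed and patch placement)

```
fra_cc 37 0.0
fra_dtw 37 0.0
```

— here the patch is off the main propagation path and both searches recover
node 37 exactly. In the canonical *gating* configuration
(`ectoloc.make_slow_cv_demo()`, apex focus with the patch downstream) the
correlation search is displaced several millimetres away from the patch
while the warping search stays exact:

```python
from ectoloc import make_slow_cv_demo, localize
sc = make_slow_cv_demo()
for method in ("fra_cc", "fra_dtw"):
    _, res = localize(sc.heart, sc.transfer, sc.times_search,
                      sc.reference, method, true_node=sc.focus)
    print(method, round(res.geodesic_error, 2))
```

```
fra_cc 5.25
fra_dtw 0.0
```

The same pipeline is available from the shell:

```bash
ectoloc simulate --config scenario.yaml --out ref.bspm
ectoloc localize --heart heart.off --electrodes el.txt --bspm ref.bspm \
                 --method fra_dtw --map map.csv
ectoloc evaluate --battery 20 --seed 1 --out summary.csv
```

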