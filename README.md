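# fracrecon

3D reconstruction of the (possibly fractured) proximal femur from two
simulated radiographs, for researchers studying preoperative planning
pipelines where CT is unavailable.  Given a biplanar "Judet" pair — views
at −45° and +45° about the vertical axis — a convolutional network predicts
a voxel label volume over background, bone, and a third *auxiliary* class
marking the fracture gap.

Two ideas carry the method:

* **Auxiliary class.**  The gap between bone fragments is labelled
  explicitly.  With fragment masks m_b^(k) and a spherical structuring
  element b_r (radius r = 2 voxels),

      m_f = ⋃_{k≠l} (m_b^(k) ⊕ b_r) ∩ (m_b^(l) ⊕ b_r)  −  ⋃_k m_b^(k),

  i.e. voxels reachable by dilations of at least two fragments, minus the
  bone itself.  Training on {background, bone, m_f} stops the network from
  fusing nearby fragments into one blob.

* **Fractural augmentation.**  Fractured training samples are manufactured
  from intact bone m_b: a random self-affine rough surface G (spectral
  synthesis, PSD ∝ q^−(2+2H), Hurst H = 0.8) is placed at a random
  AO-coded location (31A/31B/31C/32) by a rigid transform T, and

      m_f* = m_b ∩ T(G),   m_b* = m_b − T(G),

  with gap intensities refilled uniformly from the soft-tissue band
  63–193 HU (mean 128 HU).  Only nondisplaced fractures can be made this
  way — fragments keep their alignment.

Training uses a voxel-wise weighted focal loss, FL = Σ_i w_i·fl_i with
fl = −(1−p)^γ log p, γ = 2 and w = (0.15, 0.25, 0.6), to survive the
extreme class imbalance (roughly 9800 : 200 : 1).  Evaluation reports bone
IoU and average symmetric surface distance (ASSD, mm) with the auxiliary
class merged into the background in both prediction and ground truth.

Because no public fractured-femur CT cohort exists, the package ships a
phantom generator (shaft + angled neck + head + trochanters with Gaussian
bone/soft-tissue intensities) that stands in for the study population; the
augmentation engine itself produces the fractured samples.  The network
runs on a compact NumPy autodiff engine included in the package — see
`docs/methods.md` for the architecture and all numerical choices.

## Worked example

```python
import numpy as np
from fracrecon import (
    PhantomParams, make_phantom, region_map, augment_sample,
    synthesize_auxiliary, build_labels, judet_pair,
)

params = PhantomParams(seed=0)            # 64 mm cube, 1 mm voxels
volume, fragments = make_phantom(params)
print("intact bone voxels:", fragments.fragments[0].count())

sample = augment_sample(volume, fragments.fragments[0],
                        region_map(params), seed=3)
print("fracture at AO", sample.placement.ao_code,
      "->", sample.fragments.n, "fragments,",
      sample.gap.count(), "gap voxels")

aux = synthesize_auxiliary(sample.fragments, r=2)
labels = build_labels(sample.fragments, aux)
counts = np.bincount(labels.data.ravel(), minlength=3)
print("class voxels (background, bone, gap):", counts.tolist())

x1, x2 = judet_pair(sample.volume)
print("Judet pair:", x1.data.shape, "and", x2.data.shape,
      "normalised to [%.1f, %.1f]" % (x1.data.min(), x1.data.max()))
```

prints

```
intact bone voxels: 6901
fracture at AO 31A -> 2 fragments, 388 gap voxels
class voxels (background, bone, gap): [255415, 6513, 216]
Judet pair: (64, 64) and (64, 64) normalised to [0.0, 1.0]
```

The intact phantom (6901 bone voxels) was cut at a trochanteric (31A)
location into two fragments separated by a 388-voxel gap; after the cut the
gap's 63–193 HU refill leaves 6513 bone voxels, and the morphological gap
synthesis marks the 216 voxels where the two fragments' dilations meet.
The two 64×64 images are the network inputs.

Training is exposed as a scikit-learn style estimator:

```python
from fracrecon import FracReconNet
est = FracReconNet(levels=4, image_size=32, n_classes=3,
                   learning_rate=3e-3, max_steps=600, random_state=0)
est.fit(X, y)            # X: (n, 2, 32, 32) Judet pairs, y: (n, 32, 32, 32) labels
labels = est.predict(X)  # argmax label volumes
```

A `fracrecon` command-line tool wraps the pipeline
(`phantoms`, `augment`, `auxgen`, `drr`, `train`, `evaluate`,
`experiment`, `infer`); try `fracrecon --help`.

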