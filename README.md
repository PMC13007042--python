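# nerveseg

Anatomy-aware 3D segmentation of peripheral-nerve microCT volumes.

Ex vivo microCT of contrast-stained nerves (the motivating case is the
plexiform human vagus nerve) resolves the full 3D fascicular architecture:
dozens of fascicles per cross section that wander, split, and merge along
the nerve, all wrapped in an epineurium sheath. Segmenting these volumes
voxel-by-voxel into **background / fascicle / epineurium** is the
bottleneck for fascicle tracking, morphometrics, and computational models
of nerve stimulation — and generic segmentation losses happily produce
anatomical nonsense (fascicles touching background, tubes that flicker in
and out between slices) that voxel-overlap scores barely notice.

`nerveseg` provides, end to end:

* a **3D U-Net** (7-stage encoder-decoder; instance norm + leaky ReLU;
  strided convolutions) with its full patch-based training protocol — SGD
  with Nesterov momentum µ = 0.99, poly learning-rate decay
  `lr₀·(1−e/e_max)^0.9`, 33% foreground-guaranteed patch sampling —
  implemented on NumPy/numba with hand-derived, finite-difference-verified
  backward passes (no GPU framework required);
* the **anatomy-aware compound loss** `L = L_CE + L_Dice + λ·L_Topo`,
  where `L_Topo` is cross-entropy restricted to the *critical voxel map* V
  — the voxels where the prediction's hard labels violate the rules
  "fascicles are enclosed by epineurium" and "fascicles never touch
  background" (a 26-neighborhood test), recomputed from the argmax every
  step;
* **sliding-window inference** with 25% patch overlap and Gaussian
  blending (σ = 0.125 of the patch edge);
* the **evaluation suite** such segmentations need: Dice, surface Dice,
  ASSD (µm), IoU/sensitivity/specificity; per-fascicle detection F1 across
  IoU thresholds 0.50–0.95, over-/under-segmentation and size-stratified
  miss rates (tiny < 0.02 mm² … large > 0.3 mm², effective circular
  diameter d = 2√(A/π)); clDice connectivity, anatomical error rate,
  inter-slice boundary-F1, and split/merge event detection with per-mm
  rate deviation `(|ΔR_split|+|ΔR_merge|)/2`;
* a **synthetic phantom generator** producing nerve volumes with known
  geometry and a known split/merge event ledger — the ground truth for
  every shipped experiment, so no scanner data are needed.

A scikit-learn style estimator (`nerveseg.estimator.NerveSegmenter`, with
`fit` / `predict` / `score` / `get_params`) wraps training and inference;
a `nerveseg` CLI exposes `phantom`, `train`, `predict`, `evaluate`.

See `docs/methods.md` for the model, the loss normalization and gradient
balancing, phantom construction, metric conventions, and limitations.

## Worked example

Train the desk-scale network on four synthetic phantoms and evaluate on a
held-out one (about two minutes on one CPU):

```python
from nerveseg.losses import LossConfig
from nerveseg.metrics import evaluate_pair
from nerveseg.study import make_phantom_corpus, train_and_score

train, test = make_phantom_corpus(seed=1)
result = train_and_score(train, test, LossConfig(), seed=1)
report = evaluate_pair(result["predictions"][0], test[0].labels)
print(f"fascicle Dice        {report['dice']['fascicle']:.3f}")
print(f"fascicle surf. Dice  {report['surface_dice']['fascicle']:.3f}")
print(f"fascicle ASSD        {report['assd_um']['fascicle']:.1f} um")
print(f"fascicle clDice      {report['cldice']:.3f}")
print(f"anatomical errors    {100 * report['anatomical_error_rate']:.2f}%")
```

output (seed 1):

```
fascicle Dice        0.893
fascicle surf. Dice  0.906
fascicle ASSD        31.7 um
fascicle clDice      0.741
anatomical errors    0.09%
```

A fascicle Dice around 0.9 with an anatomical error rate well below 1% is
the expected desk-scale behavior. Retraining with
`LossConfig(use_topo=False)` (the ablation) at the same seed leaves a
higher anatomical error rate (0.24% vs 0.09% here) at comparable overlap
accuracy — the effect the topology term exists for. The report also tracks
split/merge events; at this small training scale the prediction still
contains flickering components that register as spurious events, which is
precisely the failure mode the longitudinal metrics are designed to
expose.

The same pipeline from the shell:

```bash
nerveseg phantom --seed 7 --out-image img.tif --out-labels gt.tif --out-events ev.csv
nerveseg train --config config.yaml --images img.tif --labels gt.tif ... --out w.npz
nerveseg predict --image img.tif --weights w.npz --out-labels seg.tif
nerveseg evaluate --pred seg.tif --truth gt.tif --report report.json
```

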