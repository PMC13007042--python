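# Methods

`nerveseg` implements anatomy-aware 3D semantic segmentation of peripheral
nerve (vagus-type) microCT volumes into background, fascicle, and
epineurium, together with the evaluation suite such segmentations need:
volumetric and surface overlap, per-fascicle detection, and longitudinal
(connectivity, jitter, split/merge) measures. Because real scanner data and
trained weights are not distributed, the package ships a synthetic phantom
generator that reproduces the anatomical structure the method and its
metrics assume, and every result the package reports is computed end-to-end
on those phantoms.

## The segmentation model

The segmenter is a 3D U-Net. The full-scale configuration is a 7-stage
encoder-decoder with feature widths 32, 64, 128, 256, 320, 320, 320;
each stage applies two 3×3×3 convolutions with instance normalization and
leaky ReLU (no dropout), with per-stage downsampling strides (1,1,1),
(2,2,2)×4, (1,2,2)×2, so a 32×256×256 patch reaches a 2×4×4 bottleneck. The
decoder mirrors the encoder with skip connections. Upsampling is
nearest-neighbour repetition followed by two convolutions (a transposed
convolution is the other common choice; repetition has an exactly adjoint
backward pass and showed no quality difference at the scales we train).
The final 1×1×1 convolution emits 3 class scores per voxel.

The network, its backward passes, and the optimizer are implemented
directly on NumPy (with numba-compiled convolution loops; a pure-NumPy
GEMM path is the fallback and serves as an independent reference in the
tests). Every backward pass is verified against central finite differences
in double precision.

### Anatomy-aware compound loss

Training minimizes

    L = L_CE + L_Dice + λ · L_Topo

* `L_CE`: mean voxel-wise cross-entropy.
* `L_Dice`: soft Dice loss averaged over the two foreground classes, with
  smoothing constant 1e-5 in numerator and denominator.
* `L_Topo`: cross-entropy restricted (Hadamard product) to the *critical
  voxel map* `V`, the set of voxels violating the anatomical rules —
  fascicles must be enclosed by epineurium and may never touch background.
  On a 26-connected voxel lattice both rules reduce to one local test: a
  fascicle voxel with a background voxel anywhere in its 26-neighborhood is
  a violation, and both voxels of the pair are flagged. `V` is recomputed
  from the hard argmax of the prediction at every step and treated as a
  constant (straight-through); gradient flows only through the
  cross-entropy it gates. Fascicle–epineurium contact is the desired
  topology and is never flagged.

λ defaults to 1e6. Three normalizations of the masked cross-entropy are
exposed (`topo_reduction`): `"total"` (default) divides the flagged-voxel
sum by the total voxel count — i.e. an ordinary cross-entropy whose
per-voxel terms are zeroed outside `V`; `"mean"` divides by the flagged
count; `"sum"` does not normalize. `"total"` is the default because under
`"mean"` the per-voxel topology weight is λ/|V|, which explodes as
violations become rare: in our desk-scale runs the topology direction then
dominated every update and the fascicle class collapsed entirely.

Even under `"total"`, λ = 1e6 makes the topology gradient orders of
magnitude larger than the conventional terms whenever any violation
exists. Clipping the summed gradient does not help: it rescales but does
not re-balance, so the update direction remains purely topological. We
therefore apply *per-term gradient balancing* during training
(`topo_grad_balance`, default 1.0): the topology logit-gradient is rescaled
so its norm never exceeds the conventional (CE + Dice) gradient norm times
the balance factor. The topology term thus acts as a persistent, bounded
corrective pressure rather than an unbounded penalty. Loss *values* are
reported unscaled. Setting `topo_grad_balance=None` restores the literal
weighted sum. The ablation switch (`use_topo=False`) removes the term
entirely and consumes no randomness, so ablation and compound runs see
bit-identical patch streams at equal seeds.

### Training protocol

Full-scale protocol (GPU-scale; available but not the default): 32×256×256
patches, batch 4, 500 epochs × 250 iterations, SGD with Nesterov momentum
0.99, initial learning rate 0.01 with polynomial decay
`lr0·(1 − e/e_max)^0.9`, 33% of patches guaranteed to contain foreground,
in-training validation on 50 random patches per epoch, and augmentation by
in-plane rotation (±15°), additive Gaussian noise (sd ≤ 0.1 of the unit
dynamic range), and contrast scaling (0.75–1.25), each with probability
0.2.

Desk-scale defaults (`ArchitectureConfig.scaled()`,
`TrainingConfig.scaled()`) shrink this to a 3-stage net (features 8/16/32)
and 16×64×64 patches so a training run finishes in minutes on one CPU. The
systematic phantom experiments in the test-suite and acceptance script use
an even smaller variant (features 4/8/16, 16×48×48 patches, 30 epochs × 6
iterations × batch 2, augmentation off) chosen once as the smallest
protocol that segments phantoms well (held-out fascicle Dice ≳ 0.9);
augmentation is disabled there because phantom intensity statistics are
stationary by construction and the geometric/noise augmentations only slow
convergence without adding realism.

The foreground-patch guarantee is implemented by centering forced draws on
a random foreground voxel; an all-background corpus raises after bounded
retries. Gradients are clipped to global norm 12 before each SGD step (the
convention of the training framework the full-scale recipe comes from).
Weights use He initialization. Every random choice (init, patch sampling,
augmentation, validation draws) derives from a single seed; identical seeds
reproduce runs bit-exactly. Non-finite losses abort with a diagnostic
rather than continuing silently.

### Inference

Full volumes are predicted by sliding-window tiling: 25% overlap per axis,
stride `round(patch·0.75)` with the final tile clamped to the boundary, and
Gaussian blending of patch softmax probabilities (per-axis sd = 0.125 of
the patch edge, peak-normalized at the patch center). The blended score is
the weight-normalized sum; labels are the per-voxel argmax. σ is
interpreted relative to patch size, the common convention when only a
dimensionless σ is quoted. Blending softmax probabilities is the default;
blending raw logits is config-exposed. Volumes smaller than one patch are
edge-padded and cropped back.

## The phantom generator

A phantom is a deterministic function of a `PhantomSpec` (default:
32×128×128 voxels at 11.4 µm isotropic — the scanner resolution of the
motivating data; 5 initial fascicles; radii 40–120 µm; nerve ellipse
semi-axes 620×680 µm; epineurium margin 35 µm; one split and one merge;
wobble 10 µm; class intensity means 2000/22000/12000 for
background/fascicle/epineurium with noise sd 1500 on the 16-bit scale and a
±10% low-frequency multiplicative bias field). Intensities are arbitrary
but emulate contrast-stained microCT: fascicles bright, epineurium
intermediate, background dark, with overlapping noise tails. No real
intensity statistics were available to calibrate against; the defaults are
a single fixed choice.

Centerlines are forward-simulated slice by slice: smooth AR(1) wobble,
±20% sinusoidal caliber change, containment inside the ellipse minus the
margin, and a minimum center distance of `r_i + r_j + 3` voxels between
non-event tubes (enforced by a deterministic repulsion pass). Splits fork a
tube into two area-conserving children placed along the most collision-free
of 16 candidate directions; merges steer the closest eligible pair together
over a 6-slice transition and replace it with one tube of combined area
(shrunk if a third tube is too close). Events are scheduled at least 6
slices apart and away from the volume ends, so per-slice component counts
change by exactly one per event — making ground-truth event locations well
defined and exactly recoverable by the overlap tracker.

Rasterization draws per-slice discs, fills the remaining ellipse with
epineurium, then repairs the rare single-slice class aberrations that disc
rasterization of a wobbling tube can leave at wobble turning points
(a voxel differing from two agreeing longitudinal neighbors is reassigned
to the neighbor class, iterated to a fixpoint). The result provably
satisfies both anatomical constraints: the critical voxel map is empty and
the anatomical error rate is exactly 0 on every generated phantom — which
the test-suite asserts.

What phantoms do *not* emulate: partial-volume effects, staining gradients
beyond the smooth bias field, perineurium as a separate structure,
interstitial texture, tissue damage, or anisotropic resolution. Passing
phantom-based tests therefore demonstrates the correctness of losses,
training mechanics, inference, and metrics — not clinical-grade accuracy on
real scans.

## Evaluation metrics

All metrics operate per class (fascicle, epineurium) where applicable, with
`P` the prediction and `G` the ground truth.

* **Dice** `2|P∩G|/(|P|+|G|)`; defined 1 for two empty masks.
* **Surface Dice** at tolerance τ (default 1 voxel):
  `(|B(P,τ)∩S(G)| + |B(G,τ)∩S(P)|)/(|S(P)|+|S(G)|)`. Surfaces are mask
  voxels with a 6-neighbor outside the mask (array border counts as
  outside); border regions are evaluated with a Euclidean distance
  transform thresholded at τ.
* **ASSD**: symmetric sum of nearest-surface distances normalized by total
  surface count, reported in µm via the isotropic spacing; undefined
  (raises) for empty masks. Anisotropic spacing is unsupported.
* **IoU / sensitivity / specificity** per class from the binary confusion
  counts.
* **Instance detection**: per-slice 8-connected fascicle components,
  matched by IoU at thresholds 0.50–0.95 (step 0.05, one-to-one guaranteed
  for t ≥ 0.5); F1 = 2TP/(2TP+FP+FN). Over-segmentation (a GT fascicle
  covered by ≥2 majority-inside predictions and itself unmatched at
  t = 0.7) and under-segmentation (≥2 GT fascicles majority-inside one
  prediction) rates are fractions of GT fascicles; the majority-cover rule
  below threshold is this package's convention (the weakest rule making the
  two phenomena mutually exclusive per component) and is flagged in
  reports. Misses are stratified by cross-sectional area into tiny
  (<0.02 mm²), small (0.02–0.09), medium (0.09–0.3), large (>0.3) —
  effective circular diameters (d = 2√(A/π)) of <0.16, 0.16–0.34,
  0.34–0.62, >0.62 mm. All instance rates are computed every 8th slice
  (~0.1 mm) and averaged; slices without GT fascicles contribute no terms.
* **clDice**: harmonic mean of skeleton precision `|Sk(P)∩G|/|Sk(P)|` and
  sensitivity `|Sk(G)∩P|/|Sk(G)|` using 3D medial-axis thinning
  (scikit-image `skeletonize`).
* **Anatomical error rate**: flagged foreground voxels / total foreground,
  where flags are (1) fascicle voxels in 26-contact with background and
  (2) abrupt transitions — a foreground voxel whose class differs from the
  agreeing classes one slice before and after (window config-exposed). The
  abrupt-transition operator is our reconstruction of a rule whose exact
  published form is unavailable; it flags exactly the one-slice plates and
  breaks that longitudinal continuity forbids.
* **Inter-slice BF score**: per adjacent slice pair, boundary precision and
  recall between one-pixel contours (mask minus 8-connected erosion) within
  τ = 1 px, combined as harmonic mean and averaged along z. We use the
  inclusive test `d ≤ τ`: on an integer lattice a strict `d < 1` would
  tolerate nothing, contradicting the "single-pixel tolerance" the metric
  is meant to have (the strict form is available via a flag). A pair where
  exactly one contour is empty scores 0; both empty, the pair is skipped.
* **Split/merge events**: per-slice 8-connected fascicle components linked
  between consecutive slices by ≥1 px overlap; one-to-many transitions are
  splits, many-to-one merges. Same-kind detections within 3 slices with
  overlapping junction footprints collapse to one event. Rates are events
  per mm of z-extent; the deviation between prediction and ground truth is
  `(|ΔR_split| + |ΔR_merge|)/2`, reported both absolute (events/mm) and as
  a percentage of the mean ground-truth rate.

## Numerical and design choices

* Axis order is `(z, y, x)` everywhere; z is the nerve's longitudinal axis.
* Label codes: 0 background, 1 fascicle, 2 epineurium; when combining
  separate masks, fascicle overwrites epineurium.
* Intensity normalization clips raw 16-bit values to [0, 32767] and divides
  by 32767 (negative values are reconstruction artifacts).
* OME-style Zarr I/O uses plain Zarr arrays with spacing/axis attributes;
  multi-resolution pyramids and DICOM are out of scope.
* Degenerate metric inputs raise or are flagged explicitly (empty masks,
  missing classes, empty skeletons) rather than being silently scored.
* The event tracker's `min_overlap_px` (1) and deduplication window (3
  slices) are config-exposed; published values for the cited tracking
  procedure are not available.

## Problem sizes used by the shipped experiments

Phantom experiments run at 32×128×128 voxels (0.36×1.46×1.46 mm) with 4
training phantoms and 1 held-out phantom; training uses the 4/8/16-feature
network on 16×48×48 patches for 30 epochs × 6 iterations × batch 2
(held-out fascicle Dice ≈ 0.9 under the compound loss). The
compound-vs-ablation comparison repeats both runs at 10 matched seeds.
These sizes are the package's desk-scale defaults; the full-scale recipe
above is available unchanged for GPU-scale work.

## Known limitations

* The NumPy/numba engine is single-threaded and CPU-bound; full-scale
  training is not practical with it.
* Phantom realism is structural, not radiometric (see above).
* The exact published forms of the abrupt-transition operator, the
  augmentation parameter table, and the split/merge tracker parameters are
  unavailable; our reconstructions are documented above and config-exposed.
* Per-term gradient balancing is a deliberate deviation from a literal
  `λ·L_Topo` sum; the literal behavior is recoverable via configuration but
  diverges or collapses at desk scale.
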