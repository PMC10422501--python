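# Methods

## Model and assumptions

The pipeline assumes pre-segmented clips, each showing one activity from a
wearable camera, and that (a) activity-relevant objects produce localised
activations in the convolutional feature maps of an image CNN, and (b) the
gross temporal structure of an activity is captured by a whole-clip
maximum plus first-half/second-half means of frame descriptors.  No
end-to-end training takes place: the backbone is frozen, all learning is
in the linear SVM.

Per frame, the pool5 activation grid (7×7 cells × 512 channels) is pooled
per channel over six fixed regions — whole [1,7]×[1,7], centre [3,5]×[3,5]
and four 4×4 quadrants that deliberately overlap on row/column 4
([1,4]/[4,7] splits; the shared row/column is counted in both quadrants,
exactly as the region definitions state).  Means and maxima over the six
regions give 12 blocks of 512 values: the 6144-dimensional MMSP
descriptor.  Indexing is 1-based inclusive in all documentation and
converted to 0-based half-open slices in exactly one place
(`RegionSpec.slices`).

Two mean conventions coexist.  `true_mean` (default) divides each regional
sum by the region's actual cell count (49, 9 or 16).  `paper_literal`
applies coefficient 1/49 to the whole grid and 1/9 to every sub-region,
including the 16-cell quadrants — arithmetic we judge to be a transcribed
typo (1/9 matches only the 9-cell centre) but preserve verbatim for exact
replication.  Both modes are tested against a brute-force oracle; the two
differ only by a per-block positive scale (16/9 on four mean blocks),
which a linear SVM on L2-normalised features can largely absorb.

TPMM halves an odd-length clip as first ⌊N/2⌋ frames / remainder, each
mean using its own denominator (the printed 1/(N/2) assumes even N).  A
single-frame clip reuses its frame for both halves rather than erroring,
so very short clips remain processable; this is logged.  TPMM is invariant
to frame reordering within each half but not to swapping the halves —
property-tested, since that asymmetry is the point of the pyramid.

The motion stream estimates dense optical flow between consecutive
*sampled* frames (not native-rate neighbours): the pyramid pools one
descriptor per sampled frame and this keeps the two streams on identical
temporal supports; the final motion image is duplicated so the sequences
have equal length.  Flow fields are rendered with hue = direction
(linear over the full hue circle), saturation = magnitude, value = 1.
Magnitude normalisation is per-frame min–max by default (scale-invariant,
robust to camera-speed differences); a fixed-cap mode exists when
cross-clip magnitude comparability matters.

Normalisation order: each stream's clip vector is L2-normalised, the two
are concatenated, and the fused vector re-normalised.  This equalises
stream energy so neither modality dominates by scale alone; a
normalise-after-concatenation-only mode is available in the config.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `target_fps` | 1 | frames/s | one frame per second suffices for ADL-scale activities; 10 fps supported |
| sampling anchor | frame 0, stride round(native/target) | — | deterministic; offset configurable |
| `spatial_mode` | `true_mean` | — | see above |
| `temporal_pooling` | `tpmm` | — | max-only and mean-only are baselines |
| `streams` | `both` | — | early fusion of appearance + motion |
| `svm_cost` (C) | 1.0 | — | liblinear cost; results are insensitive to C in this regime |
| SVM tolerance | 1e-4 | — | liblinear default-tier tolerance, seeded solver |
| flow solver | iLK, radius 7, 10 warps | px | library defaults, echoed into run metadata |
| backbone input | 224×224, bilinear, RGB, mean-centred | px | VGG16 input contract; resize without crop (cropping loses the egocentric periphery where hands appear) |

Prediction ties are broken by sorted class order (deterministic).  A class
never predicted contributes Pre(j) = 0 to AP — the 0/0 column is defined
to penalise degenerate classifiers.  AP is computed on the confusion
matrix pooled over all LOPO folds; per-fold accuracies are reported in the
fold log.

## Backbone providers

The `vgg16` provider is a numpy implementation of the VGG16 architecture
(13 3×3 conv layers in five blocks with 2×2 max pooling, then two
4096-unit fully connected layers) with seeded He-initialised random
weights.  It guarantees the geometry every contract depends on — pool5 is
7×7×512, fc7 is 4096 — and is deterministic given its seed, but its
features are random projections, not ImageNet semantics: classification
results with it characterise the pooling machinery, not transfer
learning.  Pretrained features can be used by caching externally computed
descriptors in the documented cache format.  The `mock` provider
block-averages the image onto the 7×7 grid and projects the three colour
channels to 512 through a seeded random matrix with a ReLU: a pure
function of (seed, image) that preserves spatial image structure, so
synthetic class-dependent content stays separable through it.

## Synthetic data

The generator emulates the two properties the method relies on:

* **Feature stacks** — i.i.d. Gaussian noise (sd 0.5) around baseline 1.0,
  plus an additive bump of strength 3.0 inside one named MMSP region on a
  seeded 25% channel subset; the region cycles per class.  Placing the
  signal in pooling regions makes the spatial-pooling stage, specifically,
  the step that renders classes linearly separable: the end-to-end 100%
  LOPO result is a targeted integration test of the region arithmetic.
  The default satisfies the separability margin (strength > 3 × noise sd).
* **Videos** — a textured square (¼ frame width) translating over a
  textured noise background with a known integer shift per interval,
  giving the flow estimator a ground truth; class-dependent motion assigns
  each class a direction on the circle at 3 px/frame.

The label-shuffled control permutes labels within each subject.  This
stratification keeps every LOPO training fold exactly class-balanced; an
unstratified permutation makes the training-set majority class
anti-correlated with the held-out subject's composition and biases
null accuracy below chance (the familiar pessimism of leave-one-out on
null data), which would misrepresent the chance level the control is
meant to pin down.

What the fixtures do *not* emulate: photorealistic scenes, camera shake
and motion blur, class imbalance, inter-subject appearance variation, or
any correlation structure between appearance and motion streams.  Passing
tests therefore demonstrate the correctness of the pooling, fusion and
evaluation machinery — not benchmark-level recognition performance on
real egocentric video, which additionally depends on pretrained backbone
quality.

## Numerical and protocol choices

* Problem sizes: fixture datasets use 3–4 subjects, 2 classes, 2–3 clips
  per subject×class and 64–512 channels; the brute-force pooling oracle
  runs on 200 random 7×7 stacks.  These sizes exercise every code path
  while keeping the whole suite and the acceptance script fast on a
  single CPU.
* All generators and tests derive randomness from explicit integer seeds;
  `scripts/acceptance.py` threads its `--seed` through every stochastic
  component.
* Degenerate inputs: zero vectors pass through L2 normalisation unchanged
  (logged); empty descriptor sequences, single-class training sets,
  mismatched shapes and non-finite arrays raise typed errors; a cache
  miss is a sentinel, not an exception, and is distinguishable from a
  cached empty array.
* LOPO asserts per fold that the held-out subject contributes no training
  clip, and single-class training folds abort the run unless explicitly
  allowed to be skipped.

## Known limitations

* No pretrained weights ship with the package; headline benchmark
  accuracies on public ADL datasets are out of scope here.
* MP4/AVI input requires an imageio video plugin; frame directories are
  the dependency-free path.
* The fv-pool5 flattening and fc7 baselines are provided for dimensional
  and contract parity but share the random-weight caveat above.
* Only a two-level temporal pyramid is implemented; deeper pyramids and
  gradient-based time-series pooling operators are out of scope.
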