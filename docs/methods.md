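# Methods

## Model

The classifier scores a lung nodule as benign or malignant from three
aligned 3D patches ("3D" meaning the central axial slice plus its two
immediate z-neighbours, stacked as channels). The three patch scales carry
complementary information: the tight crop carries margin texture, the two
context crops carry the surrounding tissue, here including a faint
high-intensity ring the generator can place 10–20 voxels outside malignant
blobs. Three capsule networks are trained independently, one per scale, and
a fully connected fusion stack combines them.

A single-scale capsule network is: a valid-padding 2D convolution (kernel 9,
stride 1) with ReLU; a second convolution (kernel 9, stride 2) whose output
channels are grouped into 8-dimensional primary capsules and squashed; and a
routed capsule layer onto 2 class capsules of dimension 16. Routing by
agreement runs 3 iterations by default with the log-priors reset to zero at
every forward pass. Two conventions the literature leaves open are fixed
here and tested against an independent step-by-step oracle: the routing
softmax is taken over the *upper* capsules, and the agreement term is
computed against the squashed output of the current iteration. The squash
nonlinearity is `v = (|s|²/(1+|s|²)) s/|s|`.

Class capsules are trained with the margin loss (defaults `m⁺ = 0.9`,
`m⁻ = 0.1`, `λ = 0.5`). The fusion stack consumes the 96-dim concatenation
of the three masked 32-vectors (per scale, the lower-norm class capsule is
zeroed; on an exact norm tie, class 0 is masked) and ends in a two-class
softmax trained with the weighted binary cross-entropy
`−(α y log p + β(1−y) log(1−p))`, `p` being the malignant-class
probability. `α` weights the malignant-class term, so raising it penalises
missed malignancies and raises sensitivity; `β` trades the other way.
Probabilities are clipped to `[1e−7, 1−1e−7]` inside the loss. Masking uses
the predicted (lower-norm) class at both training and inference time; the
capsule branches are frozen when the fusion stack trains.

All networks are NumPy with hand-derived reverse-mode gradients and Adam
(learning rate 1e-3 by default; the batch loss is the mean over samples).
During backpropagation the routing coupling coefficients are treated as
constants of the forward pass — the standard practice for trained routing —
so the gradient check against finite differences is exact for one routing
iteration and intentionally approximate beyond it.

## Patch extraction

Scale specifications are (margin 0, pad 80), (margin 10, pad 100),
(margin 20, pad 120), all emitting `out_size × out_size` patches
(80 by default, 40 in the tiny preset). The annotated in-plane bounding box
is expanded by the margin per side on each of the three slices, zero-padded
centered (odd remainders go to the high-index side), and down-sampled by
separable linear interpolation: one axis first, then the other, each output
sample being the weighted average of its two bracketing input samples.
Output sample centers follow the align-corners-false convention
`(i + 0.5)·n_in/n_out − 0.5`, clamped at the borders; this makes the
down-sampler exact on images that are linear in the pixel coordinates
(note the clamped border samples, not an endpoint-matching ramp).
Patches are min-max normalized to [0, 1] per patch; a constant patch maps
to all zeros to avoid 0/0. Normalization per patch (rather than a global
intensity window) is a choice; both appear in practice. Augmentation is
in-plane flips only, applied identically across scales and slices to keep
the triple aligned. A nodule whose tight-crop extent exceeds the scale-1
pad of 80 pixels is rejected with an explicit error.

## Labeling

The mean of the 1–4 integer ratings is rounded to the nearest integer with
half rounding *up* (so mean 2.5 → 3 → discard and 3.5 → 4 → malignant);
the convention is fixed so results are deterministic, since either choice
is defensible. Rounded 1–2 → benign, 4–5 → malignant, 3 → discard.
Discarded nodules are excluded from training and from accuracy metrics but
are still scored by the trained model for the confidence analysis. A
patient is malignant iff any of their labeled nodules is.

## Synthetic cohort generator

The generator emulates a multi-patient CT nodule cohort: per patient, a
160×160×32 volume (large enough that all three scales fit without
truncation) of low-amplitude Gaussian background noise (sd 0.05) with 1–4
non-overlapping nodules. A nodule is an ellipsoid indicator (semi-axis
jitter ±15% in-plane, 0.45–0.7 along z) smoothed by a Gaussian of σ = 1
voxel. Malignancy manifests three ways, each a config knob:

- radius: benign 4–6 voxels, malignant 8–11 (disjoint by default);
- margin: malignant boundaries get a radial sinusoidal perturbation of
  amplitude `spiculation_strength` (default 2 voxels);
- context: malignant nodules get a faint spherical shell
  (intensity 0.3 vs the blob's 1.0) 10–14 voxels outside the blob radius,
  which only the 10/20-pixel-margin scales can see — this gives multi-scale
  fusion signal that the tight crop genuinely lacks.

Raters perceive a latent score of 1.5 (benign) or 4.5 (malignant) plus
Gaussian noise (sd 0.9, chosen so that a realistic minority — roughly
5–10% — of nodules aggregate to the indeterminate rating 3, as multi-rater
collections do); the report is the latent rounded half-up and clipped to
[1, 5]; the rater count is drawn from (0.15, 0.25, 0.3, 0.3) over 1–4.
Rater uncertainty and appearance share a latent ambiguity factor
`clip(|mean latent − 3|/1.5, 0, 1)`: a nodule whose raters sit near the
fence is rendered nearer the class boundary (radius pulled toward the
inter-class midpoint; spiculation and ring intensity scaled down). With
zero rating noise the factor is exactly 1 and appearance reduces to the
pure class-conditional draw. This is a modelling stand-in — real rater
disagreement statistics are not being inferred — but it is what makes the
confidence analysis meaningful: rating-indeterminate nodules are also
visually ambiguous.

The train/test split is by patient (70/30, rounded to the nearest patient
count), so no patient contributes nodules to both sides. All generation is
bit-identical under a repeated seed. What the generator does *not* emulate:
CT physics and HU calibration, lung anatomy, nodule detection (annotations
are given), slice-thickness anisotropy, and systematic rater biases. Tests
passing on this cohort show the pipeline is wired and trained correctly and
that its relative behaviours (fusion vs single scale, loss-weight
directions, feature–size correlation) point the right way; they do not
certify performance on real CT data.

## Problem sizes and presets

The tiny preset trains on 40×40 patches with 8 convolution maps and 4
primary-capsule channels (≈150k routed parameters), 25 epochs per scale and
200 fusion epochs at batch size 16 — chosen as the smallest configuration
that trains in about a minute per experiment on one CPU while still
saturating the separable default cohort. The default experiment cohort is
20 patients (roughly 40–60 nodules). The paper-scale preset (80×80 inputs,
256 maps, 32 primary channels, fusion hidden sizes 1028/512/256 — 1028 as
specified, though 1024 may have been intended; it is configurable) is
instantiated and shape-checked in the tests but not trained there.

## Numerical choices and degenerate inputs

- Squash at the origin returns the zero vector; its vector–Jacobian product
  is guarded against division by zero below norm 1e-12.
- Coupling coefficients are computed with a max-shifted softmax; rows sum
  to 1 within 1e-9 in tests.
- Confusion-metric denominators of an absent class yield `None` (flagged
  undefined) rather than raising or returning 0.
- AUC is trapezoidal over all distinct thresholds (ties grouped), which
  equals pairwise concordance with ties counted ½; an independent O(n²)
  oracle checks this.
- Pearson correlations with a constant column are NaN, flagged, not errors.
- Confidence histograms use 10 equal bins on [0.5, 1].
- A training set with a single class warns and proceeds (the loss is still
  well defined); an empty one raises.
- Nodule placement uses rejection sampling keeping each neighbour's blob
  outside every nodule's coarsest crop footprint; a volume too dense to
  place raises a placement error, and cohort generation retries a patient
  with deterministically derived seeds before giving up.

## Known limitations

- The synthetic cohort is far easier than LIDC-IDRI-like data; absolute
  metrics near 1.0 are expected and carry little information beyond
  correctness of the plumbing. Confidence saturates correspondingly
  (softmax probabilities near 1), so the indeterminate-vs-clear confidence
  gap, while consistently directional, is numerically small.
- Training the paper-scale preset in NumPy on one CPU is possible but slow;
  the package targets desk-scale verification, not GPU-scale training.
- No reconstruction/decoder regulariser is included, and the three capsule
  branches are not fine-tuned jointly through the fusion stack.
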