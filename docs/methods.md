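# Methods

This note records the modelling assumptions, parameter conventions and
design choices behind drpipe, and what the synthetic-data tests do and do
not demonstrate.

## Preprocessing

A row or column is trimmed while **every** channel of **every** one of its
pixels is strictly below the dark threshold (default 7); a single channel
at 7 keeps the line. Trimming is a bounding-box crop: only contiguous
border rows/columns are removed, never interior ones, since deleting
interior lines would shear the anatomy. Circle membership uses pixel-centre
distance: centre ((H−1)/2, (W−1)/2), radius min(H, W)/2, a pixel surviving
when its centre lies within the radius. The chain is trim → mask → trim →
resize; the second trim exists because masking a non-square image darkens
rows/columns at the long edges. Resizing forces both dimensions to the
target side (default 299 px) with bilinear interpolation — a constant image
stays constant under it, and aspect ratio is deliberately not preserved
because the preceding steps already leave a roughly square retina.
Trimming is applied once per occurrence, not iterated to a fixed point; a
fixed-point iteration could only remove lines the mask step darkened, which
the second trim already handles.

## Balancing

The add-per-image count `Add_i = (N_0 − N_i)/N_i` uses floor division —
integer counts force it, and the resulting totals `N_i (Add_i + 1)` then
never exceed `N_0` (the shortfall is `N_0 mod N_i`). Allocation of the
generated images across the three transforms is deterministic: left-right
flip first, up-down flip second, the remainder independent rotations with
angles drawn uniformly from [0°, 360°). The two flips can each contribute
at most one distinct image per source, so they are used exactly once before
rotations take over. Rotations are not deduplicated against flips; the
probability of a duplicate under a continuous angle draw is zero. Every
generated image is re-masked to the inscribed circle, which is a no-op for
flips of already-masked inputs but removes the bright corner bars rotation
can introduce. The majority class is never upsampled. Class weights follow
`w_c = n_samples/(n_classes · count_c)`; their support-weighted mean is 1,
so they rescale per-class loss contributions without changing the overall
loss scale.

## Dataset splitting

The 3:1:1 split fixes validation and test sizes to ceil(N/5) each with the
remainder to training (for N = 35,126 this gives 21,074/7,026/7,026; plain
rounding of 0.6·N would not). Assignment is stratified: per-class training
counts are apportioned by largest remainder against quota 0.6·count with
the global totals fixed, and each class's remaining images are split evenly
between validation and test, again by largest remainder. This keeps each
class's training share within about one image of 3/5 while making the
global sizes exact. Membership within a class is a seeded shuffle; the
same seed reproduces the split exactly. Patient-level grouping is out of
scope — the manifest schema has no patient identity.

## Classifiers and training

A classifier is backbone → attention → global average pooling → dense
softmax head. The attention block gates channels first (shared two-layer
MLP with reduction ratio 8 over the average- and max-pooled channel
vectors, sigmoid of the sum) and positions second (7×7 convolution over
the stacked channel-wise mean and max maps, sigmoid). Both gates lie in
(0, 1), so the block never increases a feature's magnitude, preserves
shape, and maps zero input to zero output. The block sits once, after the
backbone's final feature maps, and its parameters train in phase 1 — they
are part of the added top.

Backbones are opaque feature extractors behind a registry. The five
full-scale ImageNet architectures are registered as names whose
implementations users supply (`register_backbone`); re-deriving their
internals is explicitly out of scope. The shipped `tiny_test` backbone is
three 3×3-conv/ReLU/2×2-maxpool stages (8→16→32 channels, ~7k parameters)
on the package's own numpy reverse-mode autodiff engine (float64; He
initialisation; Adam). At 32×32 input it trains in seconds on one CPU.

Two-phase schedule: phase 1 optimises only attention + head with the
backbone frozen (the freeze is exact — backbone arrays are bit-identical
afterwards, which the tests assert); phase 2 optimises everything.
Defaults are Adam with 1e−3 (phase 1) and 1e−5 (phase 2), the usual
transfer-learning convention of a much smaller fine-tuning rate; the
from-scratch tiny backbone benefits from a larger phase-2 rate, which
desk-scale configs set explicitly. Loss is softmax cross-entropy with
optional per-class weights applied per sample, so a minority sample's loss
contribution exceeds a majority sample's by exactly the weight ratio. The
validation score recorded for the ensemble is **macro-F1**: the
downstream weighting needs one scalar per classifier that is sensitive to
minority-class performance, which micro-F1 (= accuracy) is not.

## Ensembling

`λ_i = F1_i/ΣF1 + (F1_i − mean F1)·n`. The difference terms sum to zero
analytically, so Σλ = 1 for every n (1e−12 numerically, which the tests
assert over random draws). For large n, below-mean classifiers get
negative weights; the formula is applied verbatim and a warning is
emitted — fused rows may then leave [0, 1], but the argmax stays defined.
Argmax ties break to the lowest grade (the less severe call). The
amplification search evaluates the coarse grid 10–100 (step 10) and the
fine grid 1–10 (step 1), maximising macro-F1 with accuracy as tie-breaker
and smaller n preferred; the pipeline scores the search on the
**validation** set to keep the test set untouched. Macro-F1 with an
accuracy tie-break is also what makes the search stable on skewed data,
where accuracy alone is dominated by grade 0.

## Metrics

All scores derive from the confusion matrix via one-vs-rest counts.
Vanishing denominators (a class never predicted, or absent) give 0 —
conservative, and different from raising. ACA is the mean of the
row-normalised diagonal and requires every true class present; macro-F1 is
the unweighted mean of per-class F1; micro-F1 pools the one-vs-rest counts
and equals accuracy exactly for single-label multiclass (asserted as an
identity test). AUC is one-vs-rest with midrank ties by the rank-sum
identity, macro-averaged; it is undefined (raised) when a class has no
positives or no negatives. The tabular report prints a per-class
"Accuracy" row that repeats recall — the conventional per-class accuracy
in grading reports — while the Overall column carries the global accuracy;
display rounds to 4 decimals, CSV keeps full precision.

## Synthetic data

`make_fundus` emulates only the geometry the pipeline depends on: a frame
of per-pixel intensity 0–6 (strictly below the trim threshold), a bright
ellipse with random eccentricity (so non-square trimming paths are
exercised), fundus-like channel ratios, and optional bright lesion blobs.
For labelled sets, grade g gets disc intensity 60 + 35g and about 2g
lesions — a proxy that makes classes learnable by a tiny model, not a
claim about pathology. Default canvas is 96 px with an 8 px border; the
end-to-end tests use 48 px canvases, 32 px network inputs and class counts
of a few dozen, sizes chosen so a full run finishes in seconds while still
exercising every stage. Synthetic classifiers for ensemble tests predict
the true class with probability `skill` and spread `1 − concentration` of
the mass uniformly.

Consequently, passing tests demonstrate the correctness of the arithmetic,
the contracts and the end-to-end plumbing — not clinical performance.
Real fundus photographs differ in essentially every photometric respect
(illumination gradients, vessel structure, lesion morphology, camera
artefacts), and the reported scores of full-scale GPU-trained ensembles on
real data are out of this package's scope.

## Numerical conventions

- Images are uint8 RGB end to end; grayscale promotes to 3 channels.
- Rotation and resize interpolate bilinearly; rotated output is rounded
  and clipped back to uint8 (tests allow ±2 intensity levels on
  rotation-invariant fixtures).
- The autodiff engine uses float64; max-pool gradients follow the argmax,
  reduction-max gradients split evenly across ties.
- All randomness flows through `numpy.random.Generator` seeds; the
  pipeline derives per-stage seeds from one root seed via `SeedSequence`,
  so a run is reproducible end to end.
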