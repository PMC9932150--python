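# Methods

This note documents the models, parameters and design decisions behind
`mammotv`, and what its tests do and do not demonstrate.

## Problem setting

Input is a square 8-bit grayscale mammogram ROI patch, labelled normal,
benign or malignant, with a background-tissue type (D dense-glandular,
F fatty, G fatty-glandular). The pipeline classifies patches by
(1) extracting deep features from three frozen CNN branches, (2) reducing
them with an unsupervised variance filter applied in two stages, and
(3) training a multiclass SVM on stratified holdout splits.

## Frozen CNN feature extraction

Three branches are tapped as frozen feature extractors:

| branch key | style | input | tap | features |
| --- | --- | --- | --- | --- |
| `inception_v3` | parallel-branch Inception modules | 299×299×3 | global average pool | 2048 |
| `resnet50` | bottleneck residual stages | 224×224×3 | global average pool | 2048 |
| `alexnet` | 5 conv + 3 FC stack | 227×227×3 | penultimate FC ("fc7") | 4096 |

The implementations are compact numpy forward passes that preserve each
family's topology style, native input geometry, tap-layer type and tap
dimensionality, with reduced mid-network depth/width so that extracting
features for the full 416-patch dataset takes on the order of a minute per
branch on one CPU. Weights are He-normal, drawn once from a fixed
`weight_seed` and frozen, so extraction is a pure function of the patch:
repeated runs are bit-identical, and results are independent of batch size
because images are evaluated one at a time. Patches are scaled to [0, 1],
replicated to three channels and bilinearly resized; no further
normalisation is applied in `random_init` mode (random weights carry no
training-data convention). The `imagenet_pretrained` weight mode is
accepted by the configuration type but raises: no pretrained weight set
ships with the package, and none of the package's contracts depend on one —
random frozen convolutional features act as a nonlinear random projection,
which is sufficient to carry the synthetic class signal through the
pipeline.

Feature dimensionality (2048/2048/4096, fused 8192) is architectural: it
depends on neither weights nor input content, which is why the dimensional
test suite runs on ten small patches.

## Term-Variance selection

TV scores column j of the N×M feature matrix by its **population** variance
(divisor N, exactly as the score is defined):

    TV(f_j) = (1/N) Σ_{i=1..N} (f_ij − f̄_j)².

Scores are accumulated in float64 on the float32 feature values. Ranking is
by descending score with ties broken by ascending original column index —
the tie-break makes every ranking, and hence the whole cascade,
deterministic. Useful consequences that the property tests exercise:
scaling a column by c scales its score by c², shifting leaves it unchanged,
and permuting rows changes nothing.

The cascade:

* **stage 1** — per branch, keep the top 1500 (`inception_v3`),
  600 (`resnet50`) and 1400 (`alexnet`) columns, then concatenate in that
  order: 3500 columns. The per-branch counts are configuration defaults
  (`SelectionPlan`), not derived quantities.
* **stage 2** — recompute TV on the fused 3500-column matrix (a fresh
  ranking, not a reuse of stage-1 scores) and keep the top 600.
* **subset sweep** — rank-prefixes of the stage-2 ordering at widths
  100, 200, …, 600; prefixes are nested by construction.

No feature standardisation is applied before TV: scaling would change the
variance ranking, and the method is defined on raw extracted features. TV is fitted on the full
feature matrix before splitting, matching the pipeline order
extraction → selection → split → SVM; the score is unsupervised, so no
label information leaks into the selection.

## Classification and evaluation

* **Splits** — stratified holdout at 70/80/90 % training. Per class,
  ⌊fraction·n⌋ shuffled members go to train, the remainder to test, so both
  partitions preserve the 300/66/50 imbalance up to rounding (at 70 %:
  291 train / 125 test). One seeded generator, classes processed in fixed
  order: deterministic.
* **MSVM** — `sklearn.svm.SVC`, i.e. one-vs-one binary decomposition;
  linear kernel and C = 1 by default (kernel and C are config). Linear is
  the standard choice on high-dimensional deep features and adds no kernel
  hyperparameter. Per-class continuous scores for ROC come from the
  one-vs-rest aggregation of the one-vs-one decision values.
* **Metrics** — per class via one-vs-rest reduction of the 3×3 confusion
  matrix (TP = diagonal cell, FN = rest of row, FP = rest of column,
  TN = remainder): recall, specificity, precision, F1 and per-class
  accuracy; overall accuracy is trace/total. AUC is computed by the
  rank-sum (Mann–Whitney) formulation with average ranks, so tied
  positive/negative pairs count half. A zero-denominator metric is reported
  as NaN and listed in the report's `undefined` field — never silently 0,
  which would corrupt averages. Reported values are percentages, rounded to
  two decimals only at serialisation.
* **Aggregation** — unweighted arithmetic means per tissue, per class, or
  overall. The accuracy table reports both the mean over {D, F, G, All} and
  over {D, F, G}, labelled `Avg_CA_all_subsets` and `Avg_CA_DFG`, since
  either averaging convention is defensible.

## Synthetic fixtures

The generator emulates the structure of the MIAS patch dataset, not its
appearance:

* **counts** — default (tissue × class) cells D = 100/23/17, F = 100/23/17,
  G = 100/20/16: 416 patches, 300/66/50 by class.
* **texture** — band-limited Gaussian noise with per-tissue power-spectral
  slope (D 3.0, G 2.4, F 1.8) and base gray level (150/115/85, σ = 18
  gray levels), giving the tissue subsets distinguishable second-order
  statistics without any biological claim.
* **lesions** — additive bright blobs with radial profile
  `A·exp(−(d/r)^s)`. Benign: smooth round profile (A = 35, r ∈ [18, 30] px
  at side 256, s = 2). Malignant: brighter, sharper and spiculated —
  the radius is modulated by 9 angular lobes of depth 0.45
  (A = 55, r ∈ [14, 26] px, s = 3). Amplitudes are multiplied by the
  spec's `separability`; at 0 the classes are statistically identical, and
  at 3 the lesion amplitude is ≈ 3× the texture σ ("high separability").
* **determinism** — one integer seed drives a single generator; equal specs
  give pixel-identical patches. Pixels are clipped to 8-bit [0, 255],
  matching PGM conventions.

On disk, fixtures use binary PGM (P5) plus a metadata file in the MIAS Info
dialect (`refnum tissue NORM` or `refnum tissue CODE B|M x y radius`, with
`y` measured from the bottom-left corner), so the `mias` module's parser and
patch extractors exercise the same code paths real data would.

What passing tests show: the pipeline recovers class structure that the
generator injects (accuracy > 90 % at high separability), does no better
than the majority rate when no signal exists (binomial band around 72.1 %),
and degrades or holds when components are ablated. What they do not show:
performance on real mammograms — the fixtures have none of the appearance,
compression artefacts, annotation noise or inter-patient variability of
clinical data.

## MIAS data handling

* The Info-file `y` coordinate uses a bottom-left origin; row index is
  `height − 1 − y`. The conversion is explicit because a silent axis flip
  is the classic failure mode with this metadata.
* ROI crops are fixed-size squares centred on the annotated abnormality;
  crops that would overlap the border are shifted inward (never padded), so
  every patch pixel is real tissue. The annotated radius is parsed but not
  used for crop sizing — inputs to fixed-size networks want fixed-size
  patches (default side 256).
* Normal images get uniformly random fully-inside crops; candidates with
  mean intensity below a threshold (default 20/255 gray levels) are
  rejected to avoid empty border regions, with a bounded number of draws.
  The number of normal patches per normal image is configurable (default 1):
  the canonical 300-normal-patch count implies more than one patch from
  some normal images, and the exact scheme is a user decision.
* The parser is strict: abnormal entries must carry severity, centre and
  radius (7 fields). Real MIAS metadata contains a handful of abnormal
  lines without coordinates; these are rejected rather than guessed at —
  a known limitation.
* PGM reading accepts P5 and P2, 8-bit only (`maxval > 255` is a format
  error); payload decoding is delegated to Pillow.

## Ablation harness

Each study removes exactly one component while everything else stays fixed:
`wo_inception_v3`, `wo_resnet50`, `wo_alexnet` (the two remaining blocks go
through stage-1 TV, fusion and a stage-2 top-600) and `wo_tv` (all 8192 raw
features straight to the MSVM), plus the unmodified baseline. Studies share
one feature extraction, so ablation accuracy differences are attributable to
the removed component, not to re-extraction noise.

## Problem sizes and numerical choices

* Unit and property tests run on 10–30 patch fixtures at patch side 64
  (feature widths are architectural, so nothing is lost); the end-to-end
  recovery tests and the acceptance script use the full 416-patch
  distribution at patch side 256.
* Features are float32; TV scores and metrics are float64. The TV oracle
  tests compare against a naive two-pass variance to 1e-12 relative error
  on identical float32 inputs.
* SVM fitting is deterministic given the data (libsvm's optimiser has no
  randomised step at these sizes), which the identical-seed → identical
  run-record test relies on.
* Degenerate inputs fail loudly: empty patch lists, single-class training
  sets, classes with fewer than two members, out-of-range top-k, misaligned
  feature blocks and non-finite features all raise typed errors.

## Known limitations

* Random frozen weights are not pretrained weights: absolute accuracies on
  real mammograms would differ, and no claim is made about them.
* The compact branch topologies preserve family style and tap geometry, not
  layer-for-layer fidelity to the canonical 48/50-layer networks.
* The strict metadata parser rejects the few coordinate-free abnormal lines
  present in the real MIAS Info file.
* Single holdout splits only (by design): no cross-validation, calibration,
  or cost-sensitive training.
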