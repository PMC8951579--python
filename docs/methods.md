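# Methods

This note documents the models and procedures implemented in `lungreport`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data does and does not establish.

## Feature schema

A nodule is represented by 113 named real-valued features: the 107
default features of the standard radiomics extractor (first-order
intensity 18, shape 14, GLCM 24, GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14)
and 6 SISN features. We adopt the extractor's default feature *names*
(`original_firstorder_Mean`, `original_glcm_Contrast`, …) so that real
CSV exports load without renaming; the feature *formulas* are explicitly
out of scope — this package consumes feature tables, it does not compute
radiomics from images. Nodule size (`size_mm`, longest diameter in mm) is
a first-class column rather than a value derived from the shape features,
because its derivation in the source workflow is not specified. Missing
feature values are an error, never imputed: the upstream extractor
produces complete vectors, and silent imputation would mask misaligned
columns.

### SISN features

SISN ("slice information of segmentation of nodules") summarizes which
axial slices of the segmentation stack contain the nodule. The source
workflow names only one of its six features — the ratio of labeled slices
to total slices — and motivates them as indicating nodule location. The
remaining five shipped here are a documented reconstruction: the minimal
slice-position statistics `first`, `last`, `centroid` (area-weighted),
`span` (envelope), and `peak` (max-area slice, ties to the lowest index).
All six use 0-based indices divided by the total slice count, keeping
every value in [0, 1] on the same scale as the ratio. Consequences worth
knowing: `ratio ≤ span`, with equality iff the labeled run has no gaps,
and the centroid is area-weighted so it need not be the run's midpoint.

## Multi-objective classifier

Three per-task towers share one standardized input and are trained
jointly by a single optimization loop minimizing the *sum* of the three
cross-entropy losses. This realizes "multi-objective" in the weakest
assumption-free form: the towers share no weights (the wiring diagram of
the source architecture does not determine any sharing), but the tasks
are coupled through joint optimization and a shared input representation.

Architecture per tower: `dense(64) → σ → dropout → dense(32) → σ →
dropout → dense(k) → softmax`, σ = tanh for Location and Texture, ReLU
for Margin. Location consumes 113 inputs, Texture and Margin 107
(radiomics only). Fixed by the source description: the activations, the
input widths, Location dropout (0.35, 0.25), Texture dropout
(0.25, 0.15), batch size 32, 50 epochs, RMSprop. Our choices where the
source is silent:

- **Hidden widths (64, 32).** Unstated; chosen small enough that a
  458-fold LOOCV runs at desk scale. Configurable per tower.
- **Margin dropout (0.25, 0.15).** Unstated; defaults to Texture's rates.
- **Categorical cross-entropy.** The printed loss is the binary form; we
  use the categorical generalization per task (they coincide at k = 2),
  with predictions clipped to [ε, 1−ε], ε = 1e-7, so log 0 cannot occur.
- **z-score standardization** (fit on the training split only). The
  source is silent; raw radiomics magnitudes span orders of magnitude and
  saturate tanh, so some normalization is required for the stated
  activations to train at all.
- **Inverted dropout** (scale by 1/keep at train time), so inference is a
  plain deterministic forward pass; the expectation of a training-mode
  layer output equals the inference activation, a property the test suite
  checks by Monte Carlo.
- **RMSprop: learning rate 1e-3, decay 0.9, ε = 1e-8.** Standard defaults;
  the source gives none.
- **Glorot-uniform initialization, zero biases,** from a seeded generator:
  training is bit-reproducible from `(config, seed)`.
- **Ties at argmax** break toward the first class in canonical vocabulary
  order (so an all-uniform model predicts RUL / Solid / Sharp
  Circumscribed).

Backpropagation is explicit numpy; analytic gradients are verified
against central finite differences (relative error < 1e-4) for both
activation types in the test suite. The output-layer gradient uses the
standard softmax/cross-entropy form, which ignores the loss clipping;
the clip is inactive unless a probability reaches the 1e-7 floor, where
the true gradient is zero on the clipped side — the discrepancy can only
shrink steps taken from numerically saturated predictions.

## Lung-RADS rule engine

Categories 2, 3, 4A, 4B are assigned by an ordered rule table over
(texture set, margin set or wildcard, half-open size interval [lo, hi)).
Load-time validation enforces **totality** (every texture × margin ×
positive size matches some rule; checked exhaustively by probing one size
per cell of the partition induced by all rule boundaries, plus the
boundaries themselves) and **determinism** (overlapping rules must agree
in category; first match wins). The shipped default encodes: texture
decides the branch; margin matters only for subsolid nodules, split into
benign-leaning (sharp circumscribed, lobulated) versus suspicious
(spiculated, indistinct) margins; sizes use the ACR v1.1 baseline
cut-offs (solid: 6/8/15 mm; pure GGO: 30 mm; subsolid benign-branch 6 mm,
suspicious-branch 8 mm). The subsolid branch's category-per-size-bin
assignment is our interpretation — the source describes the branch
criteria but not the resulting categories — and the exact thresholds are
not printed there either, which is precisely why the table ships as data.
Boundary semantics: a size exactly at a cut-off belongs to the upper
category (half-open intervals, matching the "≥" phrasing of the ACR
thresholds). Categories 0, 1, 4X and S are out of scope: they need prior
exams or solid-component measurements this pipeline does not produce.

## Report templating

Templates are plain text with `{slot}` placeholders over six known slots
(location, texture, margin, size_mm, category, record_id), validated at
load time; rendering is `str.format` substitution through an English
surface-form lexicon shipped as a YAML data file (lobes render with their
abbreviation, e.g. "right upper lobe (RUL)"; size renders as "12.0 mm";
category as "4A"). Rendering is deterministic and total on complete
contexts. One nodule produces one report; multi-nodule studies are
concatenations upstream. The original system's template wording is not
public, so the shipped templates are our own, pinned by golden tests.

## Evaluation

Metrics are computed from one-vs-rest confusion counts with the
conventions P = 0 when TP+FP = 0, R = 0 when TP+FN = 0, F1 = 0 when
P = R = 0. Macro averages run over the classes *present in gold* —
on small folds a never-occurring class would contribute an undefined row.
LOOCV trains n models, each with a per-fold seed derived deterministically
from (base seed, fold index) via a seed sequence, and pools the n held-out
predictions into a single confusion matrix per task. ROC curves sweep
distinct score thresholds with ties grouped (tied scores move the curve
diagonally), and AUC is the trapezoid area, which equals the Mann–Whitney
U statistic normalized by n₊·n₋ with half credit for ties; the test suite
verifies both this identity and exact agreement with scikit-learn on
randomized fixtures.

## Synthetic cohort generator

The generator's defaults state the study conditions: n = 458 single
nodules, diameters truncated below 30 mm, 5 mm slice thickness, 0.618 mm
pixel pitch, 6/3/4-way vocabularies. Where the source states nothing, the
defaults are fixed once: uniform location and texture priors (the real
class frequencies are unpublished); margin priors conditional on texture
with solid nodules leaning toward spiculated/indistinct margins
(configurable to independence); log-normal sizes with log-mean 2.0 and
log-SD 0.6 (median ≈ 7.4 mm, right-skewed, a realistic screening-size
distribution) truncated at 30 mm by rejection; a 60-slice stack.

Radiomics features follow a block-prototype model: each task owns a
disjoint block of the 107 radiomics dimensions in registry order
(texture → intensity+GLCM, margin → shape+GLDM, location →
GLRLM+GLSZM+NGTDM), split into one contiguous sub-block per class; a
record's class shifts its sub-block by the effect size δ (default 3, in
units of the noise SD) on top of i.i.d. Gaussian noise. This makes the
Bayes rule nearest-prototype, with a Monte-Carlo Bayes-error estimator
shipped for calibration; at δ = 3 the per-task Bayes error is far below
1%. SISN features are computed — through the same code path users apply
to real masks — from a simulated contiguous axial run whose extent is
`ceil(size/thickness)` slices, placed inside a location-dependent band of
the stack (the stack splits into six bands in label order), with a
unimodal per-slice area profile.

**What a green test establishes, and what it does not.** The generator
produces linearly separated, isotropic-noise features with no
inter-feature correlation, no class imbalance by default, and no
radiomics realism; passing parameter-recovery tests establishes that the
training loop, data plumbing and evaluation are correct, *not* that the
classifier would reach any particular accuracy on clinical data. The
published headline performance is explicitly not reproducible here: it
requires the private cohort.

**The δ = 0 case.** Setting δ = 0 removes all class signal from the
radiomics features, so Texture and Margin predictions must sit at chance
(the tests assert accuracy within four binomial standard errors of 1/k
and macro-F1 below the corresponding band). Location does *not* fall to
chance: the SISN features encode the nodule's axial band by construction —
they exist precisely because slicing information indicates lobe — so at
δ = 0 the tests assert Location stays significantly *above* chance. This
is a property of the stated world, not a defect: a location-independent
placement would contradict the generator's contract.

## Numerical and degenerate-input choices

- Cohort CSV round-trips bitwise: values serialize with shortest-exact
  float repr and parse with pandas' `round_trip` float precision.
- Standardization guards zero-variance columns (SD 0 → 1).
- Softmax subtracts the row max before exponentiation.
- `validate_record` reports violations rather than raising; a size at or
  beyond 30 mm is a warning (user data may exceed the study bound), while
  missing/non-finite features and out-of-range SISN values are errors.
- Empty cohorts, unlabeled records, single-record LOOCV, empty masks and
  nonpositive sizes all raise with specific messages rather than
  propagating NaNs.

## Known limitations

- No image processing: DICOM ingestion, segmentation and the 107
  radiomics formulas are upstream concerns (the schema guarantees name
  compatibility with the standard extractor's defaults).
- The five unnamed SISN features are a surrogate reconstruction; only the
  labeled-slice ratio is guaranteed to match the source system.
- The default rule table interprets the subsolid branch; users with the
  authors' exact system should supply their own YAML.
- The three towers share no parameters; if the original architecture
  shared trunk layers, per-task capacity here differs from it.
- Single-nodule reports only; no growth assessment across timepoints, no
  categories 0/1/4X/S.
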