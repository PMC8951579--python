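# lungreport

Automatic structured radiology reporting for single lung nodules on
low-dose CT, from precomputed radiomics features. The package is aimed at
medical-imaging informatics groups who already run a radiomics extractor
over segmented nodules and want the downstream half of the pipeline:
semantic labeling, Lung-RADS categorization, and controllable report text —
plus a synthetic-cohort generator so the whole chain can be developed and
validated without access to protected patient data.

## What it does

Given a 113-dimensional feature vector per nodule — the standard
extractor's 107 default radiomics features (first-order intensity, shape,
GLCM, GLRLM, GLSZM, NGTDM, GLDM) plus 6 SISN features (slice information
of segmentation of nodules, summarizing which axial slices contain the
nodule) — the pipeline:

1. **Predicts three semantic labels** with a jointly trained
   multi-objective MLP: Location (RUL, RML, RLL, LUL, LLL, lingular lobe),
   Texture (solid, subsolid, pure GGO) and Margin (sharp circumscribed,
   lobulated, indistinct, spiculated). Each task has its own tower
   `dense(64) → σ → dropout → dense(32) → σ → dropout → dense(k) → softmax`
   over a z-scored input; σ = tanh for Location and Texture, ReLU for
   Margin. The Location tower consumes all 113 dimensions (the SISN
   features carry axial position); Texture and Margin use the 107
   radiomics dimensions. Towers are trained jointly by minimizing the
   summed categorical cross-entropy

   L = Σ_tasks −Σ_c y_c log ŷ_c,  ŷ = softmax(M F + b)

   with RMSprop, batch size 32, 50 epochs, inverted dropout
   ((0.35, 0.25) for Location, (0.25, 0.15) for Texture and Margin).

2. **Assigns a Lung-RADS category** (2, 3, 4A, 4B) through an ordered rule
   table over (texture, margin, size). The shipped default transcribes the
   ACR Lung-RADS v1.1 baseline size cut-offs; the table is YAML data,
   validated at load time for totality and determinism, so a revision of
   the standard is a config edit.

3. **Renders report text** by deterministic slot filling of `{slot}`
   templates through an English surface-form lexicon.

Evaluation utilities implement one-vs-rest precision/recall/F1
(P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R)), macro-averaging over
classes present in gold, leave-one-out cross-validation with pooled
held-out predictions, and tie-aware ROC/AUC.

Because the original cohort is available only on request, the
`synthetic` module generates labeled stand-in cohorts matching the stated
study conditions (458 single-nodule cases, diameters < 30 mm, 5 mm slices,
0.618 mm pixel pitch) with auditable class-conditional structure; see
`docs/methods.md` for exactly what it does and does not emulate.

## Worked example

```python
from lungreport import (GeneratorConfig, ModelConfig, PipelineConfig,
                        build_default_registry, run_end_to_end)

config = PipelineConfig(
    generator=GeneratorConfig(n=10, effect_size=5.0),
    model=ModelConfig(epochs=40),
    out_dir="pipeline_output",
    seed=7,
)
manifest = run_end_to_end(config)
```

prints nothing but writes `pipeline_output/`; `examples/07_end_to_end.py`
then reports:

```
records processed: 10
outputs: ['predictions.csv', 'reports/syn-000.txt', ...]
--- syn-000.txt ---
A 3.0 mm solid nodule with lobulated margin in the left upper lobe (LUL). Lung-RADS 2.
```

i.e. the predicted texture/margin/location, the measured size, and the
rule-table category for a 3.0 mm solid nodule (below the 6 mm cut-off,
hence Lung-RADS 2). A cross-validated accuracy check
(`examples/06_loocv_evaluation.py`, 100 records, 10 epochs per fold):

```
folds run: 100 (one per record)
overall macro F1: 0.9403
  location  macro P=0.921 R=0.912 F1=0.911 AUC=0.991
  texture   macro P=1.000 R=1.000 F1=1.000 AUC=1.000
  margin    macro P=0.917 R=0.905 F1=0.910 AUC=0.990
```

High scores here reflect the generator's default class separation (3
noise-SD between prototypes), not clinical performance; the numbers fall
toward chance as `effect_size` is reduced.

The other scripts in `examples/` each demonstrate one capability:
cohort simulation and CSV round-trip, SISN features from a segmentation
phantom, model training and prediction, rule-table lookups, and template
rendering.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package from scratch and writes the recomputed structural
quantities as JSON: the record count of the default synthetic cohort
(with its size bound asserted) and the number of folds executed by the
leave-one-out cross-validation harness on it, using a reduced-epoch model
configuration so the full run finishes in well under a minute.

## Layout

- `src/lungreport/schema.py` — vocabularies, 113-feature registry, cohort I/O
- `src/lungreport/synthetic.py` — cohort generator and segmentation phantoms
- `src/lungreport/sisn.py` — SISN slice-position features
- `src/lungreport/model.py` — the three-tower multi-objective MLP
- `src/lungreport/lungrads.py` — rule engine + shipped v1.1 default table
- `src/lungreport/reporting.py` — templates and surface forms
- `src/lungreport/evaluation.py` — metrics, ROC, LOOCV
- `src/lungreport/pipeline.py` — `run_end_to_end`
- `docs/methods.md` — model, assumptions, parameter choices, limitations
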