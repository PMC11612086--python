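# sectorvit

Predicting postoperative renal-function decline from multimodal data with a
sector-split vision transformer.

After partial or radical nephrectomy for renal-cell carcinoma, a fraction of
patients lose a clinically meaningful amount of kidney function.  `sectorvit`
implements a transformer classifier that predicts whether a patient's
estimated glomerular filtration rate (eGFR) will fall by more than a
threshold (ΔeGFR > 10 or > 20 mL/min/1.73 m²), fusing inputs of very
different shapes and sizes: clinical variables, radiomic features of the
tumor, and CT-derived image crops.

The model splits a concatenated 1-D input by fixed *sector* lengths
{a₁, …, a_N} — class token (0), demographics (3), comorbidities (3), habits
(2), surgical variables (6), selected radiomics (32), and two flattened
128×128 crops (tumor; kidney + tumor).  Each sector runs through its own
patch embedding, learned class token, pre-norm transformer encoder
(multi-head self-attention + GELU MLP blocks with residual connections), and
an MLP head with softmax; the model's probability is the mean of the sector
probabilities ("voting").  Sector contribution is measured by permutation
feature importance: reassign one sector's data between patients, re-evaluate
patient-level accuracy, repeat 100×, and compare sectors with Mann-Whitney U
tests.  The full evaluation suite (accuracy, sensitivity, specificity, PPV,
NPV, F-score, AUC-ROC, log-loss, kappa with bootstrap CIs; McNemar and
DeLong model comparisons) is included.

The entire model — forward pass, analytic backpropagation, Adam — is NumPy;
there is no deep-learning-framework dependency.  A synthetic cohort
generator (clinical table, CT-like slices with kidney/tumor masks, eGFR
outcomes with controllable per-sector effect sizes) makes the pipeline fully
testable end-to-end without any data download.  See `docs/methods.md` for
the model, conventions, and design choices.

## Worked example

Run the full pipeline on a synthetic 60-patient cohort with a strong planted
surgical effect:

```bash
python - <<'PY'
import json
from pathlib import Path
from sectorvit.pipeline import default_config, run_pipeline

cfg = default_config(seed=1)
# plant the signal in the surgical sector only
cfg["sim"].update(surgical_beta=30.0, radiomic_beta=0.0,
                  image_beta=0.0, demographic_beta=0.0)
run_pipeline(cfg, ["simulate", "prepare", "radiomics", "select",
                   "train", "evaluate", "importance"], "run1")
metrics = json.loads(Path("run1/evaluate/metrics_patient.json").read_text())
print({k: round(v["value"], 3) for k, v in metrics.items()})
print(Path("run1/importance/summary.json").read_text())
PY
```

On this seed the patient-based test report prints

```
{'accuracy': 0.929, 'sensitivity': 0.857, 'specificity': 1.0, 'ppv': 1.0,
 'npv': 0.875, 'f_score': 0.923, 'auc_roc': 1.0, 'log_loss': 0.69,
 'kappa': 0.857}
```

and the importance summary ranks the surgical sector first with a mean
accuracy drop of 0.44 (95% CI 0.41-0.47) while every other sector's drop is
exactly zero — the pipeline recovers the planted signal: the label was
constructed to depend only on the surgical variables (radical nephrectomy
and ischemia time), so permuting that sector destroys the accuracy and
permuting any other changes no prediction.  The log-loss stays near ln 2 by
construction: with eight voting sectors the voted probability is pulled
toward 0.5 even when the ranking is perfect.

The same stages are available on the command line (`sectorvit run --seed 1
--out run1`, or stage-by-stage: `sectorvit simulate|prepare|radiomics|
select|train|evaluate|importance|compare`).  To analyse a real cohort,
place the documented clinical CSV and per-patient slice arrays in the
simulate-stage layout and run the remaining stages;
`imaging.iter_nifti_slices` converts NIfTI volumes with {0 background,
1 kidney, 2 tumor} segmentation labels into those slice arrays.

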