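"""Clinical cohort handling: labels, exclusion criteria, balancing, splitting.

The prediction target is the postoperative drop in estimated glomerular
filtration rate, delta-eGFR = preoperative - postoperative (positive =
deterioration), binarised at a threshold of 10 or 20 mL/min/1.73 m^2.

Patients flow through four exclusion criteria applied in order:

(i)   missing any of the 14 clinical fields (after setting ischemia time to 0
      for radical nephrectomy, where no residual kidney is clamped);
(ii)  missing pre- or postoperative eGFR;
(iii) no CT slice whose tumor annotation has at least 256 pixels;
(iv)  usable-slice count outside mean +/- SD (sample SD, inclusive bounds)
      computed over patients surviving (i)-(iii);

followed by (v) random removal of patients then individual slices from the
image-majority class until the two classes hold equally many images.
Train/test splitting is stratified by label and always per patient, never
per slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: clinical fields checked by exclusion criterion (i)
CLINICAL_FIELDS = [
    "age", "sex", "bmi",
    "pvd", "diabetes", "liver_disease",
    "smoking", "alcohol",
    "ischemia_time", "blood_loss", "surgery_type", "procedure", "approach",
    "operative_time",
]

CSV_COLUMNS = ["patient_id"] + CLINICAL_FIELDS + ["pre_egfr", "post_egfr"]

CATEGORIES = {
    "sex": ["male", "female"],
    "smoking": ["current", "previous", "never"],
    "alcohol": ["more_than_two_daily", "two_or_fewer_daily", "never_or_not_3mo"],
    "surgery_type": ["robotic", "open", "laparoscopic"],
    "procedure": ["partial_nephrectomy", "radical_nephrectomy"],
    "approach": ["transperitoneal", "retroperitoneal"],
}

MIN_TUMOR_PIXELS = 256


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    sex: str
    bmi: float
    pvd: bool
    diabetes: bool
    liver_disease: bool
    smoking: str
    alcohol: str
    ischemia_time: float
    blood_loss: float
    surgery_type: str
    procedure: str
    approach: str
    operative_time: float
    pre_egfr: float
    post_egfr: float
    n_slices: int = 0


@dataclass
class LabeledCohort:
    """Included patients with binary labels and per-patient usable slices."""

    patients: List[PatientRecord]
    threshold: float
    labels: Dict[str, int]
    usable_slices: Dict[str, List[int]]  # patient_id -> usable slice indices
    split: Dict[str, str] = field(default_factory=dict)

    def patient_ids(self) -> List[str]:
        return [p.patient_id for p in self.patients]

    def image_counts(self) -> Tuple[int, int]:
        """(negative-class image count, positive-class image count)."""
        neg = sum(len(self.usable_slices[p.patient_id]) for p in self.patients
                  if self.labels[p.patient_id] == 0)
        pos = sum(len(self.usable_slices[p.patient_id]) for p in self.patients
                  if self.labels[p.patient_id] == 1)
        return neg, pos


def compute_delta_egfr(pre: float, post: float) -> float:
    """delta-eGFR = pre - post; positive values mean renal deterioration."""
    if pre is None or post is None or not np.isfinite(pre) or not np.isfinite(post):
        raise ValueError("pre/post eGFR must be present and finite")
    return float(pre) - float(post)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV missing columns: {missing}")
    return df


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return pd.isna(v)


def apply_exclusions(raw_table: pd.DataFrame,
                     image_index: Mapping[str, Sequence[int]],
                     threshold: float = 10.0):
    """Apply criteria (i)-(iv) and derive labels.

    ``image_index`` maps patient_id to the per-slice tumor-mask pixel counts.
    Returns ``(LabeledCohort, exclusion_log)`` where the log maps each
    criterion to the list of removed patient ids.
    """
    if len(raw_table) == 0:
        raise ValueError("empty clinical table")
    df = raw_table.copy()
    # radical-nephrectomy rule: no residual kidney is clamped, so a missing
    # ischemia time is defined as 0
    rn = df["procedure"] == "radical_nephrectomy"
    df.loc[rn & df["ischemia_time"].isna(), "ischemia_time"] = 0.0

    log: Dict[str, List[str]] = {"i": [], "ii": [], "iii": [], "iv": []}
    survivors = []
    usable: Dict[str, List[int]] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if any(_is_missing(row[f]) for f in CLINICAL_FIELDS):
            log["i"].append(pid)
            continue
        if _is_missing(row["pre_egfr"]) or _is_missing(row["post_egfr"]):
            log["ii"].append(pid)
            continue
        counts = list(image_index.get(pid, []))
        good = [k for k, c in enumerate(counts) if c >= MIN_TUMOR_PIXELS]
        if len(good) == 0:
            log["iii"].append(pid)
            continue
        survivors.append(row)
        usable[pid] = good

    if survivors:
        n_slices = np.array([len(usable[str(r["patient_id"])]) for r in survivors], dtype=float)
        mean, sd = n_slices.mean(), (n_slices.std(ddof=1) if len(n_slices) > 1 else 0.0)
        lo, hi = mean - sd, mean + sd
        kept = []
        for row in survivors:
            pid = str(row["patient_id"])
            if lo <= len(usable[pid]) <= hi:
                kept.append(row)
            else:
                log["iv"].append(pid)
                del usable[pid]
        survivors = kept

    if not survivors:
        raise ValueError(f"all patients excluded; log: {json.dumps(log)}")

    patients, labels = [], {}
    for row in survivors:
        pid = str(row["patient_id"])
        rec = PatientRecord(
            patient_id=pid,
            age=float(row["age"]), sex=str(row["sex"]), bmi=float(row["bmi"]),
            pvd=bool(row["pvd"]), diabetes=bool(row["diabetes"]),
            liver_disease=bool(row["liver_disease"]),
            smoking=str(row["smoking"]), alcohol=str(row["alcohol"]),
            ischemia_time=float(row["ischemia_time"]),
            blood_loss=float(row["blood_loss"]),
            surgery_type=str(row["surgery_type"]), procedure=str(row["procedure"]),
            approach=str(row["approach"]),
            operative_time=float(row["operative_time"]),
            pre_egfr=float(row["pre_egfr"]), post_egfr=float(row["post_egfr"]),
            n_slices=len(usable[pid]),
        )
        patients.append(rec)
        labels[pid] = int(compute_delta_egfr(rec.pre_egfr, rec.post_egfr) > threshold)

    cohort = LabeledCohort(patients=patients, threshold=threshold,
                           labels=labels, usable_slices=usable)
    return cohort, log


def balance_images(cohort: LabeledCohort, rng_seed: int = 0) -> LabeledCohort:
    """Equalize per-class image counts (criterion v).

    Whole patients are removed first from the image-majority class, each
    uniformly chosen among patients whose removal does not overshoot the
    balance; remaining excess is trimmed by removing uniformly chosen
    individual slices.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    neg, pos = cohort.image_counts()
    if neg == 0 or pos == 0:
        raise ValueError("cannot balance: one class has no images")

    patients = list(cohort.patients)
    usable = {k: list(v) for k, v in cohort.usable_slices.items()}
    labels = dict(cohort.labels)

    def counts():
        c = [0, 0]
        for p in patients:
            c[labels[p.patient_id]] += len(usable[p.patient_id])
        return c

    while True:
        c = counts()
        if c[0] == c[1]:
            break
        maj = int(c[1] > c[0])
        excess = c[maj] - c[1 - maj]
        candidates = sorted(p.patient_id for p in patients
                            if labels[p.patient_id] == maj
                            and len(usable[p.patient_id]) <= excess)
        if not candidates:
            break
        drop = candidates[rng.integers(len(candidates))]
        patients = [p for p in patients if p.patient_id != drop]
        del usable[drop]

    c = counts()
    if c[0] != c[1]:
        maj = int(c[1] > c[0])
        excess = c[maj] - c[1 - maj]
        # trim individual slices, never emptying a patient
        for _ in range(excess):
            pool = sorted((pid, k) for pid, sl in usable.items()
                          if labels[pid] == maj and len(sl) > 1 for k in sl)
            if not pool:
                raise ValueError("cannot balance image counts without emptying a patient")
            pid, k = pool[rng.integers(len(pool))]
            usable[pid].remove(k)

    c = counts()
    assert c[0] == c[1], "balancing failed to equalize image counts"
    for p in patients:
        p.n_slices = len(usable[p.patient_id])
    return LabeledCohort(patients=patients, threshold=cohort.threshold,
                         labels={p.patient_id: labels[p.patient_id] for p in patients},
                         usable_slices=usable)


def split_patients(cohort: LabeledCohort, test_fraction: float = 0.265,
                   rng_seed: int = 0) -> LabeledCohort:
    """Stratified-by-label per-patient train/test split.

    No patient's slices straddle the split; per-class test counts are the
    rounded fraction, clipped so both splits keep at least one patient of
    each class.  Patient ids are canonically sorted before sampling so the
    split is invariant to input ordering.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    split: Dict[str, str] = {}
    for cls in (0, 1):
        ids = sorted(pid for pid in cohort.patient_ids() if cohort.labels[pid] == cls)
        if len(ids) < 2:
            raise ValueError(f"need at least 2 patients in class {cls} to split")
        n_test = int(np.clip(round(test_fraction * len(ids)), 1, len(ids) - 1))
        test_ids = set(rng.choice(ids, size=n_test, replace=False))
        for pid in ids:
            split[pid] = "test" if pid in test_ids else "train"
    return LabeledCohort(patients=cohort.patients, threshold=cohort.threshold,
                         labels=cohort.labels, usable_slices=cohort.usable_slices,
                         split=split)


def split_manifest(cohort: LabeledCohort) -> pd.DataFrame:
    """Split manifest: one row per patient (patient_id, split, label)."""
    if not cohort.split:
        raise ValueError("cohort has no split assigned")
    rows = [(pid, cohort.split[pid], cohort.labels[pid])
            for pid in sorted(cohort.patient_ids())]
    return pd.DataFrame(rows, columns=["patient_id", "split", "label"])
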