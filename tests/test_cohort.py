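"""Cohort construction: labels, exclusion criteria, balancing, splitting."""

import numpy as np
import pandas as pd
import pytest

from sectorvit.cohort import (CSV_COLUMNS, LabeledCohort, PatientRecord,
                              apply_exclusions, balance_images,
                              compute_delta_egfr, split_manifest, split_patients)


def make_row(pid, **overrides):
    row = dict(patient_id=pid, age=60.0, sex="male", bmi=30.0, pvd=False,
               diabetes=False, liver_disease=False, smoking="never",
               alcohol="never_or_not_3mo", ischemia_time=15.0, blood_loss=200.0,
               surgery_type="robotic", procedure="partial_nephrectomy",
               approach="transperitoneal", operative_time=240.0,
               pre_egfr=80.0, post_egfr=65.0)
    row.update(overrides)
    return row


def make_table(rows):
    return pd.DataFrame(rows)[CSV_COLUMNS]


def make_cohort(slice_counts_by_label, threshold=10.0):
    """Synthetic LabeledCohort: {label: [n_slices per patient]}."""
    patients, labels, usable = [], {}, {}
    i = 0
    for label, counts in slice_counts_by_label.items():
        for c in counts:
            pid = f"p{i:03d}"
            i += 1
            patients.append(PatientRecord(**{**make_row(pid), "patient_id": pid,
                                             "n_slices": c}))
            labels[pid] = label
            usable[pid] = list(range(c))
    return LabeledCohort(patients=patients, threshold=threshold, labels=labels,
                         usable_slices=usable)


class TestDeltaEgfr:
    @pytest.mark.parametrize("pre,post,expected", [
        (80.0, 65.0, 15.0),
        (70.0, 70.0, 0.0),
        (73.5, 60.5, 13.0),
    ])
    def test_delta(self, pre, post, expected):
        assert compute_delta_egfr(pre, post) == pytest.approx(expected)

    def test_labels_at_both_thresholds(self):
        assert compute_delta_egfr(80.0, 65.0) > 10
        assert not compute_delta_egfr(80.0, 65.0) > 20
        assert not compute_delta_egfr(70.0, 70.0) > 10

    def test_missing_raises(self):
        with pytest.raises(ValueError):
            compute_delta_egfr(float("nan"), 60.0)


class TestExclusions:
    def idx(self, n_patients, pixels=500, n_slices=10):
        return {f"p{i}": [pixels] * n_slices for i in range(n_patients)}

    def test_missing_clinical_field_is_criterion_i(self):
        rows = [make_row(f"p{i}") for i in range(5)]
        rows[2]["operative_time"] = np.nan
        cohort, log = apply_exclusions(make_table(rows), self.idx(5))
        assert log["i"] == ["p2"]
        assert len(cohort.patients) == 4

    def test_rn_missing_ischemia_is_zero_not_excluded(self):
        rows = [make_row("p0", procedure="radical_nephrectomy", ischemia_time=np.nan),
                make_row("p1"), make_row("p2")]
        cohort, log = apply_exclusions(make_table(rows), self.idx(3))
        assert log["i"] == []
        rec = next(p for p in cohort.patients if p.patient_id == "p0")
        assert rec.ischemia_time == 0.0

    def test_pn_missing_ischemia_is_excluded(self):
        rows = [make_row("p0", ischemia_time=np.nan), make_row("p1"), make_row("p2")]
        _, log = apply_exclusions(make_table(rows), self.idx(3))
        assert log["i"] == ["p0"]

    def test_missing_egfr_is_criterion_ii(self):
        rows = [make_row("p0", post_egfr=np.nan), make_row("p1"), make_row("p2")]
        cohort, log = apply_exclusions(make_table(rows), self.idx(3))
        assert log["ii"] == ["p0"]

    def test_small_tumor_slices_only_criterion_iii(self):
        idx = self.idx(3)
        idx["p1"] = [100, 255, 10]  # no slice reaches 256 pixels
        idx["p2"] = [100, 256] + [500] * 8
        rows = [make_row(f"p{i}") for i in range(3)]
        cohort, log = apply_exclusions(make_table(rows), idx)
        assert log["iii"] == ["p1"]
        # p2 keeps only its usable slices
        assert cohort.usable_slices["p2"] == [1] + list(range(2, 10))

    def test_zero_variance_slice_counts_excludes_none(self):
        rows = [make_row(f"p{i}") for i in range(3)]
        cohort, log = apply_exclusions(make_table(rows), self.idx(3, n_slices=10))
        assert log["iv"] == []
        assert len(cohort.patients) == 3

    def test_slice_count_outside_mean_pm_sd(self):
        # counts {5,10,10,10,25}: mean 12, sample SD ~7.58 -> only 25 excluded
        counts = {"p0": 5, "p1": 10, "p2": 10, "p3": 10, "p4": 25}
        idx = {pid: [500] * c for pid, c in counts.items()}
        rows = [make_row(pid) for pid in counts]
        cohort, log = apply_exclusions(make_table(rows), idx)
        assert log["iv"] == ["p4"]
        assert {p.patient_id for p in cohort.patients} == {"p0", "p1", "p2", "p3"}

    def test_exclusion_log_partitions_removals(self):
        rows = [make_row(f"p{i}") for i in range(8)]
        rows[0]["age"] = np.nan
        rows[1]["pre_egfr"] = np.nan
        idx = self.idx(8)
        idx["p2"] = [10]
        cohort, log = apply_exclusions(make_table(rows), idx)
        removed = sum(len(v) for v in log.values())
        assert len(rows) == len(cohort.patients) + removed
        all_removed = [pid for v in log.values() for pid in v]
        assert len(all_removed) == len(set(all_removed))

    def test_empty_table_errors(self):
        empty = pd.DataFrame(columns=CSV_COLUMNS)
        with pytest.raises(ValueError):
            apply_exclusions(empty, {})

    def test_all_excluded_errors_with_log(self):
        rows = [make_row("p0", age=np.nan), make_row("p1", age=np.nan)]
        with pytest.raises(ValueError, match="log"):
            apply_exclusions(make_table(rows), self.idx(2))


class TestBalance:
    def test_already_balanced_unchanged(self):
        cohort = make_cohort({0: [841], 1: [841]})
        out = balance_images(cohort, rng_seed=0)
        assert out.image_counts() == (841, 841)
        assert len(out.patients) == 2

    def test_patient_then_slice_removal(self):
        # positives {6,4} slices vs negatives {6}: dropping the 6-slice
        # positive would overshoot, so the 4-slice one goes, then slices trim
        cohort = make_cohort({1: [6, 4], 0: [6]})
        out = balance_images(cohort, rng_seed=0)
        assert out.image_counts() == (6, 6)
        pos_patients = [p for p in out.patients if out.labels[p.patient_id] == 1]
        assert len(pos_patients) == 1
        assert pos_patients[0].n_slices == 6

    def test_invariant_10_vs_7(self):
        cohort = make_cohort({1: [4, 3, 3], 0: [4, 3]})
        out = balance_images(cohort, rng_seed=3)
        assert out.image_counts() == (7, 7)

    def test_never_increases_counts(self):
        cohort = make_cohort({1: [5, 5, 5], 0: [4, 4]})
        before = cohort.image_counts()
        out = balance_images(cohort, rng_seed=1)
        after = out.image_counts()
        assert after[0] == after[1]
        assert after[0] <= min(before) and after[1] <= max(before)

    def test_deterministic_under_seed(self):
        a = balance_images(make_cohort({1: [6, 4, 3], 0: [5, 2]}), rng_seed=9)
        b = balance_images(make_cohort({1: [6, 4, 3], 0: [5, 2]}), rng_seed=9)
        assert a.usable_slices == b.usable_slices

    def test_one_class_empty_errors(self):
        cohort = make_cohort({1: [5, 5]})
        with pytest.raises(ValueError):
            balance_images(cohort, rng_seed=0)


class TestSplit:
    def test_reference_cohort_split_sizes(self):
        # 102 patients (54 positive / 48 negative: images were balanced, not
        # patients) at fraction 0.265 -> 75 train / 27 test
        cohort = make_cohort({0: [10] * 48, 1: [10] * 54})
        out = split_patients(cohort, test_fraction=0.265, rng_seed=0)
        n_test = sum(1 for v in out.split.values() if v == "test")
        assert (len(out.split) - n_test, n_test) == (75, 27)

    def test_smallest_stratified_case(self):
        cohort = make_cohort({0: [5, 5], 1: [5, 5]})
        out = split_patients(cohort, test_fraction=0.5, rng_seed=0)
        for cls in (0, 1):
            splits = [out.split[p] for p in out.labels if out.labels[p] == cls]
            assert sorted(splits) == ["test", "train"]

    def test_no_patient_straddles_and_sizes_stable_across_seeds(self):
        cohort = make_cohort({0: [8] * 50, 1: [8] * 50})
        a = split_patients(cohort, test_fraction=0.25, rng_seed=1)
        b = split_patients(cohort, test_fraction=0.25, rng_seed=2)
        size = lambda s: sorted(sum(1 for v in s.split.values() if v == w)
                                for w in ("train", "test"))
        assert size(a) == size(b)
        assert a.split != b.split  # different memberships

    def test_order_invariance(self):
        cohort = make_cohort({0: [8] * 10, 1: [8] * 10})
        shuffled = LabeledCohort(patients=list(reversed(cohort.patients)),
                                 threshold=cohort.threshold, labels=cohort.labels,
                                 usable_slices=cohort.usable_slices)
        a = split_patients(cohort, 0.3, rng_seed=5)
        b = split_patients(shuffled, 0.3, rng_seed=5)
        assert a.split == b.split

    def test_too_few_patients_errors(self):
        cohort = make_cohort({0: [5], 1: [5, 5]})
        with pytest.raises(ValueError):
            split_patients(cohort, 0.5, rng_seed=0)

    def test_manifest_columns(self):
        cohort = split_patients(make_cohort({0: [5, 5], 1: [5, 5]}), 0.5, 0)
        man = split_manifest(cohort)
        assert list(man.columns) == ["patient_id", "split", "label"]
        assert len(man) == 4
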