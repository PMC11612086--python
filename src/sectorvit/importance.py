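"""Sector-wise permutation feature importance.

One sector's data is reassigned between patients by a uniformly random
non-identity permutation; the trained model is re-evaluated (patient-based
accuracy) and the drop from the original accuracy is recorded.  Repeating
100 times per sector yields a distribution of accuracy differences whose
mean ranks the sectors; pairwise Mann-Whitney U tests compare sectors.

Because sectors are processed by independent encoders and voting is an
elementwise mean, permuting a sector's patient payloads permutes that
sector's per-slice output probabilities in exactly the same pattern (with
the donor's slice list cycled to the recipient's slice count).  The default
fast path therefore evaluates permutations on cached per-sector
probabilities; it is algebraically identical to permuting the raw data and
re-running the model, which remains available as the direct path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import SectorDataset
from .evaluation import mann_whitney_u
from .training import predict_probs
from .vvit import VvitModel


@dataclass
class ImportanceResult:
    sector: str
    diffs: np.ndarray  # original accuracy - permuted accuracy, one per repeat
    mean: float
    ci_lo: float
    ci_hi: float

    @classmethod
    def from_diffs(cls, sector: str, diffs) -> "ImportanceResult":
        d = np.asarray(diffs, dtype=np.float64)
        se = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else 0.0
        return cls(sector=sector, diffs=d, mean=float(d.mean()),
                   ci_lo=float(d.mean() - 1.96 * se), ci_hi=float(d.mean() + 1.96 * se))


def random_nonidentity_permutation(n: int, rng) -> np.ndarray:
    """Uniform draw over the n!-1 non-identity permutations (rejection)."""
    if n < 2:
        raise ValueError("need at least 2 patients to permute")
    while True:
        perm = rng.permutation(n)
        if not np.array_equal(perm, np.arange(n)):
            return perm


def permute_sector(dataset: SectorDataset, sector: str, rng) -> SectorDataset:
    """Reassign one sector's data between patients; other sectors untouched.

    Patient-level: donor slice lists are reassigned wholesale; when slice
    counts differ, the donor's list is cycled to the recipient's count.  The
    multiset of patient payloads is preserved.
    """
    names = [s.name for s in dataset.sectors]
    if sector not in names:
        raise KeyError(f"unknown sector {sector!r} (have {names})")
    pidx = dataset.patient_index()
    pids = sorted(pidx)
    perm = random_nonidentity_permutation(len(pids), rng)
    out = dataset.copy()
    col = dataset.X[sector]
    new_col = col.copy()
    for i, pid in enumerate(pids):
        donor_rows = pidx[pids[perm[i]]]
        recip_rows = pidx[pid]
        take = donor_rows[np.arange(len(recip_rows)) % len(donor_rows)]
        new_col[recip_rows] = col[take]
    out.X[sector] = new_col
    return out


def patient_accuracy_from_probs(sector_probs: np.ndarray, dataset: SectorDataset) -> float:
    """Patient-based accuracy from per-slice per-sector positive probabilities."""
    voted = sector_probs.mean(axis=1)
    labels = dataset.patient_labels()
    pidx = dataset.patient_index()
    correct = 0
    for pid, rows in pidx.items():
        slice_preds = (voted[rows] >= 0.5).astype(int)
        pred = int(slice_preds.mean() >= 0.5)  # majority, ties -> positive
        correct += int(pred == labels[pid])
    return correct / len(pidx)


def evaluate_patient_accuracy(model: VvitModel, dataset: SectorDataset,
                              batch_size: int = 64) -> float:
    return patient_accuracy_from_probs(predict_probs(model, dataset, batch_size), dataset)


def run_importance(model: VvitModel, test_set: SectorDataset,
                   sectors: Optional[Sequence[str]] = None,
                   n_repeats: int = 100, seed: int = 0,
                   use_cache: bool = True, batch_size: int = 64) -> List[ImportanceResult]:
    """Permutation importance for each sector (patient-based accuracy).

    The original accuracy is computed once; each repeat draws a fresh
    non-identity patient permutation.  ``use_cache=False`` re-runs the model
    on the permuted raw data instead of permuting cached probabilities (same
    result, much slower; kept for verification).
    """
    names = [s.name for s in model.sectors]
    sectors = list(sectors) if sectors is not None else names
    for s in sectors:
        if s not in names:
            raise KeyError(f"unknown sector {s!r}")
    probs = predict_probs(model, test_set, batch_size)
    a0 = patient_accuracy_from_probs(probs, test_set)
    pidx = test_set.patient_index()
    pids = sorted(pidx)
    results = []
    for sector in sectors:
        j = names.index(sector)
        rng = np.random.default_rng(np.random.SeedSequence([seed, j]))
        diffs = np.empty(n_repeats)
        for r in range(n_repeats):
            if use_cache:
                perm = random_nonidentity_permutation(len(pids), rng)
                col = probs[:, j].copy()
                for i, pid in enumerate(pids):
                    donor_rows = pidx[pids[perm[i]]]
                    recip_rows = pidx[pid]
                    take = donor_rows[np.arange(len(recip_rows)) % len(donor_rows)]
                    col[recip_rows] = probs[take, j]
                permuted = probs.copy()
                permuted[:, j] = col
                acc = patient_accuracy_from_probs(permuted, test_set)
            else:
                permuted_ds = permute_sector(test_set, sector, rng)
                acc = evaluate_patient_accuracy(model, permuted_ds, batch_size)
            diffs[r] = a0 - acc
        results.append(ImportanceResult.from_diffs(sector, diffs))
    return results


def compare_sectors(results: Sequence[ImportanceResult]):
    """Pairwise two-sided Mann-Whitney U on the accuracy-difference
    distributions.  Returns (p-value DataFrame, star-annotation DataFrame)."""
    names = [r.sector for r in results]
    P = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    stars = pd.DataFrame("", index=names, columns=names)
    for i, a in enumerate(results):
        for k in range(i + 1, len(results)):
            b = results[k]
            _, p = mann_whitney_u(a.diffs, b.diffs)
            P.iloc[i, k] = P.iloc[k, i] = p
            s = "***" if p < 1e-4 else "**" if p < 1e-3 else "*" if p < 0.05 else ""
            stars.iloc[i, k] = stars.iloc[k, i] = s
    return P, stars


def importance_summary(results: Sequence[ImportanceResult]) -> pd.DataFrame:
    rows = [(r.sector, r.mean, r.ci_lo, r.ci_hi) for r in
            sorted(results, key=lambda r: -r.mean)]
    return pd.DataFrame(rows, columns=["sector", "mean_diff", "ci_lo", "ci_hi"])
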