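"""In-memory dataset container shared by training, evaluation and importance.

A :class:`SectorDataset` holds one row per CT slice: for every sector a
(n_slices, sector_length) matrix, plus the slice's patient id and binary
label.  Clinical sectors repeat a patient's row across their slices; image
and radiomic sectors vary per slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .vvit import SectorSpec


@dataclass
class SectorDataset:
    sectors: List[SectorSpec]
    X: Dict[str, np.ndarray]            # sector name -> (n_slices, length)
    y: np.ndarray                       # (n_slices,) binary slice labels
    patient_ids: np.ndarray             # (n_slices,) patient id per slice

    def __post_init__(self):
        n = len(self.y)
        self.y = np.asarray(self.y)
        self.patient_ids = np.asarray(self.patient_ids)
        for s in self.sectors:
            x = np.asarray(self.X[s.name])
            if x.ndim == 1:
                x = x.reshape(n, -1) if s.length else x.reshape(n, 0)
            if x.shape != (n, s.length):
                raise ValueError(
                    f"sector {s.name!r}: expected shape {(n, s.length)}, got {x.shape}")
            self.X[s.name] = x

    @property
    def n(self) -> int:
        return len(self.y)

    def patient_index(self) -> Dict[str, np.ndarray]:
        """patient id -> slice row indices, in stable order."""
        idx: Dict[str, list] = {}
        for k, pid in enumerate(self.patient_ids):
            idx.setdefault(str(pid), []).append(k)
        return {pid: np.asarray(rows) for pid, rows in idx.items()}

    def patient_labels(self) -> Dict[str, int]:
        out = {}
        for pid, rows in self.patient_index().items():
            labels = set(int(v) for v in self.y[rows])
            if len(labels) != 1:
                raise ValueError(f"patient {pid} has inconsistent slice labels")
            out[pid] = labels.pop()
        return out

    def batch(self, rows) -> Dict[str, np.ndarray]:
        return {s.name: self.X[s.name][rows] for s in self.sectors}

    def subset(self, rows) -> "SectorDataset":
        rows = np.asarray(rows)
        return SectorDataset(
            sectors=self.sectors,
            X={s.name: self.X[s.name][rows] for s in self.sectors},
            y=self.y[rows],
            patient_ids=self.patient_ids[rows],
        )

    def copy(self) -> "SectorDataset":
        return SectorDataset(
            sectors=self.sectors,
            X={k: v.copy() for k, v in self.X.items()},
            y=self.y.copy(),
            patient_ids=self.patient_ids.copy(),
        )
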