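"""PSPI score consolidation into five clinical pain categories.

The Prkachin–Solomon Pain Intensity (PSPI) score is an integer 0–10
composed from facial Action Unit intensities. For classification it is
consolidated into five categories:

    ========== ===== ==================
    PSPI range label clinical descriptor
    ========== ===== ==================
    0          0     No Pain
    1          1     Mid Pain
    2–3        2     Moderate Pain
    4–6        3     Very Pain
    7–10       4     Severe Pain
    ========== ===== ==================

Note the source scale orders "Very Pain" (label 3) below "Severe Pain"
(label 4); the descriptor strings are kept verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES", "N_CLASSES", "consolidate_pspi", "class_weights",
    "FaceRecord", "read_manifest", "write_manifest",
]

CLASS_NAMES = ("No Pain", "Mid Pain", "Moderate Pain", "Very Pain", "Severe Pain")
N_CLASSES = 5

# right-inclusive upper PSPI bound of each label bin
_BIN_UPPER = (0, 1, 3, 6, 10)


def consolidate_pspi(score: int) -> int:
    """Map an integer PSPI score 0–10 to its 5-level pain label.

    Real-valued scores are rejected rather than rounded: the bins are
    defined on integer ranges and rounding would silently resolve
    ambiguous values such as 3.5.
    """
    if isinstance(score, bool) or not isinstance(score, (int, np.integer)):
        raise TypeError(f"PSPI score must be an integer, got {score!r}")
    if not 0 <= score <= 10:
        raise ValueError(f"PSPI score must be in [0,10], got {score}")
    for label, upper in enumerate(_BIN_UPPER):
        if score <= upper:
            return label
    raise AssertionError("unreachable")


def class_weights(label_counts) -> np.ndarray:
    """Inverse-frequency sampling weights, one per class.

    weight_c = total / (n_classes * count_c); sampling classes with these
    weights yields a uniform expected class frequency. A zero count is an
    error — augment or exclude that class first.
    """
    counts = np.asarray(label_counts, dtype=np.int64)
    if counts.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} class counts, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    if (counts == 0).any():
        missing = [CLASS_NAMES[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"classes with zero samples: {missing}; augment these classes or "
            "exclude them before computing sampling weights")
    return counts.sum() / (N_CLASSES * counts.astype(np.float64))


@dataclass
class FaceRecord:
    """One labeled face image.

    ``image_ref`` is either a path to a PNG or an in-memory 64x64x3 float
    array in [0,1]. The consolidated label and descriptor are derived from
    the PSPI score at construction and verified if passed explicitly.
    """

    image_ref: object
    subject_id: str
    pspi_score: int
    label: int = field(default=None)
    class_name: str = field(default=None)
    augmented: bool = False

    def __post_init__(self):
        derived = consolidate_pspi(self.pspi_score)
        if self.label is None:
            self.label = derived
        elif self.label != derived:
            raise ValueError(
                f"label {self.label} inconsistent with PSPI {self.pspi_score} "
                f"(expected {derived})")
        expected_name = CLASS_NAMES[self.label]
        if self.class_name is None:
            self.class_name = expected_name
        elif self.class_name != expected_name:
            raise ValueError(
                f"class_name {self.class_name!r} does not match label "
                f"{self.label} ({expected_name!r})")


def write_manifest(records: list[FaceRecord], path: str | Path,
                   extra_columns: dict[str, list] | None = None) -> pd.DataFrame:
    """Write the manifest CSV (path,subject_id,pspi,label[,augmented,...])."""
    frame = pd.DataFrame({
        "path": [str(r.image_ref) for r in records],
        "subject_id": [r.subject_id for r in records],
        "pspi": [r.pspi_score for r in records],
        "label": [r.label for r in records],
        "augmented": [int(r.augmented) for r in records],
    })
    for name, values in (extra_columns or {}).items():
        frame[name] = values
    frame.to_csv(path, index=False)
    return frame


def read_manifest(path: str | Path) -> list[FaceRecord]:
    """Read a manifest CSV; labels are recomputed and verified if present."""
    frame = pd.read_csv(path, dtype={"subject_id": str})
    required = {"path", "subject_id", "pspi"}
    if missing := required - set(frame.columns):
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        label = int(row.label) if "label" in frame.columns else None
        records.append(FaceRecord(
            image_ref=row.path,
            subject_id=str(row.subject_id),
            pspi_score=int(row.pspi),
            label=label,
            augmented=bool(getattr(row, "augmented", 0)),
        ))
    return records
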