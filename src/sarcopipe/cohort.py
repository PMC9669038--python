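"""Patient/study/series/slice data model and patient-level cross-validation.

The unit of cross-validation is the *patient*: all slices — across every
study, series and sequence — of one patient share a CV group, so no model is
ever evaluated on a patient it trained on. Within each class the splitter
balances total slice counts across groups with a greedy largest-first
heuristic; the sequence composition of groups is deliberately not balanced.
The prediction unit downstream is the examination (study), the split unit is
the patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phantoms import MANIFEST_COLUMNS
from .sequences import SEQUENCE_INDEX, SEQUENCE_TYPES

__all__ = [
    "SliceRecord",
    "CvAssignment",
    "load_manifest",
    "write_manifest",
    "make_cv_groups",
    "split_learn_eval",
]

LABELS = ("sarcoma_group", "leiomyoma")
POSITIVE_LABEL = "sarcoma_group"


@dataclass(frozen=True)
class SliceRecord:
    """One 2-D image slice with its clinical metadata."""

    patient_id: str
    study_id: str
    series_id: str
    sequence_type: str
    slice_index: int
    label: str
    image_path: str
    tumor_bbox: tuple[int, int, int, int]  # half-open (x0, y0, x1, y1)
    phenotype: str = "none"

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE_LABEL

    @property
    def slice_id(self) -> str:
        return f"{self.series_id}:{self.slice_index}"


class ManifestError(ValueError):
    """Raised when a manifest fails validation; the message names the row."""


def load_manifest(path, check_images: bool = True) -> list[SliceRecord]:
    """Load and validate a slice manifest CSV.

    Validation enforces the closed 15-name sequence enumeration, known class
    labels and nonempty in-bounds bounding boxes. When ``check_images`` is
    set and an image file exists, the bbox is additionally checked against
    the actual image dimensions. Paths in the manifest are interpreted
    relative to the manifest's directory.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    base = path.parent
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        where = f"manifest row {i} (patient {row.patient_id})"
        if row.sequence_type not in SEQUENCE_INDEX:
            raise ManifestError(
                f"{where}: unknown sequence type {row.sequence_type!r}; "
                f"allowed: {', '.join(SEQUENCE_TYPES)}"
            )
        if row.label not in LABELS:
            raise ManifestError(
                f"{where}: unknown label {row.label!r}; allowed: {LABELS}"
            )
        bbox = (int(row.bbox_x0), int(row.bbox_y0), int(row.bbox_x1), int(row.bbox_y1))
        if not (bbox[0] >= 0 and bbox[1] >= 0 and bbox[2] > bbox[0] and bbox[3] > bbox[1]):
            raise ManifestError(f"{where}: empty or negative bbox {bbox}")
        img_path = base / str(row.slice_path)
        if check_images and img_path.exists():
            with Image.open(img_path) as im:
                w, h = im.size
            if bbox[2] > w or bbox[3] > h:
                raise ManifestError(
                    f"{where}: bbox {bbox} outside {w}x{h} image {row.slice_path}"
                )
        records.append(
            SliceRecord(
                patient_id=str(row.patient_id),
                study_id=str(row.study_id),
                series_id=str(row.series_id),
                sequence_type=str(row.sequence_type),
                slice_index=int(row.slice_index),
                label=str(row.label),
                image_path=str(img_path),
                tumor_bbox=bbox,
                phenotype=str(row.phenotype),
            )
        )
    return records


def write_manifest(records: list[SliceRecord], path) -> None:
    """Serialize records back to manifest CSV (paths written as stored)."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "study_id": r.study_id,
                "series_id": r.series_id,
                "sequence_type": r.sequence_type,
                "slice_path": r.image_path,
                "slice_index": r.slice_index,
                "label": r.label,
                "bbox_x0": r.tumor_bbox[0],
                "bbox_y0": r.tumor_bbox[1],
                "bbox_x1": r.tumor_bbox[2],
                "bbox_y1": r.tumor_bbox[3],
                "phenotype": r.phenotype,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


@dataclass
class CvAssignment:
    """Patient-level partition into CV groups (1-based group indices)."""

    groups: dict[str, int]
    n_groups: int

    def __getitem__(self, patient_id: str) -> int:
        return self.groups[patient_id]

    def patients_in(self, group: int) -> set[str]:
        return {p for p, g in self.groups.items() if g == group}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.groups.items()), columns=["patient_id", "group"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CvAssignment":
        frame = pd.read_csv(path)
        groups = dict(zip(frame["patient_id"].astype(str), frame["group"].astype(int)))
        return cls(groups=groups, n_groups=int(frame["group"].max()))


def make_cv_groups(
    records: list[SliceRecord], n_groups: int = 6, seed: int = 0
) -> CvAssignment:
    """Partition patients into ``n_groups`` CV groups, balancing slice counts.

    Class-stratified greedy bin packing: within each class, patients are
    taken in order of decreasing slice count (ties broken by a seeded
    shuffle) and each is placed in the group whose running slice total for
    that class is smallest. Deterministic for a fixed seed; every study of a
    patient stays with the patient.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    counts: dict[str, int] = {}
    labels: dict[str, str] = {}
    for r in records:
        counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
        labels[r.patient_id] = r.label

    rng = np.random.default_rng(seed)
    groups: dict[str, int] = {}
    for label in LABELS:
        patients = [p for p in counts if labels[p] == label]
        if not patients:
            continue
        if len(patients) < n_groups:
            raise ValueError(
                f"class {label!r} has {len(patients)} patients, "
                f"fewer than {n_groups} groups"
            )
        order = rng.permutation(len(patients))
        patients = [patients[i] for i in order]
        patients.sort(key=lambda p: -counts[p])  # stable: shuffle breaks ties
        totals = [0] * n_groups
        for p in patients:
            g = int(np.argmin(totals))
            groups[p] = g + 1
            totals[g] += counts[p]
    return CvAssignment(groups=groups, n_groups=n_groups)


def split_learn_eval(
    records: list[SliceRecord], assignment: CvAssignment, eval_group: int
) -> tuple[list[SliceRecord], list[SliceRecord]]:
    """Split records into (learning, evaluation) sets for one fold.

    The evaluation set is the slices of patients in ``eval_group``; the
    learning set is everything else — a (n_groups-1):1 split by groups.
    """
    if not 1 <= eval_group <= assignment.n_groups:
        raise ValueError(
            f"eval_group {eval_group} outside 1..{assignment.n_groups}"
        )
    learn, evaluation = [], []
    for r in records:
        (evaluation if assignment[r.patient_id] == eval_group else learn).append(r)
    return learn, evaluation
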