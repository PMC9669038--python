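"""Slice-, sequence- and patient-level prediction from the model matrix.

Every evaluation slice is predicted only by models whose fold matches the
slice's CV group — one probability per training-set replicate. On top of the
single-model predictions, T leave-one-out ensemble sets (set e pools all
training sets except e) yield T patient-level calls per case; the *sarcoma
likelihood* is the percentage of ensemble sets calling the case positive,
which is the value a radiologist would be shown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import crop_to_roi, load_slice_image
from .cohort import POSITIVE_LABEL, CvAssignment, SliceRecord
from .training import ModelMatrix

__all__ = [
    "EnsembleSet",
    "predict_slices",
    "build_ensemble_sets",
    "sequence_call",
    "sequence_call_table",
    "sarcoma_likelihood",
    "patient_report",
]

PREDICTION_COLUMNS = [
    "training_set",
    "fold",
    "patient_id",
    "study_id",
    "series_id",
    "sequence_type",
    "slice_index",
    "label",
    "probability",
]


@dataclass(frozen=True)
class EnsembleSet:
    """Leave-one-out ensemble: all training sets except ``omitted``."""

    index: int
    members: tuple[int, ...]

    @property
    def omitted(self) -> int:
        return self.index


def build_ensemble_sets(n_training_sets: int) -> list[EnsembleSet]:
    """The T leave-one-out ensemble sets over T training-set replicates."""
    if n_training_sets < 2:
        raise ValueError("leave-one-out ensembles require at least 2 training sets")
    return [
        EnsembleSet(
            index=e,
            members=tuple(m for m in range(1, n_training_sets + 1) if m != e),
        )
        for e in range(1, n_training_sets + 1)
    ]


def predict_slices(
    matrix: ModelMatrix,
    records: list[SliceRecord],
    assignment: CvAssignment,
    input_size: tuple[int, int] = (224, 224),
    batch_size: int = 256,
) -> pd.DataFrame:
    """Predict a sarcoma probability for every (training set, slice) pair.

    Evaluation crops are deterministic (tumor-centred) so repeated calls
    produce identical tables. Each slice is routed to the models of its own
    CV group; a slice whose group has no model raises an error naming the gap.
    """
    for r in records:
        g = assignment[r.patient_id]
        if (1, g) not in matrix.models:
            raise ValueError(
                f"no model for fold {g} (slice {r.slice_id}); matrix has "
                f"{matrix.n_folds} folds"
            )

    by_group: dict[int, list[SliceRecord]] = {}
    for r in records:
        by_group.setdefault(assignment[r.patient_id], []).append(r)

    rows = []
    for g, recs in sorted(by_group.items()):
        images = np.empty((len(recs), *input_size, 3))
        for i, r in enumerate(recs):
            crop = crop_to_roi(
                load_slice_image(r), r.tumor_bbox, input_size, deterministic=True
            )
            images[i] = np.repeat(crop[:, :, None], 3, axis=2) / 255.0
        for m in range(1, matrix.n_training_sets + 1):
            probs = matrix.model(m, g).predict_proba(images, batch_size=batch_size)
            for r, p in zip(recs, probs):
                rows.append(
                    {
                        "training_set": m,
                        "fold": g,
                        "patient_id": r.patient_id,
                        "study_id": r.study_id,
                        "series_id": r.series_id,
                        "sequence_type": r.sequence_type,
                        "slice_index": r.slice_index,
                        "label": r.label,
                        "probability": float(p),
                    }
                )
    table = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    if ((table["probability"] < 0) | (table["probability"] > 1)).any():
        raise ValueError("model produced probabilities outside [0, 1]")
    return table


def _member_means(
    table: pd.DataFrame, members: tuple[int, ...], study_id: str, sequence_type: str
) -> np.ndarray:
    sel = table[
        (table["study_id"] == study_id)
        & (table["sequence_type"] == sequence_type)
        & (table["training_set"].isin(members))
    ]
    if sel.empty:
        return np.array([])
    return sel.groupby("training_set")["probability"].mean().to_numpy()


def sequence_call(
    table: pd.DataFrame,
    members: tuple[int, ...] | int,
    study_id: str,
    sequence_type: str,
    mode: str = "mean",
) -> str:
    """Sequence-level call for one study: 'positive', 'negative' or
    'unavailable'.

    ``members`` is a training-set index (single-model call) or a tuple of
    them (ensemble call). In ``mean`` mode (default) the call is positive
    iff the mean over member models of the mean slice probability is >= 0.5
    (ties positive); ``vote`` mode thresholds each member's mean first and
    takes a majority (ties positive).
    """
    if isinstance(members, int):
        members = (members,)
    means = _member_means(table, members, study_id, sequence_type)
    if means.size == 0:
        return "unavailable"
    if mode == "mean":
        return "positive" if means.mean() >= 0.5 else "negative"
    if mode == "vote":
        votes = means >= 0.5
        return "positive" if votes.sum() * 2 >= votes.size else "negative"
    raise ValueError(f"unknown aggregation mode {mode!r}")


def sequence_call_table(
    table: pd.DataFrame,
    ensembles: list[EnsembleSet] | None = None,
    mode: str = "mean",
) -> pd.DataFrame:
    """Sequence calls for every (ensemble, study, sequence) triple.

    Returns one row per triple with columns (ensemble, patient_id, study_id,
    sequence_type, label, call) where call is +1 (positive) or -1 (negative);
    unavailable sequences simply have no row. With ``ensembles=None`` the
    single-model table is produced instead, keyed by training set.
    """
    per_member = (
        table.groupby(
            ["training_set", "patient_id", "study_id", "sequence_type", "label"],
            sort=False,
        )["probability"]
        .mean()
        .reset_index()
    )
    rows = []
    if ensembles is None:
        for r in per_member.itertuples(index=False):
            rows.append(
                {
                    "ensemble": r.training_set,
                    "patient_id": r.patient_id,
                    "study_id": r.study_id,
                    "sequence_type": r.sequence_type,
                    "label": r.label,
                    "call": 1 if r.probability >= 0.5 else -1,
                }
            )
        return pd.DataFrame(rows)

    for ens in ensembles:
        sub = per_member[per_member["training_set"].isin(ens.members)]
        grouped = sub.groupby(
            ["patient_id", "study_id", "sequence_type", "label"], sort=False
        )["probability"]
        agg = grouped.mean() if mode == "mean" else None
        if mode == "mean":
            for key, prob in agg.items():
                pid, sid, seq, label = key
                rows.append(
                    {
                        "ensemble": ens.index,
                        "patient_id": pid,
                        "study_id": sid,
                        "sequence_type": seq,
                        "label": label,
                        "call": 1 if prob >= 0.5 else -1,
                    }
                )
        elif mode == "vote":
            for key, probs in grouped:
                pid, sid, seq, label = key
                votes = (probs.to_numpy() >= 0.5).sum()
                rows.append(
                    {
                        "ensemble": ens.index,
                        "patient_id": pid,
                        "study_id": sid,
                        "sequence_type": seq,
                        "label": label,
                        "call": 1 if votes * 2 >= len(probs) else -1,
                    }
                )
        else:
            raise ValueError(f"unknown aggregation mode {mode!r}")
    return pd.DataFrame(rows)


def sarcoma_likelihood(ensemble_calls) -> float:
    """Percentage of ensemble sets calling the case positive, in [0, 100]."""
    calls = list(ensemble_calls)
    if not calls:
        raise ValueError("no ensemble calls")
    positives = sum(1 for c in calls if c in (True, 1, "positive"))
    return 100.0 * positives / len(calls)


def patient_report(
    seq_calls: pd.DataFrame,
    combination: tuple[str, ...],
    threshold: float,
) -> pd.DataFrame:
    """Per-study report: sequence calls, per-ensemble score call, likelihood.

    For each study and ensemble set, the +-1 scores of the available
    sequences in ``combination`` are summed; the ensemble calls the study
    positive iff the score is >= ``threshold`` (studies with no contributing
    sequence are called negative). The sarcoma likelihood is the percentage
    of positive ensemble calls. This is the payload shown to readers.
    """
    from .scoring import patient_score

    rows = []
    for (pid, sid, label), grp in seq_calls.groupby(
        ["patient_id", "study_id", "label"], sort=False
    ):
        calls_by_ens = {
            e: dict(zip(sub["sequence_type"], sub["call"]))
            for e, sub in grp.groupby("ensemble")
        }
        ens_calls = []
        for e, calls in sorted(calls_by_ens.items()):
            score, n_contrib = patient_score(calls, combination)
            ens_calls.append(n_contrib > 0 and score >= threshold)
        rows.append(
            {
                "patient_id": pid,
                "study_id": sid,
                "label": label,
                "sarcoma_likelihood": sarcoma_likelihood(ens_calls),
                "n_ensembles": len(ens_calls),
            }
        )
    return pd.DataFrame(rows)
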