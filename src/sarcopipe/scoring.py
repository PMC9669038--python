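"""Patient-level classification by per-sequence +-1 scoring and exhaustive
sequence-combination search.

For a chosen subset ("combination") of the 15 sequence types, each available
sequence contributes +1 if its call is positive and -1 if negative; the total
score predicts the patient. The decision threshold on the score is chosen on
the ROC curve at the maximum of (sensitivity + specificity)/2 (SS-Avg, the
balanced-accuracy statistic). All 2^15 = 32,768 subsets are enumerable, each
gets its own optimal threshold, and combinations are ranked by SS-Avg; the
mean over the top-k (k=10 at full scale) is the headline result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import POSITIVE_LABEL
from .sequences import SEQUENCE_INDEX, SEQUENCE_TYPES

__all__ = [
    "CombinationResult",
    "patient_score",
    "optimal_threshold",
    "enumerate_combinations",
    "rank_combinations",
    "results_to_frame",
]


@dataclass(frozen=True)
class CombinationResult:
    """Metrics of one sequence combination at its optimal score threshold."""

    combination: tuple[str, ...]
    threshold: float
    ss_avg: float  # percentages
    accuracy: float
    sensitivity: float
    specificity: float
    rank: int = 0


def patient_score(
    sequence_calls: dict[str, int | str],
    combination: tuple[str, ...] | frozenset,
) -> tuple[int, int]:
    """Total +-1 score of one case over a sequence combination.

    ``sequence_calls`` maps sequence type to a call (+1/-1, or
    'positive'/'negative'); sequences absent from the mapping (not acquired
    for this case) contribute nothing. Returns ``(score, n_contributing)``.
    """
    score = 0
    n_contributing = 0
    for seq in combination:
        if seq not in sequence_calls:
            continue
        call = sequence_calls[seq]
        if call in ("positive", 1, True):
            score += 1
        elif call in ("negative", -1, False):
            score -= 1
        else:
            raise ValueError(f"unrecognised call {call!r} for sequence {seq}")
        n_contributing += 1
    return score, n_contributing


def optimal_threshold(
    scores, labels, positive_label=POSITIVE_LABEL
) -> tuple[float, float]:
    """Score threshold maximizing SS-Avg under the rule: positive iff
    score >= t.

    Candidate cut-points are the observed scores plus one above the maximum
    (the all-negative rule); among ties the smallest threshold is returned.
    Returns ``(threshold, ss_avg_percent)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([label == positive_label for label in np.asarray(labels)])
    if len(scores) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to choose a threshold")
    candidates = np.unique(scores)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    best_t, best_ss = None, -1.0
    for t in candidates:
        called = scores >= t
        sens = np.sum(called & y) / n_pos
        spec = np.sum(~called & ~y) / n_neg
        ss = (sens + spec) / 2.0
        if ss > best_ss + 1e-12:
            best_t, best_ss = float(t), float(ss)
    return best_t, 100.0 * best_ss


def enumerate_combinations(
    sequence_types: tuple[str, ...] = SEQUENCE_TYPES,
) -> list[tuple[str, ...]]:
    """All subsets of the given sequence types, empty set included.

    Deterministic binary-counting order over the canonical sequence order:
    subset i contains type j iff bit j of i is set. 15 types yield 32,768
    subsets.
    """
    types = tuple(sequence_types)
    if not 1 <= len(types) <= 20:
        raise ValueError("between 1 and 20 sequence types supported")
    order = sorted(types, key=lambda s: SEQUENCE_INDEX.get(s, len(SEQUENCE_INDEX)))
    subsets = []
    for i in range(2 ** len(order)):
        subsets.append(tuple(s for j, s in enumerate(order) if i >> j & 1))
    return subsets


def _combination_metrics(
    call_matrix: np.ndarray,
    y: np.ndarray,
    member_mask: np.ndarray,
) -> tuple[float, float, float, float, float]:
    """(threshold, ss_avg, accuracy, sensitivity, specificity) for one subset.

    ``call_matrix`` is (units x sequences) with +1/-1 calls and 0 for
    unavailable; a unit with no contributing sequence is forced negative
    regardless of threshold.
    """
    contributing = (call_matrix[:, member_mask] != 0).sum(axis=1)
    scores = call_matrix[:, member_mask].sum(axis=1).astype(float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    candidates = np.append(np.unique(scores), scores.max() + 1.0)
    best = None
    for t in candidates:
        called = (scores >= t) & (contributing > 0)
        tp = int(np.sum(called & y))
        tn = int(np.sum(~called & ~y))
        sens = tp / n_pos
        spec = tn / n_neg
        ss = (sens + spec) / 2.0
        acc = (tp + tn) / len(y)
        if best is None or ss > best[1] + 1e-12:
            best = (float(t), ss, acc, sens, spec)
    t, ss, acc, sens, spec = best
    return t, 100 * ss, 100 * acc, 100 * sens, 100 * spec


def rank_combinations(
    seq_calls: pd.DataFrame,
    top_k: int = 10,
    combinations: list[tuple[str, ...]] | None = None,
) -> tuple[list[CombinationResult], dict[str, float]]:
    """Score every sequence combination and rank by SS-Avg.

    ``seq_calls`` is the sequence-call table (one row per (ensemble, study,
    sequence) with a +-1 ``call`` and the true ``label``); the evaluation
    unit is the (ensemble, study) pair, pooled across ensembles, and each
    combination gets its own SS-Avg-optimal threshold. Ties rank by higher
    SS-Avg, then higher accuracy, then fewer sequences, then canonical
    subset order. The empty combination is excluded from ranking. Returns
    the ranked results and the arithmetic mean of the top-k metrics.
    """
    present = sorted(
        seq_calls["sequence_type"].unique(), key=lambda s: SEQUENCE_INDEX[s]
    )
    if combinations is None:
        combinations = enumerate_combinations(tuple(present))
    seq_pos = {s: i for i, s in enumerate(present)}

    units = seq_calls.pivot_table(
        index=["ensemble", "patient_id", "study_id", "label"],
        columns="sequence_type",
        values="call",
        aggfunc="first",
        fill_value=0,
    )
    call_matrix = np.zeros((len(units), len(present)), dtype=int)
    for s in units.columns:
        call_matrix[:, seq_pos[s]] = units[s].to_numpy()
    y = np.array([key[3] == POSITIVE_LABEL for key in units.index])
    if y.all() or not y.any():
        raise ValueError("both classes must be present to rank combinations")

    results = []
    for combo in combinations:
        if not combo:
            continue
        mask = np.zeros(len(present), dtype=bool)
        for s in combo:
            if s in seq_pos:
                mask[seq_pos[s]] = True
        if not mask.any():
            continue
        t, ss, acc, sens, spec = _combination_metrics(call_matrix, y, mask)
        results.append(
            CombinationResult(
                combination=combo,
                threshold=t,
                ss_avg=ss,
                accuracy=acc,
                sensitivity=sens,
                specificity=spec,
            )
        )

    def sort_key(r: CombinationResult):
        return (
            -r.ss_avg,
            -r.accuracy,
            len(r.combination),
            tuple(SEQUENCE_INDEX[s] for s in r.combination),
        )

    results.sort(key=sort_key)
    results = [replace(r, rank=i + 1) for i, r in enumerate(results)]
    top = results[:top_k]
    averaged = {
        "ss_avg": float(np.mean([r.ss_avg for r in top])),
        "accuracy": float(np.mean([r.accuracy for r in top])),
        "sensitivity": float(np.mean([r.sensitivity for r in top])),
        "specificity": float(np.mean([r.specificity for r in top])),
    }
    return results, averaged


def results_to_frame(
    results: list[CombinationResult], sequence_types: tuple[str, ...] = SEQUENCE_TYPES
) -> pd.DataFrame:
    """Ranked-combination table with one indicator column per sequence."""
    rows = []
    for r in results:
        row = {
            "rank": r.rank,
            "ss_avg": r.ss_avg,
            "accuracy": r.accuracy,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "threshold": r.threshold,
        }
        for s in sequence_types:
            row[s] = int(s in r.combination)
        rows.append(row)
    return pd.DataFrame(rows)
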