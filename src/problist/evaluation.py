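"""Scoring: precision/recall/F, pair-counting cluster quality, masked-code
recovery, compression rates, per-patient summaries and Chernoff sample size.

Two evaluation protocols are implemented and kept strictly apart:

* **masked-code recovery** scores post-coding per item: a stated fraction of
  ICD-10 codes is hidden, the pipeline re-assigns them, and each masked item
  is a TP (correct code), FP (wrong code), FN (no code although one exists)
  or TN (correctly left uncoded).
* **pair-counting** scores a partition label-free: every pair of labeled
  items is classified by (same 3-digit code?) x (same cluster?).

The compression rate 1 - topics/items measures how far a redundant list is
collapsed into topic groups.  The Chernoff-bound sample size
n >= (3/eps^2) ln(2/delta) gives the number of text snippets needed so that
observed proportions are within eps of the truth with confidence 1 - delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EvalCounts",
    "PrfScores",
    "PatientSummary",
    "SamplingParams",
    "prf_from_counts",
    "f_from_pr",
    "pairwise_counts",
    "evaluate_pairwise_clustering",
    "evaluate_postcoding",
    "compression_rate",
    "summarize",
    "estimate_sample_size",
]


@dataclass(frozen=True)
class EvalCounts:
    """TP/FP/FN/TN tallies."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class PrfScores:
    precision: float
    recall: float
    f_measure: float


def f_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def prf_from_counts(counts: EvalCounts) -> PrfScores:
    """Precision, recall and F from raw tallies (0 on empty denominators)."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return PrfScores(precision, recall, f_from_pr(precision, recall))


def _comb2(counts: np.ndarray) -> int:
    return int(np.sum(counts * (counts - 1) // 2))


def pairwise_counts(
    membership: Mapping[str, int], labels: Mapping[str, str]
) -> EvalCounts:
    """Pair-counting tallies over all labeled item pairs.

    Same code & same cluster -> TP; different code & same cluster -> FP;
    same code & different cluster -> FN; neither -> TN.  Computed from the
    cluster x code contingency table, not by pair enumeration.
    """
    ids = [i for i in membership if i in labels]
    if len(ids) < 2:
        raise ValueError("pair counting needs at least two labeled items")
    clusters = np.unique([membership[i] for i in ids], return_inverse=True)[1]
    codes = np.unique([labels[i] for i in ids], return_inverse=True)[1]
    n = len(ids)
    contingency = np.zeros((clusters.max() + 1, codes.max() + 1), dtype=np.int64)
    np.add.at(contingency, (clusters, codes), 1)
    tp = _comb2(contingency.ravel())
    same_cluster = _comb2(contingency.sum(axis=1))
    same_code = _comb2(contingency.sum(axis=0))
    total = n * (n - 1) // 2
    fp = same_cluster - tp
    fn = same_code - tp
    return EvalCounts(tp=tp, fp=fp, fn=fn, tn=total - tp - fp - fn)


def evaluate_pairwise_clustering(partition, labels: Mapping[str, str]) -> EvalCounts:
    """Pair-counting evaluation of a partition against 3-digit code labels.

    ``partition`` is either a ``TopicPartition`` (has ``membership``) or a
    plain item id -> cluster id mapping.
    """
    membership = getattr(partition, "membership", partition)
    return pairwise_counts(membership, labels)


def evaluate_postcoding(
    assignments: Iterable,
    truth: Mapping[str, str | None],
) -> EvalCounts:
    """Masked-code recovery tallies, one unit per evaluated item.

    ``assignments`` are ``CodeAssignment`` records for the uncoded items;
    ``truth`` maps each evaluated item to its hidden 3-digit code, or None
    for an item that genuinely has no code.
    """
    tp = fp = fn = tn = 0
    for assignment in assignments:
        if assignment.item_id not in truth:
            continue
        true_code = truth[assignment.item_id]
        if assignment.assigned_code is not None:
            if true_code is None:
                fp += 1
            elif assignment.assigned_code == true_code:
                tp += 1
            else:
                fp += 1
        else:
            if true_code is None:
                tn += 1
            else:
                fn += 1
    return EvalCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def compression_rate(n_items: int, n_topics: int) -> float:
    """1 - topics/items: the fraction of list entries absorbed into groups."""
    if not 1 <= n_topics <= n_items:
        raise ValueError("need 1 <= n_topics <= n_items")
    return 1.0 - n_topics / n_items


@dataclass(frozen=True)
class PatientSummary:
    """Per-patient (or pooled) result row mirroring the report tables."""

    patient_id: str
    n_items: int
    n_unique: int
    n_topics: int
    coded_fraction: float
    coded_prf: PrfScores
    clustered_prf: PrfScores

    def __post_init__(self) -> None:
        if not self.n_topics <= self.n_unique <= self.n_items:
            raise ValueError("need n_topics <= n_unique <= n_items")

    @property
    def compression_rate(self) -> float:
        return compression_rate(self.n_items, self.n_topics)


def _mean(values: Sequence[float], ndigits: int | None) -> float:
    if ndigits is not None:
        values = [round(v, ndigits) for v in values]
    return float(np.mean(values))


def summarize(
    per_patient: Sequence[PatientSummary], round_to: int | None = 2
) -> dict[str, float]:
    """Unweighted means of the per-patient columns.

    Per-patient values are rounded to ``round_to`` decimals before averaging
    (mirroring how tabulated two-decimal values are aggregated in reports);
    pass ``round_to=None`` to average unrounded values.
    """
    if not per_patient:
        raise ValueError("cannot summarize an empty list of patients")
    return {
        "n_patients": float(len(per_patient)),
        "mean_items": _mean([p.n_items for p in per_patient], None),
        "mean_unique": _mean([p.n_unique for p in per_patient], None),
        "mean_topics": _mean([p.n_topics for p in per_patient], None),
        "mean_compression_rate": _mean(
            [p.compression_rate for p in per_patient], round_to
        ),
        "mean_coded_fraction": _mean(
            [p.coded_fraction for p in per_patient], round_to
        ),
        "mean_coded_precision": _mean(
            [p.coded_prf.precision for p in per_patient], round_to
        ),
        "mean_coded_recall": _mean(
            [p.coded_prf.recall for p in per_patient], round_to
        ),
        "mean_coded_f": _mean(
            [p.coded_prf.f_measure for p in per_patient], round_to
        ),
        "mean_clustered_precision": _mean(
            [p.clustered_prf.precision for p in per_patient], round_to
        ),
        "mean_clustered_recall": _mean(
            [p.clustered_prf.recall for p in per_patient], round_to
        ),
        "mean_clustered_f": _mean(
            [p.clustered_prf.f_measure for p in per_patient], round_to
        ),
    }


@dataclass(frozen=True)
class SamplingParams:
    """Accuracy/confidence parameters with the implied minimum sample size."""

    epsilon: float
    delta: float

    @property
    def n_min(self) -> int:
        return estimate_sample_size(self.epsilon, self.delta)


def estimate_sample_size(epsilon: float, delta: float) -> int:
    """Chernoff-bound sample size: ceil((3/eps^2) ln(2/delta)).

    The observed proportion of any linguistic pattern in a sample of this
    size is within +-epsilon of its population value with probability at
    least 1 - delta, independently of the pool size.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    return math.ceil(3.0 / epsilon**2 * math.log(2.0 / delta))
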