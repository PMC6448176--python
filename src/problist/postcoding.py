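"""Post-ICD-10 coding of uncoded items by nearest coded neighbor.

An uncoded item receives a code if and only if it shares a cluster with at
least one coded item; it then inherits the 3-digit category of the most
similar coded item in that cluster (arg-max cosine similarity).  Clusters
that mix several codes are resolved per item, not by cluster majority: each
uncoded member follows its individually nearest coded neighbor.  Existing
codes are never modified, and exactly one code is assigned per item.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CodeAssignment", "post_assign", "resolve_mixed_cluster"]


@dataclass(frozen=True)
class CodeAssignment:
    """Outcome of post-coding for one uncoded item."""

    item_id: str
    assigned_code: str | None = None
    source_item: str | None = None
    similarity: float | None = None

    def __post_init__(self) -> None:
        if (self.assigned_code is None) != (self.source_item is None):
            raise ValueError("assigned_code and source_item must co-occur")
        if self.similarity is not None and not -1e-9 <= self.similarity <= 1 + 1e-9:
            raise ValueError("similarity must lie in [0, 1]")


def _nearest_coded(
    item: str,
    coded_members: Sequence[str],
    coded_labels: Mapping[str, str],
    similarities: np.ndarray,
    index: Mapping[str, int],
) -> CodeAssignment:
    row = similarities[index[item]]
    best: str | None = None
    best_sim = -np.inf
    tied = False
    for candidate in coded_members:
        sim = row[index[candidate]]
        if sim > best_sim + 1e-12:
            best, best_sim, tied = candidate, sim, False
        elif abs(sim - best_sim) <= 1e-12 and best is not None:
            tied = True
            if candidate < best:  # deterministic: lexicographically smallest id
                best = candidate
    if tied:
        # common for duplicate strings (similarity 1.0 to several neighbors)
        logger.debug(
            "item %s: tie among nearest coded neighbors resolved toward %s",
            item,
            best,
        )
    assert best is not None
    return CodeAssignment(
        item_id=item,
        assigned_code=coded_labels[best],
        source_item=best,
        similarity=float(np.clip(best_sim, 0.0, 1.0)),
    )


def resolve_mixed_cluster(
    cluster: set[str],
    coded_labels: Mapping[str, str],
    similarities: np.ndarray,
    doc_ids: Sequence[str],
) -> list[CodeAssignment]:
    """Per-item nearest-coded-neighbor assignment within one cluster.

    ``similarities`` is indexed by position in ``doc_ids``.  Returns one
    record per uncoded member; the record carries no code when the cluster
    contains no coded member.
    """
    index = {doc_id: i for i, doc_id in enumerate(doc_ids)}
    members = sorted(cluster)
    coded_members = [m for m in members if m in coded_labels]
    assignments = []
    for item in members:
        if item in coded_labels:
            continue
        if not coded_members:
            assignments.append(CodeAssignment(item_id=item))
        else:
            assignments.append(
                _nearest_coded(item, coded_members, coded_labels, similarities, index)
            )
    return assignments


def post_assign(
    partition,
    coded_labels: Mapping[str, str],
    similarities: np.ndarray,
    doc_ids: Sequence[str],
) -> list[CodeAssignment]:
    """Post-code every uncoded item of a partition.

    ``partition`` is a ``TopicPartition`` (or any object with ``clusters``:
    cluster id -> set of item ids); ``similarities`` must be the cosine
    similarities of the same space the partition was clustered in, indexed
    by ``doc_ids`` position.  Coded items are left untouched; uncoded items
    in clusters without any coded member stay unassigned.
    """
    clusters = getattr(partition, "clusters", partition)
    assignments: list[CodeAssignment] = []
    for _, members in sorted(clusters.items()):
        assignments.extend(
            resolve_mixed_cluster(members, coded_labels, similarities, doc_ids)
        )
    assignments.sort(key=lambda a: a.item_id)
    return assignments
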