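"""UPGMA clustering, dendrogram cutting and supervised cut-off inference.

The dendrogram is built by average-linkage (UPGMA) agglomeration on cosine
distances: the distance between two clusters is the arithmetic mean of all
pairwise document distances between them.  A flat topic partition is
obtained by cutting the dendrogram at a height h (merges at height <= h
join).  The cut height is not chosen unsupervised: it is inferred against
the partially ICD-10 coded items by sweeping a grid of heights and keeping
the one whose partition maximizes the pairwise F-measure over coded items
(same 3-digit category <=> same cluster).  Ties are broken toward the
smallest height, i.e. toward more and purer clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .corpus import Corpus
from .evaluation import EvalCounts, pairwise_counts, prf_from_counts

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "TopicPartition",
    "CutoffSearchResult",
    "upgma",
    "cut",
    "infer_cutoff",
    "deduplicate",
    "default_height_grid",
    "to_newick",
]


@dataclass
class Dendrogram:
    """UPGMA merge tree: a SciPy linkage matrix plus leaf identifiers."""

    linkage: np.ndarray  # (n-1) x 4 scipy linkage matrix
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        """(left node, right node, height, size) per merge, in merge order."""
        return [
            (int(a), int(b), float(h), int(size)) for a, b, h, size in self.linkage
        ]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class TopicPartition:
    """Flat clustering of the leaves at a given cut height."""

    cut_height: float
    clusters: dict[int, set[str]]

    @property
    def n_topics(self) -> int:
        return len(self.clusters)

    @property
    def membership(self) -> dict[str, int]:
        """leaf id -> cluster id."""
        return {
            leaf: cluster_id
            for cluster_id, members in self.clusters.items()
            for leaf in members
        }


@dataclass
class CutoffSearchResult:
    """Outcome of the grid sweep over candidate cut heights."""

    best_height: float
    best_f: float
    trace: list[tuple[float, float, float, float]]  # (height, P, R, F)


def upgma(distances: np.ndarray, leaf_ids: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a symmetric distance matrix."""
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if distances.ndim != 2 or distances.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least two observations to cluster")
    if np.any(distances < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(distances, distances.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distances), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    elif len(leaf_ids) != n:
        raise ValueError("leaf_ids length must match the distance matrix")
    condensed = squareform((distances + distances.T) / 2.0, checks=False)
    linkage = sch.linkage(condensed, method="average")
    if np.any(np.diff(linkage[:, 2]) < -1e-12):
        logger.warning("non-monotone merge heights in UPGMA dendrogram")
    return Dendrogram(linkage=linkage, leaf_ids=list(leaf_ids))


def cut(dendrogram: Dendrogram, height: float) -> TopicPartition:
    """Flat partition at a cut height: merges with height <= cut join."""
    if height < 0:
        raise ValueError("cut height must be >= 0")
    flat = sch.fcluster(dendrogram.linkage, t=height, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for leaf, cluster_id in zip(dendrogram.leaf_ids, flat):
        clusters.setdefault(int(cluster_id), set()).add(leaf)
    return TopicPartition(cut_height=float(height), clusters=clusters)


def default_height_grid(
    start: float = 0.0, stop: float = 1.0, step: float = 0.01
) -> np.ndarray:
    """Inclusive two-decimal grid of candidate cut heights."""
    if step <= 0 or stop < start:
        raise ValueError("invalid height grid")
    n_steps = int(round((stop - start) / step))
    return np.round(start + step * np.arange(n_steps + 1), 10)


def infer_cutoff(
    dendrogram: Dendrogram,
    coded_labels: Mapping[str, str],
    grid: Sequence[float] | None = None,
    expand: Mapping[str, Sequence[str]] | None = None,
) -> CutoffSearchResult:
    """Sweep cut heights and keep the one maximizing pairwise F over coded items.

    At every height each pair of coded items is classified: same 3-digit
    code and co-clustered -> TP; different code co-clustered -> FP; same
    code separated -> FN.  Returns the smallest height attaining the maximum
    F-measure, plus the full (height, P, R, F) trace.

    When the dendrogram leaves are deduplicated strings, ``expand`` maps
    each leaf id to the item ids it stands for, so that pairs of identical
    coded items (which co-cluster at every height) are counted.
    """
    if expand is None:
        expand = {leaf: (leaf,) for leaf in dendrogram.leaf_ids}
    item_leaf = {
        item: leaf for leaf in dendrogram.leaf_ids for item in expand.get(leaf, ())
    }
    labels = {
        item: coded_labels[item] for item in item_leaf if item in coded_labels
    }
    if len(labels) < 2:
        raise ValueError("cut-off inference needs at least two coded items")
    counts = np.bincount(
        np.unique(list(labels.values()), return_inverse=True)[1]
    )
    if not np.any(counts >= 2):
        raise ValueError(
            "no pair of coded items shares a 3-digit code; recall is undefined"
        )
    if grid is None:
        grid = default_height_grid()
    grid = sorted(float(h) for h in grid)
    if not grid:
        raise ValueError("empty cut-height grid")

    best_height, best_f = grid[0], -1.0
    trace: list[tuple[float, float, float, float]] = []
    for height in grid:
        leaf_membership = cut(dendrogram, height).membership
        membership = {item: leaf_membership[leaf] for item, leaf in item_leaf.items()}
        scores = prf_from_counts(pairwise_counts(membership, labels))
        trace.append((height, scores.precision, scores.recall, scores.f_measure))
        if scores.f_measure > best_f:
            best_f = scores.f_measure
            best_height = height
    return CutoffSearchResult(best_height=best_height, best_f=best_f, trace=trace)


def deduplicate(corpus: Corpus) -> tuple[list[str], dict[str, list[str]]]:
    """Unique description strings plus the multiplicity map back to item ids.

    Clustering operates on unique strings (identical entries trivially
    co-cluster at distance zero); the returned map re-expands cluster
    membership to every original item afterwards.  Order of first
    occurrence is preserved.
    """
    unique: list[str] = []
    groups: dict[str, list[str]] = {}
    for item in corpus:
        key = item.description.strip()
        if key not in groups:
            groups[key] = []
            unique.append(key)
        groups[key].append(item.item_id)
    return unique, groups


def _escape_newick(label: str) -> str:
    if any(ch in label for ch in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick export with merge heights encoded as branch lengths."""
    tree = sch.to_tree(dendrogram.linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{_escape_newick(dendrogram.leaf_ids[node.id])}:{length:.6f}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6f}"

    return render(tree, tree.dist) + ";"
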