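"""tf-idf vector space over character 3-grams, cosine similarity and LSA.

Documents (normalized problem-list entries) become columns of an m x n
term-document matrix X over the corpus' unique character n-gram types.
Weights are raw term frequency times smoothed inverse document frequency,
idf(t) = ln((1 + n) / (1 + df(t))) + 1, with L2-normalized columns, so the
cosine similarity of two documents is a plain dot product.

Latent semantic analysis truncates the SVD X = T S D^T to the top-k
singular triplets; document representations in the reduced space are the
columns of S_k D_k^T.  At full rank these reproduce the original cosine
similarities exactly, which serves as a built-in consistency check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.io
import scipy.linalg
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer

from .preprocess import NgramDocument

logger = logging.getLogger(__name__)

__all__ = [
    "TfIdfMatrix",
    "LsaSpace",
    "build_tfidf",
    "cosine_similarity",
    "lsa_reduce",
    "distance_matrix",
    "similarity_matrix",
    "write_mtx",
]


@dataclass
class TfIdfMatrix:
    """Sparse m x n tf-idf term-document matrix (terms are gram types)."""

    vocabulary: list[str]
    matrix: sp.csr_matrix  # shape (m, n), columns unit-norm (or zero)
    doc_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def doc_vectors(self) -> np.ndarray:
        """Dense m x n array of (unit-norm) document columns."""
        return np.asarray(self.matrix.todense())


@dataclass
class LsaSpace:
    """Truncated SVD factors of a tf-idf matrix."""

    term_space: np.ndarray  # m x k, orthonormal columns (T_k)
    singular_values: np.ndarray  # k, positive, non-increasing
    doc_space: np.ndarray  # k x n (D_k^T)
    k: int
    doc_ids: list[str]

    def doc_vectors(self) -> np.ndarray:
        """k x n document representations S_k D_k^T, columns L2-normalized."""
        rep = self.singular_values[:, None] * self.doc_space
        norms = np.linalg.norm(rep, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        return rep / safe


def build_tfidf(docs: list[NgramDocument]) -> TfIdfMatrix:
    """Assemble the tf-idf weighted term-document matrix from n-gram bags.

    Documents with no grams (e.g. a description consisting only of stripped
    characters) are kept as zero columns and logged.
    """
    if not docs:
        raise ValueError("cannot build a tf-idf matrix from an empty corpus")
    vocabulary = sorted({gram for doc in docs for gram in doc.grams})
    if not vocabulary:
        raise ValueError("no n-gram types in any document")
    index = {gram: i for i, gram in enumerate(vocabulary)}

    rows, cols, data = [], [], []
    for j, doc in enumerate(docs):
        if not doc.grams:
            logger.warning("document %s has no grams; zero column", doc.item_id)
        for gram, count in doc.grams.items():
            rows.append(j)
            cols.append(index[gram])
            data.append(count)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), len(vocabulary)), dtype=float
    )
    # smooth idf ln((1+n)/(1+df)) + 1 with L2 document normalization
    weighted = TfidfTransformer(
        norm="l2", smooth_idf=True, sublinear_tf=False
    ).fit_transform(counts)
    return TfIdfMatrix(
        vocabulary=vocabulary,
        matrix=sp.csr_matrix(weighted.T),
        doc_ids=[doc.item_id for doc in docs],
    )


def cosine_similarity(space: TfIdfMatrix | LsaSpace, i: int, j: int) -> float:
    """Cosine similarity of documents *i* and *j*; 0 if either is a zero vector."""
    vectors = space.doc_vectors()
    n = vectors.shape[1]
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"document index out of range (n={n})")
    return float(vectors[:, i] @ vectors[:, j])


def similarity_matrix(space: TfIdfMatrix | LsaSpace) -> np.ndarray:
    """n x n cosine similarity matrix (unit diagonal for nonzero documents)."""
    vectors = space.doc_vectors()
    sim = vectors.T @ vectors
    np.fill_diagonal(sim, [1.0 if np.any(vectors[:, j]) else 0.0
                           for j in range(vectors.shape[1])])
    return sim


def distance_matrix(space: TfIdfMatrix | LsaSpace) -> np.ndarray:
    """Symmetric cosine-distance matrix d = 1 - sim, clipped to [0, 1].

    Clipping matters only in LSA space, where cosine can leave [0, 1];
    it keeps the distance contract identical in both spaces.
    """
    n = len(space.doc_ids)
    if n < 2:
        raise ValueError("need at least two documents for a distance matrix")
    dist = np.clip(1.0 - similarity_matrix(space), 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


def lsa_reduce(tfidf: TfIdfMatrix, fraction: float) -> LsaSpace:
    """Truncated SVD keeping k = max(1, round(fraction * min(m, n))) dimensions.

    The sign of each singular vector pair is fixed (largest-magnitude entry
    of the term vector made positive) so results are deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("LSA fraction must be in (0, 1]")
    dense = space_dense = np.asarray(tfidf.matrix.todense())
    m, n = dense.shape
    rank_upper_bound = min(m, n)
    k = max(1, round(fraction * rank_upper_bound))
    u, s, vt = scipy.linalg.svd(space_dense, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k, :]
    # deterministic sign convention
    for i in range(k):
        pivot = np.argmax(np.abs(u[:, i]))
        if u[pivot, i] < 0:
            u[:, i] = -u[:, i]
            vt[i, :] = -vt[i, :]
    positive = s > np.finfo(float).eps * max(m, n) * (s[0] if s.size else 1.0)
    if not np.all(positive):
        keep = int(np.sum(positive)) or 1
        u, s, vt = u[:, :keep], s[:keep], vt[:keep, :]
        k = keep
    return LsaSpace(
        term_space=u,
        singular_values=s,
        doc_space=vt,
        k=k,
        doc_ids=list(tfidf.doc_ids),
    )


def write_mtx(tfidf: TfIdfMatrix, matrix_path, vocabulary_path) -> None:
    """Dump the term-document matrix (MatrixMarket) and vocabulary for inspection."""
    scipy.io.mmwrite(str(matrix_path), tfidf.matrix)
    with open(vocabulary_path, "w", encoding="utf-8") as handle:
        for gram in tfidf.vocabulary:
            handle.write(gram + "\n")
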