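"""End-to-end orchestration: normalize -> vectorize -> (LSA) -> UPGMA ->
cut-off inference -> cut -> post-coding -> evaluation.

Two scenarios are supported.  In *intra*-patient mode every patient's list
is clustered in isolation: codes can only be learned from the same
patient's coded items.  In *inter*-patient mode all items are pooled so
codes propagate across patients; per-patient summary rows are then derived
by restricting the pooled partition and assignments to each patient's
items.

Clustering always operates on unique description strings (identical entries
trivially co-cluster); each unique string is represented by its first item
id, and cluster membership is re-expanded to all items afterwards.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clustering import (
    CutoffSearchResult,
    Dendrogram,
    TopicPartition,
    cut,
    deduplicate,
    default_height_grid,
    infer_cutoff,
    to_newick,
    upgma,
)
from .corpus import Corpus, save_corpus
from .evaluation import (
    PatientSummary,
    PrfScores,
    evaluate_pairwise_clustering,
    evaluate_postcoding,
    prf_from_counts,
    summarize,
)
from .postcoding import CodeAssignment, post_assign
from .preprocess import NormalizationConfig, ngram_document
from .synthgen import SynthTruth
from .vectorspace import build_tfidf, distance_matrix, lsa_reduce, similarity_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "GroupResult", "PipelineReport", "run_pipeline", "sweep_lsa"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run."""

    mode: str = "intra"  # "intra": per patient; "inter": pooled
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    lsa_fraction: float | None = None  # None = plain vector space model
    grid_start: float = 0.0
    grid_stop: float = 1.0
    grid_step: float = 0.01
    seed: int = 0  # recorded in reports; the pipeline itself is deterministic

    def __post_init__(self) -> None:
        if self.mode not in {"intra", "inter"}:
            raise ValueError("mode must be 'intra' or 'inter'")
        if self.lsa_fraction is not None and not 0.0 < self.lsa_fraction <= 1.0:
            raise ValueError("lsa_fraction must be in (0, 1]")
        default_height_grid(self.grid_start, self.grid_stop, self.grid_step)

    @property
    def grid(self) -> np.ndarray:
        return default_height_grid(self.grid_start, self.grid_stop, self.grid_step)


@dataclass
class GroupResult:
    """All artefacts for one clustered group (one patient, or the pool)."""

    group_id: str
    dendrogram: Dendrogram
    cutoff: CutoffSearchResult
    leaf_partition: TopicPartition
    item_partition: TopicPartition
    assignments: list[CodeAssignment]
    groups_map: dict[str, list[str]]  # description -> item ids


@dataclass
class PipelineReport:
    """Per-patient summaries plus the aggregate report of one run."""

    mode: str
    lsa_fraction: float | None
    results: list[GroupResult]
    summaries: list[PatientSummary]
    aggregate: dict[str, float]
    has_truth: bool

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "lsa_fraction": self.lsa_fraction,
            "has_truth": self.has_truth,
            "groups": [
                {
                    "group_id": r.group_id,
                    "best_height": r.cutoff.best_height,
                    "best_f": r.cutoff.best_f,
                    "n_topics": r.item_partition.n_topics,
                }
                for r in self.results
            ],
            "patients": [
                {
                    "patient_id": s.patient_id,
                    "n_items": s.n_items,
                    "n_unique": s.n_unique,
                    "n_topics": s.n_topics,
                    "compression_rate": round(s.compression_rate, 2),
                    "coded_fraction": round(s.coded_fraction, 2),
                    "coded_precision": round(s.coded_prf.precision, 2),
                    "coded_recall": round(s.coded_prf.recall, 2),
                    "coded_f": round(s.coded_prf.f_measure, 2),
                    "clustered_precision": round(s.clustered_prf.precision, 2),
                    "clustered_recall": round(s.clustered_prf.recall, 2),
                    "clustered_f": round(s.clustered_prf.f_measure, 2),
                }
                for s in self.summaries
            ],
            "aggregate": self.aggregate,
        }


def _cluster_group(
    group_id: str,
    corpus: Corpus,
    config: PipelineConfig,
) -> GroupResult:
    unique, groups_map = deduplicate(corpus)
    if len(unique) < 2:
        raise ValueError(f"group {group_id}: need at least two unique descriptions")
    leaf_ids = [groups_map[d][0] for d in unique]
    docs = [
        ngram_document(leaf, description, config.normalization)
        for leaf, description in zip(leaf_ids, unique)
    ]
    tfidf = build_tfidf(docs)
    space = (
        lsa_reduce(tfidf, config.lsa_fraction)
        if config.lsa_fraction is not None
        else tfidf
    )
    dendrogram = upgma(distance_matrix(space), leaf_ids)
    coded_labels = corpus.coded_labels
    expansion = {leaf: groups_map[d] for leaf, d in zip(leaf_ids, unique)}
    cutoff = infer_cutoff(dendrogram, coded_labels, config.grid, expand=expansion)
    leaf_partition = cut(dendrogram, cutoff.best_height)
    logger.info(
        "group %s: %d items, %d unique, best F %.3f at height %.2f, %d topics",
        group_id, len(corpus), len(unique), cutoff.best_f, cutoff.best_height,
        leaf_partition.n_topics,
    )

    # expand leaves back to items
    leaf_to_desc = dict(zip(leaf_ids, unique))
    item_clusters = {
        cid: {
            item
            for leaf in members
            for item in groups_map[leaf_to_desc[leaf]]
        }
        for cid, members in leaf_partition.clusters.items()
    }
    item_partition = TopicPartition(
        cut_height=leaf_partition.cut_height, clusters=item_clusters
    )

    # item-level similarities inherited from the unique-string space
    leaf_index = {leaf: i for i, leaf in enumerate(leaf_ids)}
    item_ids = [item.item_id for item in corpus]
    item_leaf = np.array(
        [leaf_index[groups_map[item.description.strip()][0]] for item in corpus]
    )
    leaf_sim = similarity_matrix(space)
    item_sim = leaf_sim[np.ix_(item_leaf, item_leaf)]
    np.fill_diagonal(item_sim, 1.0)

    assignments = post_assign(item_partition, coded_labels, item_sim, item_ids)
    return GroupResult(
        group_id=group_id,
        dendrogram=dendrogram,
        cutoff=cutoff,
        leaf_partition=leaf_partition,
        item_partition=item_partition,
        assignments=assignments,
        groups_map=groups_map,
    )


def _patient_summary(
    patient_id: str,
    corpus: Corpus,
    membership: Mapping[str, int],
    assignments: Sequence[CodeAssignment],
    truth: Mapping[str, SynthTruth] | None,
) -> PatientSummary:
    item_ids = {item.item_id for item in corpus}
    n_items = len(corpus)
    n_unique = len({item.description.strip() for item in corpus})
    n_topics = len({membership[i] for i in item_ids})
    coded_labels = corpus.coded_labels

    clustered_prf = prf_from_counts(
        evaluate_pairwise_clustering(
            {i: membership[i] for i in item_ids}, coded_labels
        )
    )
    if truth is not None:
        masked = {
            i: truth[i].true_code
            for i in item_ids
            if i in truth and truth[i].was_masked
        }
        own = [a for a in assignments if a.item_id in item_ids]
        coded_prf = prf_from_counts(evaluate_postcoding(own, masked))
    else:
        coded_prf = PrfScores(0.0, 0.0, 0.0)
    return PatientSummary(
        patient_id=patient_id,
        n_items=n_items,
        n_unique=n_unique,
        n_topics=n_topics,
        coded_fraction=len(coded_labels) / n_items,
        coded_prf=coded_prf,
        clustered_prf=clustered_prf,
    )


def run_pipeline(
    corpus: Corpus,
    config: PipelineConfig | None = None,
    truth: Mapping[str, SynthTruth] | None = None,
    output_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full grouping pipeline on a corpus.

    With ``truth`` (from the synthetic generator) masked-code recovery is
    scored; without it only the label-free pair-counting scores and the
    compression statistics are reported.  ``output_dir`` receives partition
    and assignment CSVs, Newick dendrograms and the JSON report.
    """
    if config is None:
        config = PipelineConfig()
    if len(corpus) == 0:
        raise ValueError("empty corpus")

    if config.mode == "intra":
        groups = [(pid, corpus.for_patient(pid)) for pid in corpus.patients]
    else:
        groups = [("pooled", corpus)]

    results = [
        _cluster_group(group_id, sub, config) for group_id, sub in groups
    ]

    summaries: list[PatientSummary] = []
    if config.mode == "intra":
        for (patient_id, sub), result in zip(groups, results):
            summaries.append(
                _patient_summary(
                    patient_id, sub, result.item_partition.membership,
                    result.assignments, truth,
                )
            )
    else:
        pooled = results[0]
        membership = pooled.item_partition.membership
        for patient_id in corpus.patients:
            summaries.append(
                _patient_summary(
                    patient_id, corpus.for_patient(patient_id), membership,
                    pooled.assignments, truth,
                )
            )

    report = PipelineReport(
        mode=config.mode,
        lsa_fraction=config.lsa_fraction,
        results=results,
        summaries=summaries,
        aggregate=summarize(summaries),
        has_truth=truth is not None,
    )
    if output_dir is not None:
        _write_outputs(corpus, report, Path(output_dir))
    return report


def _write_outputs(corpus: Corpus, report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cluster_ids: dict[str, object] = {}
    assigned: dict[str, object] = {}
    for result in report.results:
        for item_id, cid in result.item_partition.membership.items():
            cluster_ids[item_id] = f"{result.group_id}:{cid}"
        for a in result.assignments:
            if a.assigned_code is not None:
                assigned[a.item_id] = a.assigned_code
        with open(out / f"dendrogram_{result.group_id}.nwk", "w") as handle:
            handle.write(to_newick(result.dendrogram) + "\n")
        with open(out / f"assignments_{result.group_id}.csv", "w") as handle:
            handle.write("item_id,cluster_id,original_code,assigned_code,"
                         "source_item,similarity\n")
            membership = result.item_partition.membership
            for a in result.assignments:
                item = corpus[a.item_id]
                handle.write(
                    f"{a.item_id},{membership[a.item_id]},"
                    f"{item.code.raw if item.code else ''},"
                    f"{a.assigned_code or ''},{a.source_item or ''},"
                    f"{'' if a.similarity is None else f'{a.similarity:.6f}'}\n"
                )
    save_corpus(
        corpus,
        out / "corpus_with_clusters.csv",
        extra_columns={"cluster_id": cluster_ids, "assigned_code": assigned},
    )
    with open(out / "report.json", "w") as handle:
        json.dump(report.to_dict(), handle, indent=2, ensure_ascii=False)


def sweep_lsa(
    corpus: Corpus,
    config: PipelineConfig | None = None,
    fractions: Sequence[float] = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    truth: Mapping[str, SynthTruth] | None = None,
) -> list[dict[str, float]]:
    """Re-run the pipeline per retained-dimension fraction.

    Returns one row per fraction with the (group-averaged) inferred cut
    height and best pairwise F, mirroring a dimension-reduction sweep plot.
    """
    if config is None:
        config = PipelineConfig()
    rows = []
    for fraction in fractions:
        if not 0.0 < fraction <= 1.0:
            raise ValueError("LSA fractions must be in (0, 1]")
        report = run_pipeline(
            corpus,
            PipelineConfig(
                mode=config.mode,
                normalization=config.normalization,
                lsa_fraction=fraction,
                grid_start=config.grid_start,
                grid_stop=config.grid_stop,
                grid_step=config.grid_step,
                seed=config.seed,
            ),
            truth=truth,
        )
        rows.append(
            {
                "fraction": float(fraction),
                "best_height": float(
                    np.mean([r.cutoff.best_height for r in report.results])
                ),
                "best_f": float(np.mean([r.cutoff.best_f for r in report.results])),
            }
        )
    return rows
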