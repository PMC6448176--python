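"""Synthetic problem-list corpora with known topic structure.

Real problem lists are de-identified hospital records and cannot be shipped,
so every pipeline stage is exercised on generated corpora instead.  The
generator emulates the salient surface features of 50-character German
diagnosis entries: a small set of hidden 3-digit ICD-10 topics, each with a
canonical phrase and a few surface variants (word reorderings, umlaut
respellings, short forms), plus noise operators — per-character typos, word
abbreviation, and appended context fragments such as dates or episode
markers ("Z.n.", "ED 10.2015").  A configurable fraction of items keeps its
ICD-10 code visible; the rest are masked but retain their generating code as
hidden truth, which is what the masked-code recovery evaluation scores
against.

All randomness flows from a single seed; per-patient substreams are derived
with ``numpy.random.SeedSequence.spawn`` so that adding patients never
perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, ProblemListItem, truncate_to_category
from .vectorspace import TfIdfMatrix, LsaSpace, distance_matrix

__all__ = [
    "NoiseConfig",
    "SynthConfig",
    "SynthTruth",
    "SyntheticCorpus",
    "DEFAULT_TOPICS",
    "generate",
    "separability",
]

# (3-digit code, canonical description, surface variants).  Variants within a
# topic share the distinctive lexical core; distinctive cores are not shared
# across topics, mirroring the fact that 3-digit ICD-10 categories name
# lexically distinct conditions.
DEFAULT_TOPICS: list[tuple[str, str, list[str]]] = [
    ("N17", "Akutes Nierenversagen",
     ["Akutes Nierenversagen", "Nierenversagen akut", "Akutes Nierenversagen Stad 3"]),
    ("N18", "Chronische Niereninsuffizienz",
     ["Chronische Niereninsuffizienz", "Niereninsuffizienz chronisch",
      "Chron. Niereninsuffizienz"]),
    ("I10", "Arterielle Hypertonie",
     ["Arterielle Hypertonie", "Hypertonie arteriell", "Art. Hypertonie"]),
    ("E11", "Diabetes mellitus Typ 2",
     ["Diabetes mellitus Typ 2", "Diabetes mellitus Typ II", "Diab. mellitus Typ 2"]),
    ("E87", "Hyperkaliämie",
     ["Hyperkaliämie", "Hyperkaliaemie", "Hyperkaliämie interm."]),
    ("N39", "Harnwegsinfekt",
     ["Harnwegsinfekt", "Harnwegsinfektion", "Rez. Harnwegsinfekt"]),
    ("I48", "Vorhofflimmern",
     ["Vorhofflimmern", "Vorhofflimmern parox.", "Parox. Vorhofflimmern"]),
    ("D63", "Renale Anämie",
     ["Renale Anämie", "Anämie renal", "Renale Anaemie"]),
    ("E04", "Struma nodosa",
     ["Struma nodosa", "Struma multinodosa", "Struma nodosa bds."]),
    ("J18", "Pneumonie",
     ["Pneumonie", "Pneumonie basal", "Basale Pneumonie"]),
    ("M54", "Lumbalgie",
     ["Lumbalgie", "Lumbalgie links", "Lumbalgie bds."]),
    ("K80", "Cholezystolithiasis",
     ["Cholezystolithiasis", "Cholezystolithiasis sympt.",
      "Sympt. Cholezystolithiasis"]),
]

# appended context fragments; mostly digits/dots so the preprocessing strip
# pattern removes them again, as with real date/episode annotations
_CONTEXTS = ["seit 12.03.2004", "ED 10.2015", "12/2008", "Z.n. 2001", "ca. 2013"]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class NoiseConfig:
    """Rates of the surface-noise operators.

    The defaults realize surface variation through the per-topic variant
    lists (word order, short forms, umlaut respellings) and appended
    contexts only; random typo and truncation noise is off, which keeps
    topics linearly separable in gram space (a single typo in a short word
    can erase most of its 3-grams).  :meth:`heavy` switches the random
    operators on for degradation studies.
    """

    typo_rate: float = 0.0  # per-character substitution/deletion probability
    abbreviation_prob: float = 0.0  # per-item probability of truncating a word
    context_prob: float = 0.2  # per-item probability of an appended context
    truncate_at: int = 50

    @classmethod
    def heavy(cls) -> "NoiseConfig":
        """Typing-error and truncation rates of heavily edited lists."""
        return cls(typo_rate=0.01, abbreviation_prob=0.05, context_prob=0.2)

    def __post_init__(self) -> None:
        for name in ("typo_rate", "abbreviation_prob", "context_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.truncate_at < 1:
            raise ValueError("truncate_at must be >= 1")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic corpus generator."""

    n_patients: int = 5
    topics: Sequence[tuple[str, str, Sequence[str]]] = tuple(
        (c, d, tuple(v)) for c, d, v in DEFAULT_TOPICS
    )
    items_per_patient: tuple[int, int] = (200, 200)
    coded_fraction: float = 0.5
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    wrong_code_rate: float = 0.0  # deliberately wrong visible codes
    seed: int = 0

    def __post_init__(self) -> None:
        codes = [c for c, _, _ in self.topics]
        if len(codes) < 2:
            raise ValueError("need at least two topics")
        if len(set(codes)) != len(codes):
            raise ValueError("topic codes must be unique")
        if not 0.0 <= self.coded_fraction <= 1.0:
            raise ValueError("coded_fraction must lie in [0, 1]")
        if not 0.0 <= self.wrong_code_rate <= 1.0:
            raise ValueError("wrong_code_rate must lie in [0, 1]")
        lo, hi = self.items_per_patient
        if not 1 <= lo <= hi:
            raise ValueError("items_per_patient must be a non-empty range")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")


@dataclass(frozen=True)
class SynthTruth:
    """Hidden ground truth for one generated item."""

    true_code: str
    was_masked: bool
    mislabeled: bool = False


@dataclass
class SyntheticCorpus:
    """A generated corpus together with its hidden per-item truth."""

    corpus: Corpus
    truth: dict[str, SynthTruth]

    def masked_truth(self) -> dict[str, str]:
        """item id -> true 3-digit code, for the masked items only."""
        return {
            item_id: t.true_code for item_id, t in self.truth.items() if t.was_masked
        }

    def true_labels(self) -> dict[str, str]:
        """item id -> generating topic code, for every item."""
        return {item_id: t.true_code for item_id, t in self.truth.items()}

    def write_truth(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "item_id": item_id,
                    "true_code": t.true_code,
                    "was_masked": t.was_masked,
                    "mislabeled": t.mislabeled,
                }
                for item_id, t in self.truth.items()
            ]
        ).to_csv(path, index=False)


def _apply_typos(text: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return text
    out = []
    for ch in text:
        if ch.isalpha() and rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(rng.choice(list(_ALPHABET)))
        else:
            out.append(ch)
    return "".join(out)


def _abbreviate(text: str, rng: np.random.Generator) -> str:
    words = text.split()
    long_idx = [i for i, w in enumerate(words) if len(w) >= 8]
    if not long_idx:
        return text
    i = int(rng.choice(long_idx))
    words[i] = words[i][:8]
    return " ".join(words)


def _make_description(
    variant: str, noise: NoiseConfig, rng: np.random.Generator
) -> str:
    text = variant
    if rng.random() < noise.abbreviation_prob:
        text = _abbreviate(text, rng)
    text = _apply_typos(text, noise.typo_rate, rng)
    if rng.random() < noise.context_prob:
        text = text + " " + _CONTEXTS[rng.integers(len(_CONTEXTS))]
    text = " ".join(text.split())[: noise.truncate_at].strip()
    return text if text else variant[: noise.truncate_at]


def generate(config: SynthConfig) -> SyntheticCorpus:
    """Generate a corpus; fully deterministic given ``config.seed``."""
    substreams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    topics = list(config.topics)
    items: list[ProblemListItem] = []
    truth: dict[str, SynthTruth] = {}
    for p, seq in enumerate(substreams, start=1):
        rng = np.random.default_rng(seq)
        patient_id = f"P{p}"
        lo, hi = config.items_per_patient
        n_items = int(rng.integers(lo, hi + 1))
        for k in range(1, n_items + 1):
            code, _, variants = topics[int(rng.integers(len(topics)))]
            variant = variants[int(rng.integers(len(variants)))]
            description = _make_description(variant, config.noise, rng)
            visible = rng.random() < config.coded_fraction
            mislabeled = False
            visible_code = code
            if visible and config.wrong_code_rate > 0.0:
                if rng.random() < config.wrong_code_rate:
                    others = [c for c, _, _ in topics if c != code]
                    visible_code = others[int(rng.integers(len(others)))]
                    mislabeled = True
            item_id = f"{patient_id}-{k:04d}"
            items.append(
                ProblemListItem(
                    patient_id=patient_id,
                    item_id=item_id,
                    description=description,
                    code=truncate_to_category(visible_code) if visible else None,
                )
            )
            truth[item_id] = SynthTruth(
                true_code=code, was_masked=not visible, mislabeled=mislabeled
            )
    return SyntheticCorpus(corpus=Corpus(items), truth=truth)


def separability(
    labels: Mapping[str, str] | SyntheticCorpus,
    space: TfIdfMatrix | LsaSpace,
) -> tuple[float, float]:
    """(max within-topic distance, min between-topic distance) over all pairs.

    ``labels`` maps document ids of ``space`` to topic codes (a
    ``SyntheticCorpus`` may be passed directly; its true labels are used).
    A positive gap (min between > max within) guarantees that some cut
    height reproduces the generating topic partition exactly.
    """
    if isinstance(labels, SyntheticCorpus):
        labels = labels.true_labels()
    doc_ids = space.doc_ids
    labeled = [(i, labels[d]) for i, d in enumerate(doc_ids) if d in labels]
    codes = {c for _, c in labeled}
    if len(codes) < 2:
        raise ValueError("separability needs at least two topics")
    dist = distance_matrix(space)
    idx = np.array([i for i, _ in labeled])
    lab = np.array([c for _, c in labeled])
    sub = dist[np.ix_(idx, idx)]
    same = lab[:, None] == lab[None, :]
    triu = np.triu(np.ones_like(same, dtype=bool), k=1)
    within = sub[same & triu]
    between = sub[~same & triu]
    max_within = float(within.max()) if within.size else 0.0
    return max_within, float(between.min())
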