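"""Data model and I/O for problem-list corpora.

A problem list is the running list of a patient's diagnoses in the EHR.
Here each entry is a free-text description of at most 50 characters,
optionally linked to an ICD-10 code.  Downstream analysis only ever uses the
3-character ICD-10 category (letter + two digits, e.g. ``N17``), so codes
are normalized to that level at load time while the raw text is retained.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MAX_DESCRIPTION_LENGTH = 50

_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")

__all__ = [
    "Icd10Code",
    "ProblemListItem",
    "Corpus",
    "CorpusFormatError",
    "ValidationError",
    "truncate_to_category",
    "split_coded",
    "load_corpus",
    "save_corpus",
    "MAX_DESCRIPTION_LENGTH",
]


class ValidationError(ValueError):
    """A row or value violates the corpus data contract."""


class CorpusFormatError(ValueError):
    """The input file does not have the expected structure."""


@dataclass(frozen=True)
class Icd10Code:
    """An ICD-10 code with its 3-character category.

    Accepts codes with or without the dot and with 0-2 subcategory
    characters ("N17", "N17.0", "E875"); only ``category3`` is used by the
    clustering and evaluation stages.
    """

    raw: str
    category3: str

    def __post_init__(self) -> None:
        if not _CATEGORY_RE.match(self.category3):
            raise ValidationError(
                f"invalid ICD-10 category {self.category3!r} "
                "(expected letter + two digits)"
            )
        if not self.raw.startswith(self.category3):
            raise ValidationError(
                f"category {self.category3!r} is not a prefix of code {self.raw!r}"
            )


def truncate_to_category(code_text: str) -> Icd10Code:
    """Normalize a raw ICD-10 code and truncate it to its 3-digit category.

    Whitespace is stripped and the code uppercased; the category is the
    first three characters, which must be a letter followed by two digits.
    """
    normalized = code_text.strip().upper()
    if not normalized:
        raise ValidationError("empty ICD-10 code")
    category = normalized[:3]
    if not _CATEGORY_RE.match(category):
        raise ValidationError(
            f"cannot derive a 3-digit category from ICD-10 code {code_text!r}"
        )
    return Icd10Code(raw=normalized, category3=category)


@dataclass(frozen=True)
class ProblemListItem:
    """One 50-character problem-list entry, optionally ICD-10 coded."""

    patient_id: str
    item_id: str
    description: str
    code: Icd10Code | None = None

    def __post_init__(self) -> None:
        if not self.description.strip():
            raise ValidationError(f"item {self.item_id!r}: empty description")
        if len(self.description) > MAX_DESCRIPTION_LENGTH:
            raise ValidationError(
                f"item {self.item_id!r}: description longer than "
                f"{MAX_DESCRIPTION_LENGTH} characters"
            )

    @property
    def is_coded(self) -> bool:
        return self.code is not None


@dataclass
class Corpus:
    """An ordered collection of problem-list items with a patient index."""

    items: list[ProblemListItem]
    patients: dict[str, list[str]] = field(init=False, repr=False)
    _by_id: dict[str, ProblemListItem] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        self.patients = {}
        for item in self.items:
            if item.item_id in self._by_id:
                raise ValidationError(f"duplicate item id {item.item_id!r}")
            self._by_id[item.item_id] = item
            self.patients.setdefault(item.patient_id, []).append(item.item_id)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ProblemListItem:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    def subset(self, item_ids: Iterable[str]) -> "Corpus":
        """A new corpus containing the given items, in corpus order."""
        wanted = set(item_ids)
        return Corpus([it for it in self.items if it.item_id in wanted])

    def for_patient(self, patient_id: str) -> "Corpus":
        return Corpus([self._by_id[i] for i in self.patients[patient_id]])

    @property
    def coded_labels(self) -> dict[str, str]:
        """item id -> 3-digit category, for the coded fraction."""
        return {
            it.item_id: it.code.category3 for it in self.items if it.code is not None
        }


def split_coded(corpus: Corpus) -> tuple[list[str], list[str]]:
    """Partition item ids into (coded, uncoded) by presence of an ICD-10 code."""
    coded = [it.item_id for it in corpus if it.is_coded]
    uncoded = [it.item_id for it in corpus if not it.is_coded]
    return coded, uncoded


def _item_from_record(
    record: dict, row_label: str, permissive: bool
) -> ProblemListItem | None:
    description = str(record["description"]).strip()
    if len(description) > MAX_DESCRIPTION_LENGTH:
        if not permissive:
            raise ValidationError(
                f"{row_label}: description longer than {MAX_DESCRIPTION_LENGTH} "
                "characters (use permissive=True to truncate)"
            )
        logger.warning(
            "%s: truncating description to %d characters",
            row_label,
            MAX_DESCRIPTION_LENGTH,
        )
        description = description[:MAX_DESCRIPTION_LENGTH]
    code_text = record.get("code")
    code = None
    if code_text is not None and str(code_text).strip():
        try:
            code = truncate_to_category(str(code_text))
        except ValidationError as exc:
            raise ValidationError(f"{row_label}: {exc}") from exc
    try:
        return ProblemListItem(
            patient_id=str(record["patient_id"]),
            item_id=str(record["item_id"]),
            description=description,
            code=code,
        )
    except ValidationError as exc:
        raise ValidationError(f"{row_label}: {exc}") from exc


_REQUIRED_COLUMNS = ("patient_id", "item_id", "description")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "jsonl" if path.suffix.lower() in {".jsonl", ".json"} else "csv"


def load_corpus(
    path: str | Path, format: str | None = None, permissive: bool = False
) -> Corpus:
    """Load a problem-list corpus from CSV or JSONL.

    In strict mode (default) any malformed row raises :class:`ValidationError`
    naming the row; with ``permissive=True`` over-long descriptions are
    truncated and otherwise malformed rows are logged and skipped.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise CorpusFormatError(f"{path}: missing columns {missing}")
        records = frame.to_dict("records")
    elif fmt == "jsonl":
        records = []
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
                missing = [k for k in _REQUIRED_COLUMNS if k not in record]
                if missing:
                    raise CorpusFormatError(f"{path}:{lineno}: missing keys {missing}")
                records.append(record)
    else:
        raise CorpusFormatError(f"unknown corpus format {fmt!r}")

    items = []
    for i, record in enumerate(records, start=1):
        row_label = f"{path} row {i} (item {record.get('item_id')!r})"
        try:
            item = _item_from_record(record, row_label, permissive)
        except ValidationError:
            if permissive:
                logger.warning("%s: skipping malformed row", row_label)
                continue
            raise
        items.append(item)
    return Corpus(items)


def save_corpus(
    corpus: Corpus,
    path: str | Path,
    format: str | None = None,
    extra_columns: dict[str, dict[str, object]] | None = None,
) -> None:
    """Write a corpus as CSV or JSONL.

    ``extra_columns`` maps column name -> {item_id -> value} and is used to
    append pipeline outputs such as ``cluster_id`` and ``assigned_code``.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = []
    for item in corpus:
        row: dict[str, object] = {
            "patient_id": item.patient_id,
            "item_id": item.item_id,
            "description": item.description,
            "code": item.code.raw if item.code else "",
        }
        for column, values in (extra_columns or {}).items():
            row[column] = values.get(item.item_id, "")
        rows.append(row)
    if fmt == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as handle:
            for row in rows:
                handle.write(json.dumps(row, ensure_ascii=False) + "\n")
    else:
        raise CorpusFormatError(f"unknown corpus format {fmt!r}")
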