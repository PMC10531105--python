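"""Core data model for labeled radiology-report corpora.

A record holds the free-text *conclusion* section of one CT report together
with a 4-class disease-response label (NED / PR / SD / PD).  Corpora are
serialized as UTF-8 JSON-lines and split at the *patient* level so that no
patient's reports leak across train/dev/test.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseLabel",
    "ReportRecord",
    "Corpus",
    "SplitSpec",
    "CorpusFormatError",
    "CorpusIntegrityError",
    "read_corpus",
    "write_corpus",
    "split_by_patient",
    "class_distribution",
    "largest_remainder",
]

SPLITS = ("train", "dev", "test", "unassigned")


class ResponseLabel(IntEnum):
    """Four-class disease response; the code <-> name bijection is fixed."""

    NED = 0  # no evidence of disease
    PR = 1   # partial response
    SD = 2   # stable disease
    PD = 3   # progressive disease

    @classmethod
    def parse(cls, value: "int | str | ResponseLabel") -> "ResponseLabel":
        """Accept a member, an integer code, or a (case-insensitive) name."""
        if isinstance(value, cls):
            return value
        if isinstance(value, bool):
            raise ValueError(f"invalid label: {value!r}")
        if isinstance(value, int):
            return cls(value)
        if isinstance(value, str):
            s = value.strip()
            if s.lstrip("-").isdigit():
                return cls(int(s))
            try:
                return cls[s.upper()]
            except KeyError:
                raise ValueError(f"unknown response label name: {value!r}") from None
        raise ValueError(f"invalid label: {value!r}")


N_CLASSES = len(ResponseLabel)  # C = 4

_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Collapse runs of whitespace to single spaces and strip the ends."""
    return _WS.sub(" ", text).strip()


class CorpusFormatError(ValueError):
    """A record line could not be parsed."""


class CorpusIntegrityError(ValueError):
    """Corpus-level invariant violated (duplicate ids, split leakage...)."""


@dataclass(frozen=True)
class ReportRecord:
    report_id: str
    patient_id: str
    conclusion_text: str
    label: ResponseLabel
    split: str = "unassigned"
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if not normalize_text(self.conclusion_text):
            raise ValueError(
                f"record {self.report_id!r}: conclusion_text is empty after "
                "whitespace normalization"
            )
        if self.split not in SPLITS:
            raise ValueError(f"record {self.report_id!r}: unknown split {self.split!r}")
        if self.provenance not in ("synthetic", "external"):
            raise ValueError(
                f"record {self.report_id!r}: unknown provenance {self.provenance!r}"
            )

    def with_split(self, split: str) -> "ReportRecord":
        return replace(self, split=split)


class Corpus:
    """Ordered collection of ReportRecords with a patient index."""

    def __init__(self, records: Iterable[ReportRecord]):
        self.records: list[ReportRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.report_id in seen:
                raise CorpusIntegrityError(f"duplicate report_id {rec.report_id!r}")
            seen.add(rec.report_id)
        self.patient_index: dict[str, list[str]] = {}
        for rec in self.records:
            self.patient_index.setdefault(rec.patient_id, []).append(rec.report_id)
        # patient-level split consistency (ignoring unassigned)
        by_patient: dict[str, set[str]] = {}
        for rec in self.records:
            if rec.split != "unassigned":
                by_patient.setdefault(rec.patient_id, set()).add(rec.split)
        for pid, splits in by_patient.items():
            if len(splits) > 1:
                raise CorpusIntegrityError(
                    f"patient {pid!r} spans multiple splits: {sorted(splits)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReportRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ReportRecord:
        return self.records[i]

    @property
    def patients(self) -> list[str]:
        return list(self.patient_index)

    def subset(self, split: str) -> "Corpus":
        """Records carrying the given split tag, in corpus order."""
        return Corpus(r for r in self.records if r.split == split)

    def texts(self) -> list[str]:
        return [r.conclusion_text for r in self.records]

    def labels(self) -> list[ResponseLabel]:
        return [r.label for r in self.records]


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.fractions
        if len(f) != 3 or any(not (0.0 < x < 1.0) for x in f):
            raise ValueError(f"fractions must be three values in (0,1), got {f}")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got sum={sum(f)!r}")


_REQUIRED_KEYS = ("report_id", "patient_id", "conclusion_text", "label")


def read_corpus(path: "str | Path") -> Corpus:
    """Read a JSON-lines corpus; malformed lines are reported with numbers."""
    path = Path(path)
    records: list[ReportRecord] = []
    errors: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                errors.append(f"line {lineno}: invalid JSON ({exc.msg})")
                continue
            missing = [k for k in _REQUIRED_KEYS if k not in obj]
            if missing:
                errors.append(f"line {lineno}: missing field(s) {', '.join(missing)}")
                continue
            try:
                records.append(
                    ReportRecord(
                        report_id=str(obj["report_id"]),
                        patient_id=str(obj["patient_id"]),
                        conclusion_text=str(obj["conclusion_text"]),
                        label=ResponseLabel.parse(obj["label"]),
                        split=obj.get("split", "unassigned"),
                        provenance=obj.get("provenance", "external"),
                    )
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise CorpusFormatError(f"{path}: " + "; ".join(errors))
    return Corpus(records)


def write_corpus(corpus: Corpus, path: "str | Path") -> None:
    """Write JSON-lines; read_corpus(write_corpus(c)) is the identity."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus:
            obj = {
                "report_id": rec.report_id,
                "patient_id": rec.patient_id,
                "conclusion_text": rec.conclusion_text,
                "label": rec.label.name,
                "split": rec.split,
                "provenance": rec.provenance,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    """Apportion `total` items over fractions by the largest-remainder rule.

    Ties in the remainders are broken toward lower index, which keeps the
    allocation deterministic.
    """
    quotas = [total * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    short = total - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


def split_by_patient(corpus: Corpus, spec: SplitSpec) -> Corpus:
    """Assign train/dev/test split tags at the patient level.

    Sorted patient ids are shuffled with a seeded generator and cut according
    to a largest-remainder apportionment of the fractions over the patient
    count, so the same seed always produces the same assignment.
    """
    patients = sorted(corpus.patient_index)
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients to split, got {len(patients)}")
    rng = np.random.default_rng(spec.seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    counts = largest_remainder(len(patients), spec.fractions)
    assignment: dict[str, str] = {}
    start = 0
    for split_name, n in zip(("train", "dev", "test"), counts):
        for pid in order[start : start + n]:
            assignment[pid] = split_name
        start += n
    return Corpus(rec.with_split(assignment[rec.patient_id]) for rec in corpus)


def class_distribution(corpus: Corpus) -> pd.DataFrame:
    """Per-split and total class counts and percentages (1 decimal place).

    Returns a tidy frame with columns ``split, label, count, percent``;
    the percent column is computed within each split (and within "total").
    """
    if len(corpus) == 0:
        raise ValueError("class_distribution: empty corpus")
    rows = []
    splits_present = [s for s in SPLITS if any(r.split == s for r in corpus)]
    groups: list[tuple[str, list[ReportRecord]]] = [
        (s, [r for r in corpus if r.split == s]) for s in splits_present
    ]
    groups.append(("total", list(corpus)))
    for split_name, recs in groups:
        n = len(recs)
        for label in ResponseLabel:
            count = sum(1 for r in recs if r.label == label)
            rows.append(
                {
                    "split": split_name,
                    "label": label.name,
                    "count": count,
                    "percent": round(100.0 * count / n, 1),
                }
            )
    return pd.DataFrame(rows, columns=["split", "label", "count", "percent"])
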