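"""Reading, preprocessing and partitioning of free-text record collections.

A record is one clinical event: an opaque id, an optional patient id, an
optional event date, an optional diagnostic code, and a free-text entry.
Text is reduced to a *set* of lower-cased word stems — case, punctuation,
word order and repetition carry no signal for the set-covering learner.

Collections are read from delimited (default tab-separated) or JSON-lines
files. Training partitions are built from diagnostic codes alone: records
carrying a code of interest form the positive set P, records from a
designated negative source (control patients or an external collection)
form N, and everything else on the case side is unlabelled (U). Manual
review labels (``gold``) exist only for evaluation and are never consulted
when partitioning or training.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CorpusFormatError, DuplicateRecordError, PartitionError
from .stemming import porter_stem

_TOKEN_RE = re.compile(r"[a-z0-9]+")

ROLE_POSITIVE = "positive"
ROLE_NEGATIVE = "negative"
ROLE_UNLABELLED = "unlabelled"
_ROLES = (ROLE_POSITIVE, ROLE_NEGATIVE, ROLE_UNLABELLED)

_COLUMNS = ("record_id", "patient_id", "event_date", "code", "text", "gold", "role")


def preprocess(raw_text: str, *, stem: bool = True,
               stoplist: frozenset[str] | None = None) -> frozenset[str]:
    """Reduce free text to a set of lower-cased word stems.

    Splits on any non-alphanumeric character, keeps numeric tokens
    (clinical texts carry counts such as vessel numbers), and stems each
    token unless ``stem`` is False. Empty input yields the empty set.
    """
    tokens = _TOKEN_RE.findall(raw_text.lower())
    if stem:
        tokens = [porter_stem(t) for t in tokens]
    out = frozenset(tokens)
    if stoplist:
        out = out - stoplist
    return out


@dataclass(frozen=True)
class TextRecord:
    """One free-text clinical event with its code-derived label role."""

    record_id: str
    raw_text: str
    tokens: frozenset[str]
    patient_id: str | None = None
    event_date: datetime.date | None = None
    code: str | None = None
    role: str = ROLE_UNLABELLED
    gold: bool | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        for t in self.tokens:
            if not t or t != t.lower():
                raise ValueError(f"token {t!r} must be non-empty lower-case")

    def masked(self) -> "TextRecord":
        """Copy with the manual-review label hidden (for training paths)."""
        return replace(self, gold=None)


def make_record(record_id: str, text: str, *, patient_id: str | None = None,
                event_date: datetime.date | str | None = None,
                code: str | None = None, role: str = ROLE_UNLABELLED,
                gold: bool | None = None, stem: bool = True,
                stoplist: frozenset[str] | None = None) -> TextRecord:
    """Build a TextRecord, populating tokens via :func:`preprocess`."""
    if isinstance(event_date, str):
        event_date = datetime.date.fromisoformat(event_date) if event_date else None
    return TextRecord(
        record_id=str(record_id),
        raw_text=text,
        tokens=preprocess(text, stem=stem, stoplist=stoplist),
        patient_id=patient_id or None,
        event_date=event_date,
        code=code or None,
        role=role,
        gold=gold,
    )


@dataclass(frozen=True)
class TrainingPartition:
    """Disjoint positive (P), unlabelled (U) and negative (N) record sets."""

    P: tuple[TextRecord, ...]
    U: tuple[TextRecord, ...]
    N: tuple[TextRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "P", tuple(self.P))
        object.__setattr__(self, "U", tuple(self.U))
        object.__setattr__(self, "N", tuple(self.N))
        seen: set[str] = set()
        for rec in self.records():
            if rec.record_id in seen:
                raise PartitionError(
                    f"record_id {rec.record_id!r} appears in more than one set"
                )
            seen.add(rec.record_id)

    def records(self) -> tuple[TextRecord, ...]:
        return self.P + self.U + self.N

    def masked(self) -> "TrainingPartition":
        """Partition with all gold labels hidden; training consumes this."""
        return TrainingPartition(
            P=tuple(r.masked() for r in self.P),
            U=tuple(r.masked() for r in self.U),
            N=tuple(r.masked() for r in self.N),
        )


def _parse_gold(value: str | bool | None) -> bool | None:
    if value is None or value == "":
        return None
    if isinstance(value, bool):
        return value
    v = str(value).strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no"):
        return False
    raise CorpusFormatError(f"unparseable gold label {value!r}")


def _rows_from_delimited(path: Path, sep: str) -> list[dict]:
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("record_id", "text"):
        if col not in frame.columns:
            raise CorpusFormatError(f"required column {col!r} missing from {path}")
    return frame.to_dict("records")


def _rows_from_jsonlines(path: Path) -> list[dict]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: invalid JSON") from exc
            for key in ("record_id", "text"):
                if key not in obj:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: required key {key!r} missing"
                    )
            rows.append(obj)
    return rows


def load_corpus(path: str | Path, *, format: str = "delimited", sep: str = "\t",
                drop_blank: bool = True, dedupe: bool = True, stem: bool = True,
                stoplist: frozenset[str] | None = None) -> list[TextRecord]:
    """Load a record collection and preprocess every text.

    Blank texts are dropped and duplicates removed (keyed on the
    post-preprocessing token set within the same patient, keeping the first
    occurrence) unless disabled. Duplicate record ids are an error.
    """
    path = Path(path)
    if format == "delimited":
        rows = _rows_from_delimited(path, sep)
    elif format == "jsonlines":
        rows = _rows_from_jsonlines(path)
    else:
        raise CorpusFormatError(f"unknown corpus format {format!r}")

    records: list[TextRecord] = []
    seen_ids: set[str] = set()
    seen_keys: set[tuple[str | None, frozenset[str]]] = set()
    for row in rows:
        rid = str(row["record_id"])
        if rid in seen_ids:
            raise DuplicateRecordError(f"duplicate record_id {rid!r} in {path}")
        seen_ids.add(rid)
        text = str(row.get("text", ""))
        if drop_blank and not text.strip():
            continue
        rec = make_record(
            rid, text,
            patient_id=str(row.get("patient_id") or "") or None,
            event_date=str(row.get("event_date") or "") or None,
            code=str(row.get("code") or "") or None,
            role=str(row.get("role") or "") or ROLE_UNLABELLED,
            gold=_parse_gold(row.get("gold")),
            stem=stem, stoplist=stoplist,
        )
        if dedupe:
            key = (rec.patient_id, rec.tokens)
            if key in seen_keys:
                continue
            seen_keys.add(key)
        records.append(rec)
    return records


def write_corpus(records: Iterable[TextRecord], path: str | Path, *,
                 sep: str = "\t") -> None:
    """Write records in the delimited input format (round-trips with load)."""
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "patient_id": r.patient_id or "",
            "event_date": r.event_date.isoformat() if r.event_date else "",
            "code": r.code or "",
            "text": r.raw_text,
            "gold": "" if r.gold is None else str(int(r.gold)),
            "role": r.role,
        })
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, sep=sep, index=False)


def load_code_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text code list: one code per line, ``#`` comments."""
    codes = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                codes.add(line)
    return frozenset(codes)


def partition_by_code(records: Sequence[TextRecord],
                      positive_codes: Iterable[str],
                      negatives: Sequence[TextRecord] = ()) -> TrainingPartition:
    """Build a training partition from diagnostic codes only.

    Records whose code is in ``positive_codes`` become P; the supplied
    negative-source records (control patients or an external collection)
    become N; all remaining case-side records are unlabelled. Gold labels
    play no part in the assignment.
    """
    positive_codes = frozenset(positive_codes)
    if not positive_codes:
        raise PartitionError("positive_codes must be non-empty")
    neg_ids = {r.record_id for r in negatives}
    for r in negatives:
        if r.code in positive_codes:
            raise PartitionError(
                f"negative-source record {r.record_id!r} carries a positive code"
            )
    P, U, N = [], [], list(replace(r, role=ROLE_NEGATIVE) for r in negatives)
    for r in records:
        if r.record_id in neg_ids:
            raise PartitionError(
                f"record {r.record_id!r} appears in both case and negative sources"
            )
        if r.code in positive_codes:
            P.append(replace(r, role=ROLE_POSITIVE))
        else:
            U.append(replace(r, role=ROLE_UNLABELLED))
    return TrainingPartition(P=tuple(P), U=tuple(U), N=tuple(N))


def partition_from_roles(records: Sequence[TextRecord]) -> TrainingPartition:
    """Rebuild a partition from the ``role`` field of stored records."""
    P = tuple(r for r in records if r.role == ROLE_POSITIVE)
    U = tuple(r for r in records if r.role == ROLE_UNLABELLED)
    N = tuple(r for r in records if r.role == ROLE_NEGATIVE)
    return TrainingPartition(P=P, U=U, N=N)


def prepend_code_term(record: TextRecord, term_lookup: Mapping[str, str], *,
                      stem: bool = True,
                      stoplist: frozenset[str] | None = None) -> TextRecord:
    """Recompute tokens over the code's human-readable term plus the text.

    Emulates how a coded entry is displayed alongside its term on screen:
    the term's words become part of the record's token set, making short
    or empty texts informative. The original raw text is preserved. Records
    without a code, or with a code missing from the lookup, are returned
    unchanged.
    """
    if record.code is None or record.code not in term_lookup:
        return record
    term = term_lookup[record.code]
    tokens = preprocess(term + " " + record.raw_text, stem=stem, stoplist=stoplist)
    return replace(record, tokens=tokens)
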