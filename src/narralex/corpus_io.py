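"""Corpus loading, author merging, and group splitting.

A corpus is a collection of narratives, each written either by a person with
lived experience (a first-person account, FPA) or by a family member, friend
or clinician (a third-person account, TPA).  FPAs may additionally carry a
human-coded binary flag marking narratives whose text was judged to describe
interpersonal difficulties (social anxiety, no close friends, constricted
affect).  Prolific authors publish several narratives; all works by one
author are merged into a single record before any analysis.
"""

from __future__ import annotations

import csv
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACCOUNT_TYPES = ("FPA", "TPA")

#: group labels produced by :func:`split_groups`
GROUP_FPA = "FPA"
GROUP_TPA = "TPA"
GROUP_FPA_ID = "FPA_ID"
GROUP_FPA_NOID = "FPA_noID"


class CorpusValidationError(ValueError):
    """Metadata or record-level validation failure."""


class CorpusLoadError(OSError):
    """A referenced narrative file could not be read."""


@dataclass(frozen=True)
class NarrativeRecord:
    """One narrative plus its grouping metadata."""

    narrative_id: str
    author_id: str
    text: str
    account_type: str
    interpersonal_difficulties: Optional[bool] = None
    publication_order: int = 0

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise CorpusValidationError(
                f"narrative {self.narrative_id!r}: empty text"
            )
        if self.account_type not in ACCOUNT_TYPES:
            raise CorpusValidationError(
                f"narrative {self.narrative_id!r}: unknown account_type "
                f"{self.account_type!r} (expected one of {ACCOUNT_TYPES})"
            )
        if self.publication_order < 0:
            raise CorpusValidationError(
                f"narrative {self.narrative_id!r}: negative publication_order"
            )


@dataclass
class CorpusTable:
    """Ordered collection of narratives with a provenance note."""

    records: list[NarrativeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.narrative_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(f"duplicate narrative_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "narrative_id": [r.narrative_id for r in self.records],
                "author_id": [r.author_id for r in self.records],
                "account_type": [r.account_type for r in self.records],
                "interpersonal_difficulties": [
                    r.interpersonal_difficulties for r in self.records
                ],
                "publication_order": [r.publication_order for r in self.records],
                "text": [r.text for r in self.records],
            }
        )


@dataclass
class RaterCodingTable:
    """Item x rater matrix of nominal codes; NaN marks a missing code."""

    item_ids: list[str]
    rater_ids: list[str]
    codes: np.ndarray  # shape (n_items, n_raters), float with NaN for missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.item_ids), len(self.rater_ids)):
            raise CorpusValidationError("codes shape does not match ids")
        if len(self.rater_ids) < 2:
            raise CorpusValidationError("at least 2 raters required")
        pairable = (~np.isnan(self.codes)).sum(axis=1) >= 2
        if pairable.sum() < 2:
            raise CorpusValidationError(
                "at least 2 items with >=2 non-missing codes required"
            )


_BOOL_TOKENS = {
    "true": True, "1": True, "yes": True, "t": True,
    "false": False, "0": False, "no": False, "f": False,
    "": None, "na": None, "nan": None, "none": None,
}


def _parse_flag(token) -> Optional[bool]:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    if isinstance(token, (bool, np.bool_)):
        return bool(token)
    s = str(token).strip().lower()
    if s not in _BOOL_TOKENS:
        raise CorpusValidationError(
            f"unrecognized interpersonal_difficulties value {token!r}"
        )
    return _BOOL_TOKENS[s]


def normalize_text(raw: str) -> str:
    """NFC-normalize, fold line endings to \\n, map curly apostrophes to '."""
    text = unicodedata.normalize("NFC", raw)
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    # typographic apostrophes interfere with token matching ("don’t" vs "don't")
    return text.replace("’", "'").replace("‘", "'")


def load_corpus(metadata_path, text_dir) -> CorpusTable:
    """Read a metadata table (CSV or TSV) plus a directory of UTF-8 .txt files.

    Required metadata columns: ``narrative_id``, ``author_id``, ``file``,
    ``account_type``; optional: ``interpersonal_difficulties``,
    ``publication_order``.
    """
    metadata_path = Path(metadata_path)
    text_dir = Path(text_dir)
    sep = "\t" if metadata_path.suffix.lower() in {".tsv", ".tab"} else ","
    meta = pd.read_csv(metadata_path, sep=sep, dtype=str, keep_default_na=False)
    required = {"narrative_id", "author_id", "file", "account_type"}
    missing = required - set(meta.columns)
    if missing:
        raise CorpusValidationError(f"metadata missing columns: {sorted(missing)}")

    records = []
    for _, row in meta.iterrows():
        nid = row["narrative_id"]
        path = text_dir / row["file"]
        try:
            raw = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise CorpusLoadError(
                f"narrative {nid!r}: cannot read {path}: {exc}"
            ) from exc
        flag = _parse_flag(row.get("interpersonal_difficulties"))
        order_tok = str(row.get("publication_order", "") or "").strip()
        order = int(order_tok) if order_tok else 0
        records.append(
            NarrativeRecord(
                narrative_id=nid,
                author_id=row["author_id"],
                text=normalize_text(raw),
                account_type=row["account_type"],
                interpersonal_difficulties=flag,
                publication_order=order,
            )
        )
    return CorpusTable(records=records, provenance=f"loaded from {metadata_path}")


def merge_by_author(corpus: CorpusTable) -> CorpusTable:
    """Combine all narratives by one author into a single record.

    Texts are concatenated in ascending publication order (ties broken by
    narrative_id), separated by a blank line.  The interpersonal-difficulties
    flag of the merged record is the logical OR of the coded components: a
    mention anywhere in an author's works marks the author.  Idempotent.
    """
    by_author: dict[str, list[NarrativeRecord]] = {}
    order = []
    for rec in corpus.records:
        if rec.author_id not in by_author:
            order.append(rec.author_id)
        by_author.setdefault(rec.author_id, []).append(rec)

    merged = []
    for author in order:
        group = sorted(
            by_author[author], key=lambda r: (r.publication_order, r.narrative_id)
        )
        kinds = {r.account_type for r in group}
        if len(kinds) > 1:
            raise CorpusValidationError(
                f"author {author!r}: conflicting account_type values {sorted(kinds)}"
            )
        flags = [r.interpersonal_difficulties for r in group]
        coded = [f for f in flags if f is not None]
        flag = any(coded) if coded else None
        merged.append(
            NarrativeRecord(
                narrative_id=author,
                author_id=author,
                text="\n\n".join(r.text for r in group),
                account_type=group[0].account_type,
                interpersonal_difficulties=flag,
                publication_order=group[0].publication_order,
            )
        )
    return CorpusTable(records=merged, provenance=corpus.provenance + " | author-merged")


def split_groups(corpus: CorpusTable) -> dict[str, CorpusTable]:
    """Split a merged corpus into {FPA, TPA, FPA_ID, FPA_noID} subsets.

    FPA = FPA_ID U FPA_noID (disjoint); FPAs lacking an
    interpersonal-difficulties code fall in the FPA subset only and are
    logged.  Any code on a TPA record is ignored.
    """
    subsets: dict[str, list[NarrativeRecord]] = {
        GROUP_FPA: [], GROUP_TPA: [], GROUP_FPA_ID: [], GROUP_FPA_NOID: []
    }
    for rec in corpus.records:
        if rec.account_type == "TPA":
            subsets[GROUP_TPA].append(rec)
            continue
        subsets[GROUP_FPA].append(rec)
        if rec.interpersonal_difficulties is None:
            logger.warning(
                "FPA %r has no interpersonal_difficulties code; "
                "excluded from the ID split", rec.narrative_id,
            )
        elif rec.interpersonal_difficulties:
            subsets[GROUP_FPA_ID].append(rec)
        else:
            subsets[GROUP_FPA_NOID].append(rec)
    return {
        label: CorpusTable(records=recs, provenance=f"{corpus.provenance} | {label}")
        for label, recs in subsets.items()
    }


def write_corpus_tsv(corpus: CorpusTable, path) -> None:
    """Write the canonical single-file snapshot (newlines escaped as \\n)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["narrative_id", "author_id", "account_type",
             "interpersonal_difficulties", "publication_order", "text"]
        )
        for r in corpus.records:
            flag = "" if r.interpersonal_difficulties is None else str(
                r.interpersonal_difficulties).lower()
            writer.writerow(
                [r.narrative_id, r.author_id, r.account_type, flag,
                 r.publication_order,
                 r.text.replace("\\", "\\\\").replace("\n", "\\n")]
            )


def read_corpus_tsv(path) -> CorpusTable:
    """Inverse of :func:`write_corpus_tsv`."""
    path = Path(path)
    records = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        idx = {name: i for i, name in enumerate(header)}
        for row in reader:
            text = row[idx["text"]]
            # unescape \n first on a placeholder-free pass: split on literal \\
            parts = text.split("\\\\")
            text = "\\".join(p.replace("\\n", "\n") for p in parts)
            records.append(
                NarrativeRecord(
                    narrative_id=row[idx["narrative_id"]],
                    author_id=row[idx["author_id"]],
                    text=text,
                    account_type=row[idx["account_type"]],
                    interpersonal_difficulties=_parse_flag(
                        row[idx["interpersonal_difficulties"]]),
                    publication_order=int(row[idx["publication_order"]] or 0),
                )
            )
    return CorpusTable(records=records, provenance=f"loaded from {path}")


def load_rater_codes(path) -> RaterCodingTable:
    """Read an item x rater CSV of nominal codes (first column = item id)."""
    df = pd.read_csv(path, index_col=0)
    return RaterCodingTable(
        item_ids=[str(i) for i in df.index],
        rater_ids=[str(c) for c in df.columns],
        codes=df.to_numpy(dtype=float),
    )
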