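"""Readers and writers for mention corpora and normalization records.

Two families of formats are supported: BioNLP-ST standoff (``.a1`` entity
spans, ``.a2`` normalization annotations, as distributed for the Bacteria
Biotope tasks) and plain TSV for mentions, gold normalizations, predictions
and pre-computed constituency parses.  Character offsets are 0-based
half-open.  Parse tables are keyed ``doc_id:mention_id`` because standoff
mention ids restart in every document.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

from .syntax import ParseNode, parse_bracketed

__all__ = [
    "Mention",
    "NormalizationRecord",
    "Prediction",
    "CorpusFormatError",
    "read_a1",
    "read_a2",
    "write_a2",
    "read_mentions_tsv",
    "read_gold_tsv",
    "write_mentions_tsv",
    "write_gold_tsv",
    "read_parse_table",
    "write_parse_table",
    "read_predictions",
    "write_predictions",
]


class CorpusFormatError(ValueError):
    """Malformed corpus or annotation input."""


@dataclass
class Mention:
    """An annotated entity span (possibly discontinuous)."""

    doc_id: str
    mention_id: str  # e.g. "T3"
    entity_type: str
    spans: list[tuple[int, int]]  # 0-based half-open fragments
    text: str

    @property
    def key(self) -> str:
        return f"{self.doc_id}:{self.mention_id}"


@dataclass
class NormalizationRecord:
    """Gold or predicted concept assignment(s) for one mention."""

    doc_id: str
    mention_id: str
    concept_ids: list[str]

    @property
    def key(self) -> str:
        return f"{self.doc_id}:{self.mention_id}"


@dataclass
class Prediction:
    """One linker output row."""

    doc_id: str
    mention_id: str
    mention_text: str
    concept_id: str
    score: float
    fallback: str = ""  # empty when the normal pipeline produced the answer


def read_a1(stream: Iterable[str], doc_id: str = "") -> list[Mention]:
    """Read a BioNLP-ST ``.a1`` entity file.

    Lines are ``Tn<TAB>TYPE s1 e1[;s2 e2...]<TAB>text``; discontinuous
    spans are kept as fragments.  Non-entity lines (ids not starting with
    T) are ignored.
    """
    mentions: list[Mention] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise CorpusFormatError(f"line {lineno}: expected 3 tab fields")
        mid, type_and_spans, text = parts[0], parts[1], parts[2]
        if not mid.startswith("T"):
            continue
        if mid in seen:
            raise CorpusFormatError(f"line {lineno}: duplicate mention id {mid}")
        seen.add(mid)
        head, _, span_str = type_and_spans.partition(" ")
        spans: list[tuple[int, int]] = []
        for frag in span_str.split(";"):
            nums = frag.split()
            if len(nums) != 2:
                raise CorpusFormatError(f"line {lineno}: malformed span {frag!r}")
            try:
                start, end = int(nums[0]), int(nums[1])
            except ValueError:
                raise CorpusFormatError(
                    f"line {lineno}: non-integer offset in {frag!r}"
                ) from None
            if end < start or start < 0:
                raise CorpusFormatError(f"line {lineno}: invalid span {frag!r}")
            spans.append((start, end))
        mentions.append(
            Mention(doc_id=doc_id, mention_id=mid, entity_type=head, spans=spans, text=text)
        )
    return mentions


def write_a1(mentions: Iterable[Mention], fh: IO[str]) -> None:
    for m in mentions:
        spans = ";".join(f"{s} {e}" for s, e in m.spans)
        fh.write(f"{m.mention_id}\t{m.entity_type} {spans}\t{m.text}\n")


def read_a2(
    stream: Iterable[str], doc_id: str = "", resource: str = "OntoBiotope"
) -> list[NormalizationRecord]:
    """Read a ``.a2`` normalization file.

    Lines are ``Nn<TAB><resource> Annotation:Tm Referent:<concept>``;
    multiple referents for one mention are merged into a single record.
    Reading is permissive about unknown mention ids (validation is the
    caller's concern).
    """
    by_mention: dict[str, NormalizationRecord] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise CorpusFormatError(f"line {lineno}: expected 2 tab fields")
        fields = dict(
            kv.split(":", 1) for kv in parts[1].split()[1:] if ":" in kv
        )
        if "Annotation" not in fields or "Referent" not in fields:
            raise CorpusFormatError(
                f"line {lineno}: missing Annotation or Referent in {parts[1]!r}"
            )
        mid, concept = fields["Annotation"], fields["Referent"]
        rec = by_mention.setdefault(
            mid, NormalizationRecord(doc_id=doc_id, mention_id=mid, concept_ids=[])
        )
        if concept not in rec.concept_ids:
            rec.concept_ids.append(concept)
    return list(by_mention.values())


def write_a2(
    records: Iterable[NormalizationRecord], fh: IO[str], resource: str = "OntoBiotope"
) -> None:
    n = 0
    for rec in records:
        for concept in rec.concept_ids:
            n += 1
            fh.write(f"N{n}\t{resource} Annotation:{rec.mention_id} Referent:{concept}\n")


def read_mentions_tsv(stream: Iterable[str]) -> list[Mention]:
    """Read the generic mention TSV: ``doc_id<TAB>mention_id<TAB>text``."""
    mentions = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise CorpusFormatError(f"line {lineno}: expected >=3 tab fields")
        mentions.append(
            Mention(
                doc_id=parts[0],
                mention_id=parts[1],
                entity_type="",
                spans=[],
                text=parts[2],
            )
        )
    return mentions


def read_gold_tsv(stream: Iterable[str]) -> list[NormalizationRecord]:
    """Read gold TSV: ``doc_id<TAB>mention_id<TAB>text<TAB>concept_id``.

    Several rows for one mention merge their concept ids into one record.
    """
    by_key: dict[tuple[str, str], NormalizationRecord] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise CorpusFormatError(
                f"line {lineno}: gold rows need 4 tab fields (concept id missing?)"
            )
        key = (parts[0], parts[1])
        rec = by_key.setdefault(
            key, NormalizationRecord(doc_id=parts[0], mention_id=parts[1], concept_ids=[])
        )
        if parts[3] not in rec.concept_ids:
            rec.concept_ids.append(parts[3])
    return list(by_key.values())


def write_mentions_tsv(mentions: Iterable[Mention], fh: IO[str]) -> None:
    for m in mentions:
        fh.write(f"{m.doc_id}\t{m.mention_id}\t{m.text}\n")


def write_gold_tsv(records: Iterable[NormalizationRecord], fh: IO[str], texts=None) -> None:
    texts = texts or {}
    for rec in records:
        for concept in rec.concept_ids:
            fh.write(f"{rec.doc_id}\t{rec.mention_id}\t{texts.get(rec.key, '')}\t{concept}\n")


def read_parse_table(stream: Iterable[str]) -> dict[str, ParseNode]:
    """Read ``doc_id:mention_id<TAB>bracketed_parse`` rows."""
    table: dict[str, ParseNode] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        key, _, bracketed = line.partition("\t")
        if not bracketed:
            raise CorpusFormatError(f"line {lineno}: expected 2 tab fields")
        table[key] = parse_bracketed(bracketed)
    return table


def write_parse_table(parses: dict[str, str], fh: IO[str]) -> None:
    for key, bracketed in parses.items():
        fh.write(f"{key}\t{bracketed}\n")


def read_predictions(stream: Iterable[str]) -> list[Prediction]:
    preds = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise CorpusFormatError(f"line {lineno}: expected >=5 tab fields")
        preds.append(
            Prediction(
                doc_id=parts[0],
                mention_id=parts[1],
                mention_text=parts[2],
                concept_id=parts[3],
                score=float(parts[4]),
                fallback=parts[5] if len(parts) > 5 else "",
            )
        )
    return preds


def write_predictions(preds: Iterable[Prediction], fh: IO[str]) -> None:
    for p in preds:
        fh.write(
            f"{p.doc_id}\t{p.mention_id}\t{p.mention_text}\t{p.concept_id}"
            f"\t{p.score:.6f}\t{p.fallback}\n"
        )
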