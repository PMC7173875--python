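"""Typed entity dictionaries (lexicons) for dictionary-based NER.

A lexicon maps surface strings — a primary label plus synonyms — to opaque
entity ids of a single type (``disease``, ``phenotype`` or ``gene``).  The
three lexicons stand in for the rare-disease nomenclature (ORPHA ids), the
Human Phenotype Ontology (HP ids) and the gene nomenclature (HGNC ids) that
a production deployment would load.

Surface vocabularies of the three types overlap heavily in practice (the
same string can name a gene and a phenotype); overlaps are *detected* here
(:func:`find_overlaps`) but deliberately not removed — ambiguous mentions
are arbitrated downstream by the annotator's conflict-resolution precedence
rule.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("disease", "phenotype", "gene")

#: precedence used by the conflict resolver: lower index wins
TYPE_PRECEDENCE = {"phenotype": 0, "disease": 1, "gene": 2}

_WS_RE = re.compile(r"\s+")
_EDGE_PUNCT_RE = re.compile(r"^[^\w]+|[^\w]+$")


class LexiconFormatError(ValueError):
    """Raised when a lexicon TSV is malformed."""


def normalize_term(term: str) -> str:
    """Normalize a surface term for matching and overlap detection.

    Lowercases, collapses internal whitespace and strips punctuation at the
    term boundaries only (interior hyphens/punctuation are kept, so
    ``"GATA-1"`` and ``"gata-1"`` collide but ``"gata1"`` does not).
    """
    term = _WS_RE.sub(" ", term.strip()).lower()
    return _EDGE_PUNCT_RE.sub("", term)


def _clean_term(term: str) -> str:
    """Whitespace-normalize a term, preserving its original case."""
    return _WS_RE.sub(" ", term.strip())


@dataclass(frozen=True)
class LexiconEntry:
    """One entity: an id, its type, and its set of surface terms."""

    entity_id: str
    entity_type: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity_type {self.entity_type!r}")
        if not self.terms or any(not t.strip() for t in self.terms):
            raise ValueError(f"entry {self.entity_id}: terms must be non-empty")


@dataclass
class Lexicon:
    """A collection of entries of one entity type plus a stoplist.

    The term index (normalized term -> ids carrying it) is rebuilt
    deterministically from the entries; it is never serialized.
    """

    entity_type: str
    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    stoplist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity_type {self.entity_type!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def term_index(self) -> dict[str, tuple[str, ...]]:
        """Normalized term -> sorted tuple of entity ids carrying it.

        Stoplisted terms are excluded, so the index is what the annotator
        may match against.
        """
        index: dict[str, set[str]] = {}
        for entry in self.entries.values():
            for term in entry.terms:
                norm = normalize_term(term)
                if not norm or norm in self.stoplist:
                    continue
                index.setdefault(norm, set()).add(entry.entity_id)
        return {t: tuple(sorted(ids)) for t, ids in sorted(index.items())}

    def iter_terms(self) -> Iterable[tuple[str, str]]:
        """Yield (entity_id, original-case term) pairs in deterministic order."""
        for entity_id in sorted(self.entries):
            for term in sorted(self.entries[entity_id].terms):
                yield entity_id, term


@dataclass(frozen=True)
class OverlapRecord:
    term: str  # normalized form
    id1: str
    id2: str
    overlap_type: str  # "within" | "cross"


def load_lexicon(path, entity_type: str) -> Lexicon:
    """Load a lexicon from a TSV with header ``entity_id<TAB>term``.

    One synonym per row; rows are grouped by id.  Terms are
    whitespace-normalized with original case preserved.  Duplicate
    (id, term) rows are deduplicated with a warning; an empty term is a
    format error; an empty file yields an empty lexicon.
    """
    terms_by_id: dict[str, set[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return Lexicon(entity_type=entity_type)
        if header[:2] != ["entity_id", "term"]:
            raise LexiconFormatError(
                f"{path}: expected header 'entity_id<TAB>term', got {header!r}"
            )
        n_dupes = 0
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise LexiconFormatError(f"{path}:{lineno}: expected 2 columns")
            entity_id, term = row[0].strip(), _clean_term(row[1])
            if not entity_id:
                raise LexiconFormatError(f"{path}:{lineno}: empty entity_id")
            if not term:
                raise LexiconFormatError(f"{path}:{lineno}: empty term")
            bucket = terms_by_id.setdefault(entity_id, set())
            if term in bucket:
                n_dupes += 1
            bucket.add(term)
        if n_dupes:
            logger.warning("%s: %d duplicate (id, term) rows deduplicated", path, n_dupes)
    entries = {
        eid: LexiconEntry(eid, entity_type, frozenset(terms))
        for eid, terms in sorted(terms_by_id.items())
    }
    return Lexicon(entity_type=entity_type, entries=entries)


def save_lexicon(lex: Lexicon, path) -> None:
    """Write a lexicon back to its TSV form (deterministic row order)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["entity_id", "term"])
        for entity_id, term in lex.iter_terms():
            writer.writerow([entity_id, term])


def apply_stoplist(lex: Lexicon, stop: Iterable[str]) -> Lexicon:
    """Remove every term whose lowercased form is in ``stop``.

    Entries left with zero terms are dropped (and counted in the log).
    The stop set is also recorded on the returned lexicon so the annotator
    never matches those strings.  Idempotent.
    """
    stop_set = frozenset(s.lower() for s in stop)
    entries: dict[str, LexiconEntry] = {}
    n_dropped = 0
    for eid, entry in lex.entries.items():
        kept = frozenset(t for t in entry.terms if t.lower() not in stop_set)
        if kept:
            entries[eid] = LexiconEntry(eid, entry.entity_type, kept)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info(
            "stoplist dropped %d %s entries left with no terms", n_dropped, lex.entity_type
        )
    return Lexicon(
        entity_type=lex.entity_type,
        entries=entries,
        stoplist=lex.stoplist | frozenset(normalize_term(s) for s in stop_set),
    )


def find_overlaps(lexicons: Sequence[Lexicon]) -> list[OverlapRecord]:
    """Detect ids sharing a case-insensitively identical normalized term.

    Returns one record per unordered id pair per shared term;
    ``overlap_type`` is ``"within"`` when both ids come from the same entity
    type and ``"cross"`` otherwise.  Symmetric in lexicon order.
    """
    if not lexicons:
        raise ValueError("find_overlaps requires at least one lexicon")
    carriers: dict[str, set[tuple[str, str]]] = {}  # norm term -> {(id, type)}
    for lex in lexicons:
        for entry in lex.entries.values():
            for term in entry.terms:
                norm = normalize_term(term)
                if norm:
                    carriers.setdefault(norm, set()).add((entry.entity_id, lex.entity_type))
    records: list[OverlapRecord] = []
    for norm in sorted(carriers):
        ids = sorted(carriers[norm])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                (id1, t1), (id2, t2) = ids[i], ids[j]
                if id1 == id2:
                    continue
                records.append(
                    OverlapRecord(norm, id1, id2, "within" if t1 == t2 else "cross")
                )
    return records


def save_overlap_report(records: Sequence[OverlapRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term", "id1", "id2", "overlap_type"])
        for rec in records:
            writer.writerow([rec.term, rec.id1, rec.id2, rec.overlap_type])
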