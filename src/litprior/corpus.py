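"""Corpus ingestion, rare-disease filtering and co-occurrence counting.

Documents arrive as JSONL (one object per line: ``doc_id``, ``title``,
``abstract``, optional ``year``).  Only documents mentioning at least one
rare-disease term are retained, mirroring the restriction of a full
literature corpus to its rare-disease-relevant subset; the survivors define
the sample space over which occurrence probabilities are estimated.

Counting treats entity occurrence as a Bernoulli event per counting unit
(a whole abstract, or a single sentence): mention multiplicity within a
unit is ignored, and every unordered pair of distinct entities present in
a unit is counted once for that unit.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .annotator import AnnotatedDocument, annotate_document
from .lexicon import Lexicon

logger = logging.getLogger(__name__)

LEVELS = ("abstract", "sentence")


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract: str
    year: int | None = None

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}" if self.abstract else self.title


@dataclass
class CooccurrenceCounts:
    """Document (or sentence) counts of entity occurrence and co-occurrence.

    ``entity_count[a] / n_units`` estimates P(a); ``pair_count[(a, b)] /
    n_units`` estimates the joint P(a, b).  Pair keys are stored in sorted
    (canonical) order.
    """

    n_units: int
    entity_count: dict[str, int]
    pair_count: dict[tuple[str, str], int]
    entity_type: dict[str, str]
    level: str = "abstract"

    def p(self, entity_id: str) -> float:
        return self.entity_count.get(entity_id, 0) / self.n_units

    def p_joint(self, a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        return self.pair_count.get(key, 0) / self.n_units


def read_corpus(path) -> Iterator[Document]:
    """Stream documents from a JSONL file in file order.

    Malformed lines (bad JSON, missing doc_id/title/abstract) are logged
    and skipped rather than aborting the run.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                doc = Document(
                    doc_id=str(obj["doc_id"]),
                    title=str(obj["title"]),
                    abstract=str(obj["abstract"]),
                    year=int(obj["year"]) if obj.get("year") is not None else None,
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                logger.warning("%s:%d: skipping malformed line (%s)", path, lineno, exc)
                continue
            yield doc


def write_corpus(docs: Iterable[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {"doc_id": doc.doc_id, "title": doc.title, "abstract": doc.abstract}
            if doc.year is not None:
                rec["year"] = doc.year
            fh.write(json.dumps(rec) + "\n")


def filter_rare_disease(
    docs: Iterable[Document], disease_lexicon: Lexicon
) -> Iterator[Document]:
    """Keep only documents whose title+abstract mentions ≥1 disease term."""
    if disease_lexicon.entity_type != "disease":
        raise ValueError("filter requires a disease-typed lexicon")
    for doc in docs:
        ann = annotate_document(doc.doc_id, doc.title, doc.abstract, [disease_lexicon])
        if ann.annotations:
            yield doc


def count_cooccurrence(
    annotated_docs: Iterable[AnnotatedDocument], level: str = "abstract"
) -> CooccurrenceCounts:
    """Accumulate per-unit occurrence and co-occurrence counts.

    A unit is the whole document (``level="abstract"``) or one sentence
    span (``level="sentence"``).  An entity counts at most once per unit;
    all C(k, 2) unordered pairs of the k distinct entities in a unit are
    counted once; self-pairs are excluded.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    n_units = 0
    entity_count: dict[str, int] = {}
    pair_count: dict[tuple[str, str], int] = {}
    entity_type: dict[str, str] = {}
    for doc in annotated_docs:
        for ann in doc.annotations:
            entity_type[ann.entity_id] = ann.entity_type
        if level == "abstract":
            units: list[set[str]] = [{a.entity_id for a in doc.annotations}]
        else:
            units = []
            for s, e in doc.sentence_bounds:
                units.append({a.entity_id for a in doc.annotations if s <= a.start < e})
        n_units += len(units)
        for unit in units:
            for eid in unit:
                entity_count[eid] = entity_count.get(eid, 0) + 1
            for a, b in itertools.combinations(sorted(unit), 2):
                pair_count[(a, b)] = pair_count.get((a, b), 0) + 1
    return CooccurrenceCounts(
        n_units=n_units,
        entity_count=dict(sorted(entity_count.items())),
        pair_count=dict(sorted(pair_count.items())),
        entity_type=dict(sorted(entity_type.items())),
        level=level,
    )


def save_counts(counts: CooccurrenceCounts, pair_path, entity_path) -> None:
    """TSV export: pair counts plus an entity-count sidecar; each file's
    header line carries n_units and the counting level."""
    header_meta = f"# n_units={counts.n_units}\tlevel={counts.level}\n"
    with open(pair_path, "w", encoding="utf-8") as fh:
        fh.write(header_meta)
        fh.write("id_a\tid_b\tpair_count\n")
        for (a, b), c in counts.pair_count.items():
            fh.write(f"{a}\t{b}\t{c}\n")
    with open(entity_path, "w", encoding="utf-8") as fh:
        fh.write(header_meta)
        fh.write("id\tentity_count\tentity_type\n")
        for eid, c in counts.entity_count.items():
            fh.write(f"{eid}\t{c}\t{counts.entity_type.get(eid, '?')}\n")


def annotate_corpus(
    docs: Iterable[Document], lexicons: Sequence[Lexicon]
) -> Iterator[AnnotatedDocument]:
    """Convenience: run the annotator over a document stream."""
    for doc in docs:
        yield annotate_document(doc.doc_id, doc.title, doc.abstract, lexicons, year=doc.year)
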