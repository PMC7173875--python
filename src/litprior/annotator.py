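"""Dictionary NER over abstracts and precedence-based conflict resolution.

Matching is exact at the token level: text and terms are tokenized into
alphanumeric runs, compared case-insensitively, and for each entity type
independently the leftmost-longest match wins.  No stemming or plural
handling is applied — "seizures" does not match the term "seizure".

When annotations of *different* types overlap in character span, the
conflict resolver applies the fixed precedence rule

    phenotype  wins over  disease  wins over  gene

so e.g. a disease name embedded in a longer phenotype phrase is suppressed.
Within a type, the longer span wins (then leftmost, then smallest id);
multiple ids sharing one exact span are all retained — such within-type
ambiguity is deliberately preserved for downstream counting.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .lexicon import TYPE_PRECEDENCE, Lexicon, normalize_term

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

#: tokens (lowercased, incl. trailing period) that never end a sentence
_ABBREVIATIONS = frozenset(
    {"e.g.", "i.e.", "cf.", "vs.", "al.", "fig.", "figs.", "dr.", "no.", "ca.", "approx."}
)
_INITIAL_RE = re.compile(r"^[A-Z]\.$")  # capitalized initialisms like "E."

#: genes whose surface form is this short must match case exactly
SHORT_GENE_TERM_LEN = 3


@dataclass(frozen=True, order=True)
class Annotation:
    """One entity mention: a character span plus the entity it names.

    Offsets are 0-based half-open into the document text
    (``title + " " + abstract``).
    """

    doc_id: str
    start: int
    end: int
    entity_type: str
    entity_id: str
    matched_text: str

    def overlaps(self, other: "Annotation") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    annotations: list[Annotation]
    sentence_bounds: list[tuple[int, int]]
    year: int | None = None


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans (start, end), partitioning its
    non-whitespace characters.

    A sentence ends at ``.``, ``!`` or ``?`` followed by whitespace and an
    uppercase letter, unless the terminating token is a known abbreviation
    or a single-letter initialism ("E. coli" stays intact).  Text with no
    terminator is one span.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    i = 0
    while i < n and text[i].isspace():
        i += 1
    start = i
    while i < n:
        ch = text[i]
        if ch in ".!?" and i + 1 < n and text[i + 1].isspace():
            j = i + 1
            while j < n and text[j].isspace():
                j += 1
            if j < n and text[j].isupper():
                # token ending here, e.g. "vs." or "E."
                tok_start = i
                while tok_start > 0 and not text[tok_start - 1].isspace():
                    tok_start -= 1
                token = text[tok_start : i + 1].lower()
                if token not in _ABBREVIATIONS and not _INITIAL_RE.match(token):
                    spans.append((start, i + 1))
                    start = j
                    i = j
                    continue
        i += 1
    # trailing sentence (trim trailing whitespace)
    end = n
    while end > start and text[end - 1].isspace():
        end -= 1
    if end > start:
        spans.append((start, end))
    return spans


def _build_index(lex: Lexicon) -> dict[tuple[str, ...], list[tuple[str, str]]]:
    """Normalized token tuple -> [(entity_id, original term), ...]."""
    index: dict[tuple[str, ...], list[tuple[str, str]]] = {}
    for entry in lex.entries.values():
        for term in entry.terms:
            norm = normalize_term(term)
            if not norm or norm in lex.stoplist:
                continue
            toks = tuple(_TOKEN_RE.findall(norm))
            if toks:
                index.setdefault(toks, []).append((entry.entity_id, term))
    for bucket in index.values():
        bucket.sort()
    return index


def annotate(text: str, lexicons: Sequence[Lexicon]) -> list[Annotation]:
    """Find all dictionary term mentions in ``text``.

    Case-insensitive on token boundaries; per entity type, leftmost-longest
    non-overlapping matches are reported.  Gene terms of length ≤
    ``SHORT_GENE_TERM_LEN`` additionally require an exact-case match, which
    suppresses most short-acronym noise.  A term shared by k ids of one
    type yields k annotations at the same span.
    """
    if not text:
        return []
    tokens = [(m.start(), m.end(), m.group().lower()) for m in _TOKEN_RE.finditer(text)]
    out: list[Annotation] = []
    for lex in lexicons:
        index = _build_index(lex)
        if not index:
            continue
        max_len = max(len(k) for k in index)
        i = 0
        while i < len(tokens):
            matched = False
            for k in range(min(max_len, len(tokens) - i), 0, -1):
                key = tuple(tok for _, _, tok in tokens[i : i + k])
                bucket = index.get(key)
                if bucket is None:
                    continue
                span_start, span_end = tokens[i][0], tokens[i + k - 1][1]
                mention = text[span_start:span_end]
                ids: set[str] = set()
                for entity_id, term in bucket:
                    if (
                        lex.entity_type == "gene"
                        and len(term) <= SHORT_GENE_TERM_LEN
                        and mention != term
                    ):
                        continue
                    ids.add(entity_id)
                if ids:
                    for entity_id in sorted(ids):
                        out.append(
                            Annotation("", span_start, span_end, lex.entity_type, entity_id, mention)
                        )
                    i += k
                    matched = True
                    break
            if not matched:
                i += 1
    out.sort(key=lambda a: (a.start, a.end, TYPE_PRECEDENCE[a.entity_type], a.entity_id))
    return out


def _resolve_within_type(annotations: list[Annotation]) -> list[Annotation]:
    """Longest span wins, then leftmost, then smallest id; exact-span
    ambiguity (several ids at one span) is retained in full."""
    by_span: dict[tuple[int, int], list[Annotation]] = {}
    for ann in annotations:
        by_span.setdefault((ann.start, ann.end), []).append(ann)
    ordered = sorted(
        by_span,
        key=lambda s: (-(s[1] - s[0]), s[0], min(a.entity_id for a in by_span[s])),
    )
    kept_spans: list[tuple[int, int]] = []
    out: list[Annotation] = []
    for span in ordered:
        if any(span[0] < e and s < span[1] for s, e in kept_spans):
            continue
        kept_spans.append(span)
        out.extend(sorted(by_span[span], key=lambda a: a.entity_id))
    return out


def resolve_conflicts(annotations: Sequence[Annotation]) -> list[Annotation]:
    """Arbitrate overlapping annotations from one document.

    Same-type overlaps are resolved first (longest/leftmost/smallest-id);
    then cross-type overlaps by precedence: a surviving phenotype suppresses
    any overlapping disease or gene, and a surviving disease suppresses any
    overlapping gene.  The output is span-sorted and non-overlapping except
    for exact-span same-type ambiguity.
    """
    by_type: dict[str, list[Annotation]] = {"phenotype": [], "disease": [], "gene": []}
    for ann in annotations:
        by_type[ann.entity_type].append(ann)
    survivors: dict[str, list[Annotation]] = {
        t: _resolve_within_type(anns) for t, anns in by_type.items()
    }
    kept: list[Annotation] = list(survivors["phenotype"])
    for etype in ("disease", "gene"):  # ascending precedence rank
        blockers = [a for a in kept]
        for ann in survivors[etype]:
            if not any(ann.overlaps(b) for b in blockers):
                kept.append(ann)
    kept.sort(key=lambda a: (a.start, a.end, TYPE_PRECEDENCE[a.entity_type], a.entity_id))
    return kept


def conflict_stats(
    before: Sequence[Annotation], after: Sequence[Annotation]
) -> dict[tuple[str, str], int]:
    """Count resolved cross-type conflicts, keyed by unordered type pair.

    A conflict is a span-overlapping pair of different-type annotations in
    ``before`` whose lower-precedence member was removed while the
    higher-precedence member survived.
    """
    after_set = set(after)
    counts: dict[tuple[str, str], int] = {
        ("disease", "phenotype"): 0,
        ("gene", "phenotype"): 0,
        ("disease", "gene"): 0,
    }
    before = list(before)
    for i, a in enumerate(before):
        for b in before[i + 1 :]:
            if a.entity_type == b.entity_type or not a.overlaps(b):
                continue
            hi, lo = sorted((a, b), key=lambda x: TYPE_PRECEDENCE[x.entity_type])
            if hi in after_set and lo not in after_set:
                key = tuple(sorted((a.entity_type, b.entity_type)))
                counts[key] += 1  # type: ignore[index]
    return counts


def annotate_document(
    doc_id: str,
    title: str,
    abstract: str,
    lexicons: Sequence[Lexicon],
    year: int | None = None,
) -> AnnotatedDocument:
    """Run NER + conflict resolution + sentence splitting on one document."""
    text = f"{title} {abstract}" if abstract else title
    raw = [
        Annotation(doc_id, a.start, a.end, a.entity_type, a.entity_id, a.matched_text)
        for a in annotate(text, lexicons)
    ]
    resolved = resolve_conflicts(raw)
    return AnnotatedDocument(
        doc_id=doc_id,
        text=text,
        annotations=resolved,
        sentence_bounds=split_sentences(text),
        year=year,
    )


def save_annotations(docs: Iterable[AnnotatedDocument], path) -> None:
    """TSV export: doc_id, start, end, entity_type, entity_id, matched_text."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "start", "end", "entity_type", "entity_id", "matched_text"])
        for doc in docs:
            for a in doc.annotations:
                writer.writerow([doc.doc_id, a.start, a.end, a.entity_type, a.entity_id, a.matched_text])
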