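"""Phenotype-query gene ranking against the association network.

The query is the list of phenotype ids describing a clinical case.  Each
gene node is scored by the sum of its edge weights to the query phenotypes
(absent edges contribute zero); indirect phenotype→disease→gene evidence
enters through the inferred phenotype–gene edges of the ASN rather than
through explicit path search.  Genes with zero score are not ranked.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .network import AssociationNetwork

NOT_FOUND = -1  # sentinel rank for a gene absent from a ranking


@dataclass(frozen=True)
class PhenotypeQuery:
    case_id: str
    phenotype_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phenotype_ids:
            raise ValueError("query must contain at least one phenotype id")
        deduped = tuple(dict.fromkeys(self.phenotype_ids))
        object.__setattr__(self, "phenotype_ids", deduped)


@dataclass
class RankedGeneList:
    query: PhenotypeQuery
    records: list[tuple[int, str, float]] = field(default_factory=list)  # (rank, gene, score)
    n_query_terms_matched: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def gene_ids(self) -> list[str]:
        return [g for _, g, _ in self.records]


def prioritize(net: AssociationNetwork, query: PhenotypeQuery) -> RankedGeneList:
    """Rank genes by summed association strength to the query phenotypes.

    Descending score; ties broken by ascending gene id.  Query ids absent
    from the network contribute nothing; ``n_query_terms_matched`` reports
    how many were present.  An entirely unmatched query yields an empty
    list, not an error.
    """
    matched = [p for p in query.phenotype_ids if p in net.nodes]
    scores: dict[str, float] = {}
    for p in matched:
        for nb in net.neighbors(p):
            if net.nodes.get(nb) == "gene":
                scores[nb] = scores.get(nb, 0.0) + net.weight(p, nb)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    records = [(rank, gene, score) for rank, (gene, score) in enumerate(ordered, start=1)]
    return RankedGeneList(query=query, records=records, n_query_terms_matched=len(matched))


def rank_of(ranked: RankedGeneList, gene_id: str) -> int:
    """1-based rank of ``gene_id``, or the NOT_FOUND sentinel."""
    for rank, gene, _score in ranked.records:
        if gene == gene_id:
            return rank
    return NOT_FOUND


def read_queries(path) -> list[PhenotypeQuery]:
    """Batch query TSV: ``case_id<TAB>comma-separated phenotype ids``."""
    queries: list[PhenotypeQuery] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("case_id\t"):
                continue
            case_id, pheno_csv = line.split("\t")[:2]
            queries.append(PhenotypeQuery(case_id, tuple(p for p in pheno_csv.split(",") if p)))
    return queries


def save_rankings(rankings: Iterable[RankedGeneList], path, top: int | None = None) -> None:
    """Output TSV: case_id, rank, gene_id, score."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["case_id", "rank", "gene_id", "score"])
        for ranked in rankings:
            records = ranked.records if top is None else ranked.records[:top]
            for rank, gene, score in records:
                writer.writerow([ranked.query.case_id, rank, gene, f"{score:.12g}"])
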