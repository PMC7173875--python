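"""Evaluation protocols: truncated ROC AUC (AUC_N) and Top-k recall.

AUC_N restricts the ROC comparison to all true-labeled candidates and only
the first N false-labeled candidates of a ranking; it is the probability
that a random true candidate outranks a random false candidate from that
head, so AUC_N <= AUC_overall for every N.  Ties count 1/2 (the standard
Mann-Whitney convention).

Top-k recall summarizes case-level prioritization: the percentage of
clinical cases whose causal gene lands within the first k ranked genes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .network import AssociationNetwork
from .prioritizer import NOT_FOUND


class NonEvaluableError(ValueError):
    """Ranking has no true or no false candidates: AUC is undefined."""


@dataclass
class DiseaseAuc:
    disease_id: str
    auc_overall: float
    auc_n: dict[int, float]
    n_true: int
    n_false: int


@dataclass
class AucResult:
    per_disease: list[DiseaseAuc] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def mean_auc_overall(self) -> float:
        if not self.per_disease:
            raise NonEvaluableError("no evaluable diseases")
        return sum(d.auc_overall for d in self.per_disease) / len(self.per_disease)

    def mean_auc_n(self, n: int) -> float:
        if not self.per_disease:
            raise NonEvaluableError("no evaluable diseases")
        return sum(d.auc_n[n] for d in self.per_disease) / len(self.per_disease)


@dataclass
class TopkCurve:
    ks: list[int]
    percent: list[float]
    total_cases: int
    never_found: int


def auc_n(
    ordering: Sequence[tuple[str, float]],
    true_set: set[str],
    N: int | None = None,
) -> float:
    """AUC over all true candidates vs the first N false candidates.

    ``ordering`` is the ranked candidate list as (id, score) pairs, best
    first.  N=None uses every false candidate (the overall AUC).  Ties in
    score count 0.5.  Raises :class:`NonEvaluableError` when either class
    is empty.
    """
    if not ordering:
        raise NonEvaluableError("empty ordering")
    true_scores = [s for g, s in ordering if g in true_set]
    false_scores = [s for g, s in ordering if g not in true_set]
    if not true_scores or not false_scores:
        raise NonEvaluableError("need at least one true and one false candidate")
    if N is not None:
        if N < 1:
            raise ValueError("N must be >= 1")
        false_scores = false_scores[:N]
    wins = 0.0
    for t in true_scores:
        for f in false_scores:
            if t > f:
                wins += 1.0
            elif t == f:
                wins += 0.5
    return wins / (len(true_scores) * len(false_scores))


def evaluate_network(
    net: AssociationNetwork,
    gold: Mapping[str, set[str]],
    Ns: Sequence[int] = (50,),
) -> AucResult:
    """Score a network's disease–gene neighborhoods against a gold table.

    For each gold disease present in the network, the candidate set is its
    gene-typed direct neighbors ordered by edge weight (descending, ties
    by gene id); true candidates are the gold genes found among them.
    Diseases absent from the network, or with no true or no false
    neighbor, are skipped; aggregates are unweighted means over the rest.
    """
    result = AucResult()
    for disease_id in sorted(gold):
        true_genes = gold[disease_id]
        if disease_id not in net.nodes:
            result.n_skipped += 1
            continue
        candidates = [
            (g, net.weight(disease_id, g))
            for g in net.neighbors(disease_id)
            if net.nodes.get(g) == "gene"
        ]
        candidates.sort(key=lambda kv: (-kv[1], kv[0]))
        try:
            overall = auc_n(candidates, true_genes, None)
        except NonEvaluableError:
            result.n_skipped += 1
            continue
        per_n = {n: auc_n(candidates, true_genes, n) for n in Ns}
        n_true = sum(1 for g, _ in candidates if g in true_genes)
        result.per_disease.append(
            DiseaseAuc(disease_id, overall, per_n, n_true, len(candidates) - n_true)
        )
    return result


def topk_recall(
    case_ranks: Sequence[tuple[str, int]], ks: Sequence[int]
) -> TopkCurve:
    """Cumulative percentage of cases whose causal-gene rank is <= k.

    ``case_ranks`` holds one (case_id, rank) record per case, with the
    NOT_FOUND sentinel for cases whose gene never appears; a case with
    several causal genes should report its best (minimum) rank.
    """
    if not case_ranks:
        raise ValueError("case_ranks must be non-empty")
    total = len(case_ranks)
    found = [r for _cid, r in case_ranks if r != NOT_FOUND]
    percent = [100.0 * sum(1 for r in found if r <= k) / total for k in ks]
    return TopkCurve(
        ks=list(ks), percent=percent, total_cases=total, never_found=total - len(found)
    )


def load_gold(path) -> dict[str, set[str]]:
    """Gold TSV: ``disease_id<TAB>gene_id``, one association per row."""
    gold: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("disease_id\t"):
                continue
            disease_id, gene_id = line.split("\t")[:2]
            gold.setdefault(disease_id, set()).add(gene_id)
    return gold


def save_topk(curve: TopkCurve, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["k", "percent"])
        for k, p in zip(curve.ks, curve.percent):
            writer.writerow([k, f"{p:.6g}"])
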