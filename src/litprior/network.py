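"""Pairwise phi correlations and the Initial Correlation Network (ICN).

For two entities a and b, per-unit occurrence is a pair of binary
indicator variables; their Pearson correlation is the phi coefficient

    rho_ab = (P(a,b) - P(a) P(b)) / sqrt(P(a)(1-P(a)) P(b)(1-P(b)))

with the marginals P(a), P(b) and joint P(a,b) estimated as document (or
sentence) fractions.  The ICN keeps one undirected edge per positively
correlated pair — negative and zero correlations are excluded — weighted
by rho.  Inferred (graph-convolution) edges are added later to form the
Association Network (ASN); both network flavours share this container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .corpus import CooccurrenceCounts

PROVENANCES = ("direct", "inferred")


class DegenerateMarginalError(ValueError):
    """Correlation is undefined when a marginal probability is 0 or 1."""


class EmptyCorpusError(ValueError):
    pass


def pearson(p_a: float, p_b: float, p_ab: float) -> float:
    """Phi coefficient of two binary per-unit indicator variables.

    Requires 0 < p_a < 1 and 0 < p_b < 1 (otherwise the variance of an
    indicator vanishes and the correlation is undefined) and a feasible
    joint probability max(0, p_a + p_b - 1) <= p_ab <= min(p_a, p_b).
    """
    if not (0.0 < p_a < 1.0) or not (0.0 < p_b < 1.0):
        raise DegenerateMarginalError(
            f"marginals must lie strictly in (0,1); got p_a={p_a}, p_b={p_b}"
        )
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if not (lo - 1e-12 <= p_ab <= hi + 1e-12):
        raise ValueError(f"infeasible joint probability p_ab={p_ab} for ({p_a}, {p_b})")
    if p_a > p_b:  # fix evaluation order so the result is exactly symmetric
        p_a, p_b = p_b, p_a
    return (p_ab - p_a * p_b) / math.sqrt(p_a * (1.0 - p_a) * p_b * (1.0 - p_b))


def _canon(u: str, v: str) -> tuple[str, str]:
    if u == v:
        raise ValueError(f"self-loop edge ({u!r}, {v!r})")
    return (u, v) if u < v else (v, u)


@dataclass
class AssociationNetwork:
    """Undirected weighted typed graph with per-edge provenance.

    ``edges`` maps a canonical (sorted) id pair to ``(weight, provenance)``;
    weights are strictly positive; direct edges carry the phi correlation,
    inferred edges the graph-convolution score.
    """

    nodes: dict[str, str] = field(default_factory=dict)  # entity_id -> entity_type
    edges: dict[tuple[str, str], tuple[float, str]] = field(default_factory=dict)
    level: str = "abstract"

    def add_edge(self, u: str, v: str, weight: float, provenance: str = "direct") -> None:
        if weight <= 0:
            raise ValueError(f"edge weight must be positive, got {weight}")
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        self.edges[_canon(u, v)] = (weight, provenance)

    def has_edge(self, u: str, v: str) -> bool:
        return _canon(u, v) in self.edges

    def weight(self, u: str, v: str) -> float:
        """Edge weight, 0.0 when the pair is not connected."""
        entry = self.edges.get(_canon(u, v))
        return entry[0] if entry else 0.0

    def neighbors(self, u: str) -> list[str]:
        out = [b if a == u else a for (a, b) in self.edges if u in (a, b)]
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_icn(counts: CooccurrenceCounts, min_support: int = 1) -> AssociationNetwork:
    """Build the Initial Correlation Network from co-occurrence counts.

    One candidate edge per counted pair with ``pair_count >= min_support``;
    pairs with rho <= 0 are discarded (strict positivity), as are pairs
    with a degenerate marginal (an entity present in every unit or none).
    The node set is the endpoints of the surviving edges.
    """
    if counts.n_units == 0:
        raise EmptyCorpusError("cannot build a network from an empty corpus")
    net = AssociationNetwork(level=counts.level)
    for (a, b), support in counts.pair_count.items():
        if support < min_support:
            continue
        try:
            rho = pearson(counts.p(a), counts.p(b), counts.p_joint(a, b))
        except DegenerateMarginalError:
            continue
        if rho <= 0:
            continue
        for eid in (a, b):
            net.nodes[eid] = counts.entity_type.get(eid, "?")
        net.add_edge(a, b, rho, "direct")
    net.nodes = dict(sorted(net.nodes.items()))
    net.edges = dict(sorted(net.edges.items()))
    return net


def edge_type_summary(net: AssociationNetwork) -> dict[tuple[str, str], int]:
    """Edge counts keyed by unordered (entity_type, entity_type) pair."""
    summary: dict[tuple[str, str], int] = {}
    for a, b in net.edges:
        key = tuple(sorted((net.nodes[a], net.nodes[b])))
        summary[key] = summary.get(key, 0) + 1  # type: ignore[index]
    return dict(sorted(summary.items()))


def save_network(net: AssociationNetwork, edges_path, nodes_path) -> None:
    """Edge-list + node-table TSVs, weights at 12 significant digits."""
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write(f"# level={net.level}\n")
        fh.write("id_a\tid_b\tweight\tprovenance\n")
        for (a, b), (w, prov) in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.12g}\t{prov}\n")
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tentity_type\n")
        for eid, etype in sorted(net.nodes.items()):
            fh.write(f"{eid}\t{etype}\n")


def load_network(edges_path, nodes_path) -> AssociationNetwork:
    net = AssociationNetwork()
    with open(nodes_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["entity_id", "entity_type"]:
            raise ValueError(f"{nodes_path}: bad node table header {header!r}")
        for line in fh:
            eid, etype = line.rstrip("\n").split("\t")
            net.nodes[eid] = etype
    with open(edges_path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# "):
            meta = dict(kv.split("=", 1) for kv in first[2:].strip().split("\t"))
            net.level = meta.get("level", "abstract")
            first = fh.readline()
        if first.rstrip("\n").split("\t") != ["id_a", "id_b", "weight", "provenance"]:
            raise ValueError(f"{edges_path}: bad edge list header")
        for line in fh:
            a, b, w, prov = line.rstrip("\n").split("\t")
            net.add_edge(a, b, float(w), prov)
    return net
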