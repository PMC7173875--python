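import pytest

from litprior.lexicon import Lexicon, LexiconEntry
from litprior.network import AssociationNetwork


def make_lexicon(entity_type, mapping, stoplist=()):
    """mapping: entity_id -> iterable of terms."""
    entries = {
        eid: LexiconEntry(eid, entity_type, frozenset(terms))
        for eid, terms in mapping.items()
    }
    return Lexicon(entity_type, entries, frozenset(stoplist))


def make_net(edges, types=None, provenance="direct"):
    """edges: {(u, v): weight}; types: entity_id -> type (default gene)."""
    net = AssociationNetwork()
    types = types or {}
    for (u, v), w in edges.items():
        for n in (u, v):
            net.nodes.setdefault(n, types.get(n, "gene"))
        net.add_edge(u, v, w, provenance)
    net.nodes = dict(sorted(net.nodes.items()))
    return net


@pytest.fixture
def phenotype_lexicon():
    return make_lexicon(
        "phenotype",
        {
            "HP:0001250": ["seizure"],
            "HP:0000176": ["submucosal cleft palate"],
            "HP:0200043": ["Warts"],
        },
    )


@pytest.fixture
def disease_lexicon():
    return make_lexicon(
        "disease",
        {
            "ORPHA:155878": ["submucosal cleft palate"],
            "ORPHA:778": ["Rett syndrome"],
        },
    )


@pytest.fixture
def gene_lexicon():
    return make_lexicon(
        "gene",
        {
            "HGNC:6514": ["Warts", "WTS"],
            "HGNC:7421": ["cox2", "COX2LONG"],
            "HGNC:9605": ["cox2"],
            "HGNC:11634": ["MECP2"],
        },
    )
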