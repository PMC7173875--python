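"""Seeded synthetic corpora with planted disease–gene–phenotype structure.

The generator emulates the statistical skeleton the pipeline relies on: a
document that is "about" a disease always names the disease and, with high
probability, its causal gene(s) and characteristic phenotypes, so those
pairs co-occur far above chance; every other entity appears in any
document at a small background rate, so decoy pairs correlate only by
sampling noise.  Documents are bags of surface terms joined into
sentence-like chunks — enough structure to exercise the sentence splitter
and the token-boundary NER, while the planted co-occurrence counts are
independent of the exact phrasing by construction.

Everything is driven by one integer seed: identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus import Document, write_corpus
from .lexicon import Lexicon, LexiconEntry, save_lexicon

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults are the package's standard recovery setting: 500 abstracts
    over 10 diseases, each with one causal gene and five characteristic
    phenotypes, mentioned in topic documents with probability 0.8 against
    a 0.05 background rate.
    """

    seed: int = 0
    n_diseases: int = 10
    genes_per_disease: int = 1
    phenotypes_per_disease: int = 5
    n_docs: int = 500
    p_topic_doc: float = 0.6
    p_mention_gene: float = 0.8
    p_mention_phenotype: float = 0.8
    p_background: float = 0.05
    vocab_noise_terms: int = 30

    def __post_init__(self) -> None:
        for name in ("p_topic_doc", "p_mention_gene", "p_mention_phenotype", "p_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_diseases", "genes_per_disease", "phenotypes_per_disease", "n_docs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    """Planted associations: which gene(s) and phenotypes belong to each
    disease.  Every referenced id exists in the generated lexicons."""

    disease_genes: dict[str, list[str]]
    disease_phenotypes: dict[str, list[str]]


@dataclass(frozen=True)
class Case:
    """One synthetic clinical case: observed phenotypes plus the causal
    gene(s) the prioritizer should recover."""

    case_id: str
    disease_id: str
    phenotype_ids: tuple[str, ...]
    causal_genes: tuple[str, ...]


@dataclass
class SimOutput:
    config: SimConfig
    documents: list[Document]
    lexicons: dict[str, Lexicon]
    truth: GroundTruth


class _WordFactory:
    """Unique pronounceable pseudowords (>= 6 letters, lowercase)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, n_syllables: int = 3) -> str:
        while True:
            idx = self.rng.integers(0, len(_SYLLABLES), size=n_syllables)
            w = "".join(_SYLLABLES[i] for i in idx)
            if w not in self.used:
                self.used.add(w)
                return w


def _make_entry(eid: str, etype: str, terms: list[str]) -> LexiconEntry:
    return LexiconEntry(eid, etype, frozenset(terms))


def generate(config: SimConfig) -> SimOutput:
    """Generate a corpus, the three lexicons, and the planted truth.

    Each document is a topic document with probability ``p_topic_doc`` (its
    disease drawn uniformly): it always names its disease, names each
    causal gene / characteristic phenotype with the mention probabilities,
    and every unrelated entity at the background rate.  Non-topic
    documents contain only background mentions plus filler — most carry no
    disease term and are removed by the rare-disease filter downstream.
    """
    if config.n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    rng = np.random.default_rng(config.seed)
    words = _WordFactory(rng)

    diseases, genes, phenotypes = {}, {}, {}
    disease_genes: dict[str, list[str]] = {}
    disease_phenotypes: dict[str, list[str]] = {}
    g_serial = p_serial = 0
    for d in range(config.n_diseases):
        did = f"ORPHA:{9000 + d}"
        diseases[did] = _make_entry(
            did, "disease", [f"{words.word()} syndrome", f"{words.word()} disease"]
        )
        disease_genes[did] = []
        disease_phenotypes[did] = []
        for _ in range(config.genes_per_disease):
            gid = f"HGNC:{5000 + g_serial}"
            g_serial += 1
            sym = words.word().upper() + str(g_serial)
            genes[gid] = _make_entry(gid, "gene", [sym, words.word()])
            disease_genes[did].append(gid)
        for _ in range(config.phenotypes_per_disease):
            pid = f"HP:{7000000 + p_serial:07d}"
            p_serial += 1
            phenotypes[pid] = _make_entry(pid, "phenotype", [words.word(), words.word()])
            disease_phenotypes[did].append(pid)

    lexicons = {
        "disease": Lexicon("disease", diseases),
        "gene": Lexicon("gene", genes),
        "phenotype": Lexicon("phenotype", phenotypes),
    }
    noise_vocab = [words.word() for _ in range(config.vocab_noise_terms)]
    primary_term = {
        eid: min(e.terms) for lex in lexicons.values() for eid, e in lex.entries.items()
    }
    all_ids = sorted(primary_term)
    disease_ids = sorted(diseases)

    documents: list[Document] = []
    for i in range(config.n_docs):
        topic: str | None = None
        if rng.random() < config.p_topic_doc:
            topic = disease_ids[int(rng.integers(0, len(disease_ids)))]
        mentioned: list[str] = []
        planted: set[str] = set()
        if topic is not None:
            planted = {topic, *disease_genes[topic], *disease_phenotypes[topic]}
            mentioned.append(topic)
            for gid in disease_genes[topic]:
                if rng.random() < config.p_mention_gene:
                    mentioned.append(gid)
            for pid in disease_phenotypes[topic]:
                if rng.random() < config.p_mention_phenotype:
                    mentioned.append(pid)
        for eid in all_ids:
            if eid not in planted and rng.random() < config.p_background:
                mentioned.append(eid)
        items = [primary_term[eid] for eid in mentioned]
        n_filler = int(rng.integers(6, 13))
        items += [noise_vocab[int(rng.integers(0, len(noise_vocab)))] for _ in range(n_filler)]
        rng.shuffle(items)
        sentences: list[str] = []
        j = 0
        while j < len(items):
            k = int(rng.integers(2, 5))
            chunk = " ".join(items[j : j + k])
            sentences.append(chunk[0].upper() + chunk[1:] + ".")
            j += k
        title, abstract = sentences[0], " ".join(sentences[1:])
        year = int(rng.integers(1980, 2019))
        documents.append(Document(f"DOC:{i:06d}", title, abstract, year))

    return SimOutput(
        config=config,
        documents=documents,
        lexicons=lexicons,
        truth=GroundTruth(disease_genes, disease_phenotypes),
    )


def make_cases(
    truth: GroundTruth, n_cases: int, phenotypes_per_case: int, seed: int
) -> list[Case]:
    """Sample synthetic clinical cases from the planted truth.

    Each case draws a disease uniformly and observes a random subset of
    its characteristic phenotypes; the causal gene(s) are recorded for
    evaluation.
    """
    rng = np.random.default_rng(seed)
    disease_ids = sorted(truth.disease_genes)
    cases: list[Case] = []
    for c in range(n_cases):
        did = disease_ids[int(rng.integers(0, len(disease_ids)))]
        pool = truth.disease_phenotypes[did]
        if phenotypes_per_case > len(pool):
            raise ValueError("phenotypes_per_case exceeds phenotypes per disease")
        picked = rng.choice(len(pool), size=phenotypes_per_case, replace=False)
        cases.append(
            Case(
                case_id=f"CASE:{c:04d}",
                disease_id=did,
                phenotype_ids=tuple(pool[i] for i in sorted(picked)),
                causal_genes=tuple(truth.disease_genes[did]),
            )
        )
    return cases


def save_cases(cases, path) -> None:
    """Case TSV: case_id, comma-separated phenotype ids, causal gene(s)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("case_id\tphenotype_ids\tcausal_genes\n")
        for case in cases:
            fh.write(
                f"{case.case_id}\t{','.join(case.phenotype_ids)}\t{','.join(case.causal_genes)}\n"
            )


def load_cases(path) -> list[Case]:
    cases: list[Case] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("case_id\t"):
                continue
            cid, phenos, gs = line.split("\t")[:3]
            cases.append(Case(cid, "", tuple(phenos.split(",")), tuple(gs.split(","))))
    return cases


def save_gold(truth: GroundTruth, path) -> None:
    """Gold association TSV: disease_id, gene_id (one pair per row)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tgene_id\n")
        for did in sorted(truth.disease_genes):
            for gid in truth.disease_genes[did]:
                fh.write(f"{did}\t{gid}\n")


def write_outputs(sim: SimOutput, outdir, cases: list[Case] | None = None) -> None:
    """Materialize a simulation as plain-text files in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus(sim.documents, outdir / "corpus.jsonl")
    for etype, lex in sim.lexicons.items():
        save_lexicon(lex, outdir / f"{etype}s.tsv")
    save_gold(sim.truth, outdir / "gold.tsv")
    truth_json = {
        "disease_genes": sim.truth.disease_genes,
        "disease_phenotypes": sim.truth.disease_phenotypes,
        "config": asdict(sim.config),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True) + "\n")
    if cases is not None:
        save_cases(cases, outdir / "cases.tsv")
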