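# litprior

Phenotype-driven rare-disease gene prioritization from literature
co-occurrence networks.

Diagnosing a rare-disease patient typically starts from a handful of
clinical phenotypes (HPO terms) and asks: which gene is causal?  Curated
disease–gene resources lag the literature, so `litprior` builds its
association network directly from abstract text.  The pipeline:

1. **Dictionary NER** — disease (ORPHA), phenotype (HP) and gene (HGNC)
   lexicons are matched against titles+abstracts (case-insensitive,
   token-boundary, leftmost-longest per type). Overlapping annotations of
   different types are arbitrated by a fixed precedence rule:
   *phenotype wins over disease wins over gene*.
2. **Co-occurrence counting** — each abstract (or sentence) is a Bernoulli
   unit; an entity counts at most once per unit. For a pair (a, b) the
   phi coefficient (Pearson correlation of the two binary indicators) is

       ρ_ab = (P(a,b) − P(a)P(b)) / √(P(a)(1−P(a)) P(b)(1−P(b)))

   Positively correlated pairs form the **initial correlation network
   (ICN)**, an undirected graph weighted by ρ.
3. **Graph-convolution association scoring** — indirect associations are
   inferred by propagating unit signals with the symmetric
   degree-normalized operator Ñ = D^(−1/2)(W+I)D^(−1/2), accumulating
   S = Σ_{t=1..T} αᵗ Ñᵗ. Non-adjacent pairs with S ≥ τ gain inferred
   edges; the augmented graph is the **association network (ASN)**.
4. **Prioritization** — a phenotype query scores each gene by the sum of
   its (direct or inferred) edge weights to the query phenotypes; genes
   are returned in descending score order.
5. **Evaluation** — AUC_N (ROC AUC over all true gene neighbors of a
   disease and the first N false ones; AUC_N ≤ AUC_overall by
   construction) and cumulative Top-k recall over clinical cases.

A seeded synthetic-corpus generator (`litprior.simulate`) plants
disease–gene–phenotype associations into toy abstracts so the entire
pipeline is testable end-to-end without any download.

## Worked example

```python
import litprior as lp

sim = lp.generate(lp.SimConfig(seed=42))          # 500 synthetic abstracts
icn, asn = lp.build_networks(sim.documents, sim.lexicons)
print(f"ICN: {icn.n_nodes} nodes, {icn.n_edges} direct edges")
print(f"ASN: {asn.n_edges} edges ({asn.n_edges - icn.n_edges} inferred)")

case = lp.make_cases(sim.truth, 1, 3, seed=43)[0]
print("query phenotypes:", ", ".join(case.phenotype_ids))
print("causal gene:     ", case.causal_genes[0])
ranked = lp.prioritize(asn, lp.PhenotypeQuery(case.case_id, case.phenotype_ids))
for rank, gene, score in ranked.records[:3]:
    print(rank, gene, f"{score:.4f}")
```

prints

```
ICN: 70 nodes, 622 direct edges
ASN: 2149 edges (1527 inferred)
query phenotypes: HP:7000025, HP:7000026, HP:7000028
causal gene:      HGNC:5005
1 HGNC:5005 1.1855
2 HGNC:5004 0.0583
3 HGNC:5008 0.0234
```

The planted causal gene HGNC:5005 ranks first: its summed association
strength to the three query phenotypes (1.19) dominates the strongest
decoy by a factor of 20.

The same flow is available from the shell:

```sh
litprior simulate --out data --seed 42
litprior build-icn --corpus data/corpus.jsonl --diseases data/diseases.tsv \
    --phenotypes data/phenotypes.tsv --genes data/genes.tsv --out icn
litprior infer --network icn --out asn
litprior prioritize --network asn --cases data/cases.tsv --top 10 --out ranks.tsv
litprior evaluate --network asn --gold data/gold.tsv --cases data/cases.tsv
```

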