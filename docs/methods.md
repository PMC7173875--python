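# Methods

## Model

`litprior` treats the literature as a sequence of counting units (whole
abstracts by default; sentences optionally). Per unit, the occurrence of
an entity — a rare disease, a phenotype, or a gene — is a binary event;
mention multiplicity within a unit is deliberately ignored, because the
correlation model below treats occurrence as Bernoulli per unit. For a
pair (a, b) with marginal occurrence probabilities P(a), P(b) and joint
P(a, b) estimated as unit fractions, the association is the phi
coefficient

    ρ_ab = (P(a,b) − P(a)P(b)) / sqrt(P(a)(1−P(a)) P(b)(1−P(b)))

— the Pearson correlation of the two indicator variables. Pairs with
ρ > 0 become edges of the initial correlation network (ICN). Negative
and zero correlations are excluded: the downstream consumers interpret
edge weight as positive association strength. A pair with a degenerate
marginal (an entity present in every unit or none) has undefined
correlation and is skipped.

The sample space is the set of documents that pass the rare-disease
filter (≥1 disease term in title+abstract); at sentence level, all
sentences within those documents. Counting over title+abstract rather
than abstract alone is a deliberate choice; titles are short and
information-dense, and the annotator operates on the concatenation
anyway.

### Indirect associations

The ICN only connects pairs that literally co-occur. Indirect evidence
(phenotype → disease → gene) is captured by a first-order spectral graph
convolution: with W the weighted adjacency and D the degree matrix of
W + I, the one-step operator is Ñ = D^(−1/2)(W + I)D^(−1/2), and the
accumulated pairwise score after T steps is

    S = Σ_{t=1..T} α^t Ñ^t ,

an attenuated sum over all walks of length ≤ T. Every non-adjacent pair
with S ≥ τ gains an edge of weight S tagged `inferred`; direct edges are
never modified. The augmented graph is the association network (ASN).

The exact convolution-filter coefficients used by the original
association-scoring algorithm are not fixed by any single standard; this
package fixes the operator to the symmetric renormalized adjacency above
with geometric attenuation, and exposes all four knobs:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `max_order` (T) | walk-length horizon | 3 | reaches phenotype→disease→gene and one step beyond; deeper orders are attenuated ~α^t |
| `alpha` (α) | per-order attenuation, (0,1] | 0.5 | halves the contribution per hop; keeps inferred scores well below typical direct weights |
| `tau` (τ) | minimum inferred score | 1e-4 | suppresses the long tail of numerically tiny walk sums without touching genuine 2–3 hop paths |
| `add_self_loops` | identity in the operator | true | the standard renormalization trick; keeps part of the signal at its source and bounds the spectrum |

Direct weights (phi, in (0,1]) and inferred scores (walk sums, typically
≪ 1 at the defaults) live on different scales. Prioritization consumes
both uniformly as non-negative association strengths; no rescaling is
applied, so direct evidence dominates where it exists — which is the
intended behaviour.

### Prioritization

A query is a set of phenotype ids. Each gene's score is the sum of its
edge weights to the query phenotypes in the queried network; genes with
zero score are not ranked; ties break by ascending gene id. This
sum-of-strengths rule is the package's design choice for "search the
network": multi-phenotype support aggregates additively, and
disease-mediated evidence enters through inferred phenotype–gene edges
rather than explicit path search. A consequence worth knowing: a gene
reachable only through a disease node but with no direct or inferred
phenotype–gene edge is not ranked; raising T is the remedy.

### Evaluation

AUC_N: for a disease's ranked gene neighbors, the ROC AUC restricted to
all true (gold) genes and the first N false genes of the ordering,
computed as the Mann-Whitney probability with ties counted 1/2. By
construction AUC_N ≤ AUC_overall. Diseases absent from the network, or
with no true or no false neighbor, are skipped; aggregates are
unweighted means over the evaluable diseases (skipped diseases are not
counted as zeros). Top-k recall: the percentage of cases whose
(best) causal-gene rank is ≤ k.

## NER and conflict resolution

Tokenization is one shared rule — alphanumeric runs, boundaries at any
transition to non-alphanumeric — with per-type stoplists, rather than
per-type tokenizers. Matching is case-insensitive with whitespace
collapsed and punctuation stripped at term boundaries only; per entity
type, leftmost-longest non-overlapping matches are reported; a term
carried by k ids of one type yields k annotations at one span. One
mitigation for short-acronym noise: gene terms of ≤3 characters must
match case exactly. No stemming or plural handling is applied.

Cross-type overlaps are resolved by precedence (phenotype > disease >
gene); within a type, longest span, then leftmost, then smallest id,
with exact-span multi-id ambiguity retained. Noise-term removal is a
user-supplied stoplist, not an automated corpus-frequency pass — there
is no principled universal threshold, and the stoplist keeps the
behaviour auditable.

The sentence splitter is intentionally minimal: a terminator in {., !, ?}
followed by whitespace and an uppercase letter, with a small abbreviation
list and a capitalized-initialism guard ("E. coli"). It only affects the
non-default sentence-level counts.

## Synthetic corpus

The generator plants a block structure: each of `n_diseases` diseases
owns `genes_per_disease` causal genes and `phenotypes_per_disease`
characteristic phenotypes. A document is a topic document with
probability `p_topic_doc` (disease drawn uniformly): it always names its
disease, names each owned gene/phenotype with probability
`p_mention_gene` / `p_mention_phenotype`, and every unrelated entity
with probability `p_background`; non-topic documents carry only
background mentions. Text is a bag of unique pseudoword surface terms
chunked into sentence-like spans — realistic enough to exercise the
splitter and token-boundary NER, while the co-occurrence counts are
independent of phrasing by construction.

Default conditions (the recovery setting): 500 documents, 10 diseases ×
1 gene × 5 phenotypes, mention probability 0.8, background rate 0.05,
`p_topic_doc` 0.6 (so a realistic minority of documents carry no disease
term and are removed by the filter), 30 decoy filler words, 20 test
cases of 3 phenotypes each. One causal gene per disease keeps Top-k
unambiguous. Setting the mention probabilities equal to the background
rate removes the planted signal, which the tests use as a negative
control.

What the synthetic conditions do **not** emulate: real synonymy and
ambiguity rates, negation and speculation ("no evidence of X"
co-occurrences count as associations), citation and topic drift, MeSH
structure, and the extreme sparsity of a multi-million-abstract corpus.
Passing the recovery test shows the machinery is sound end-to-end — it
does not certify performance on real literature.

## Numerical choices and edge cases

* phi is evaluated with arguments canonicalized (p_a ≤ p_b) so the
  function is exactly symmetric in floating point; joint probabilities
  are validated against the Fréchet bounds with a 1e-12 slack.
* Propagation applies the sparse operator successively to identity seed
  signals; no dense matrix powers. The accumulated score table is dense
  (n², thresholded immediately) — fine at the network sizes this package
  targets (10³–10⁴ nodes); corpus-scale engineering is out of scope.
* Zero-degree rows normalize to zero instead of dividing by zero.
* All iteration orders (dict construction, edge emission, file output)
  are sorted, so identical inputs give byte-identical outputs; edge
  weights serialize at 12 significant digits and round-trip within
  1e-11 relative.
* `min_support` (minimum pair count before correlation) defaults to 1,
  i.e. no support threshold is applied unless requested.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 500-document corpus (~70 entities, ~600 direct edges, ~1,500
inferred edges) and check the propagation and AUC implementations
against brute-force oracles on hundreds of randomized small instances
(graphs of ≤8 nodes, orderings of ≤25 candidates, indicator vectors of
≤1,000 units). These sizes make every oracle exactly enumerable while
leaving the code paths identical to larger runs.

## Known limitations

* The ranking rule is additive over query phenotypes; it does not model
  phenotype specificity (an uninformative, highly connected phenotype
  contributes as much as a discriminative one).
* Dictionary NER misses inflected or abbreviated mentions by design.
* Inferred scores are not calibrated against direct weights; τ and α
  shape the inferred edge set globally rather than per neighborhood.
* Correlations carry no significance testing; at small support the phi
  estimate is noisy, and `min_support` is the only guard.
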