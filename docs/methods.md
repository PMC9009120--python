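# Methods

This note documents the models implemented in `hallmarknet`, the
parameters that matter, the synthetic data the tests run on, and the
design choices made where the underlying procedure was open to
interpretation.

## Dictionary matching

Sentences and synonyms are lowercased, Unicode hyphen variants
(U+2010–U+2013) are mapped to ASCII `-`, and text is split into word
tokens (runs of letters/digits; underscores split). A synonym matches
iff its token sequence occurs contiguously among the sentence tokens,
which makes matching case-insensitive and token-boundary safe ("ERK"
never fires inside "BERKELEY"). There is no stemming and no fuzzy
matching: this is the minimal convention that is exactly reproducible,
at the cost of missing inflected or misspelled mentions. Greek letters
are kept literal; dictionaries may carry ASCII aliases as extra
synonyms. Every synonym of a descendant taxonomy term is attributed to
its root hallmark, so matching yields root-level ids only. Overlapping
synonyms all fire and deduplication happens at the entity level —
harmless because all counts are per entity per sentence.

The packaged taxonomy (65 terms, four levels, nine roots) was authored
from the standard hallmarks-of-aging vocabulary; its term counts match
the published taxonomy's shape, but label and synonym choices are this
package's own.

## Co-mention scoring

The Ochiai coefficient `OC(H,D) = n_HD / sqrt(n_H n_D)` is a cosine
similarity on sentence-set indicators: 0 when the entities never
co-occur, 1 iff every sentence mentioning either mentions both. The
marginals `n_H`, `n_D` are counted over the whole corpus, not only
over sentences containing the partner entity. A squared variant
(`squared=True`) is available for sensitivity checks. Defaults that
matter:

- `min_sentences = 250` — diseases with fewer associated sentences are
  dropped before scoring; estimates below this support are dominated
  by matcher noise.
- Curation evidence rule — a pair needs 1 confirming curated sentence
  when its hallmark has fewer than 2,500 co-mention sentences in
  total, 3 otherwise; unconfirmed pairs are zeroed. The threshold is
  interpreted per hallmark (total co-mention volume across diseases).
  `apply_curation` is idempotent, and pairs absent from the curation
  table remain untested rather than silently zeroed.
- `k = 30` — ranking depth per hallmark. Ties break lexicographically
  on disease id; the tie-break is deterministic everywhere the ranking
  is reused (including inside the permutation null).

## Subnetwork density and the permutation null

Density `D = 2E/(V(V-1))` is topology-only: edge weights play no role,
and D is monotone in added internal edges. The null shuffles the score
vector over **all** network nodes (zero-scored nodes included), takes
the new top-k with the same tie-break, and recomputes density;
`p = #{D_k >= D_0}/K` with `K = 20000` by default. As printed this
estimator can return p = 0; an optional add-one smoothing
(`smoothed=True`, `(sum+1)/(K+1)`) is off by default to match the
published definition. With distinct scores the null reduces to uniform
k-subsets, which is what the exhaustive-enumeration oracle in the
tests exploits. Because the indicator uses `>=`, the p-value is
conservative when density ties are common (small or very sparse
networks). BH correction is applied per hallmark across the four age
strata; the family is an argument, not hard-coded.

## Random walk with restart

`F_i = alpha W' F_{i-1} + (1-alpha) F_0` with `alpha = 0.5` and a
default of 30 fixed iterations plus an early stop when the max-abs
change drops below `tol = 1e-9` (pass `tol=None` for exactly fixed
iterations). "Degree" normalisation for a weighted network is
ambiguous; the default `mode="degree"` divides each row by the node's
edge count (the literal reading), and `mode="strength"` divides by the
weighted degree so rows sum to 1. Results differ across modes; under
`strength` the iterates are bounded by the prior maximum. When the
spectral radius of `alpha W'` is below 1 the iteration converges to
`(I - alpha W')^{-1}(1-alpha)F_0`, which the tests verify against a
direct linear solve. Posterior scores are not re-normalised before
re-ranking. The "incompletely understood pathogenesis" flag used by
`newly_prioritized` is an editorial user input, not derived.

## GWAS and GO

Genome-wide significance is a strict `p < 5e-8`; ancestry filtering is
case-insensitive substring matching on the study ancestry description
(include and exclude pattern lists), and a study-id exclusion list
supports removing publications that overlap the mined corpus. Gene
intervals are 1-based inclusive; BED input is converted on read. A SNP
links to every gene containing it, and otherwise to every gene whose
nearest interval boundary (strand ignored, not TSS) is strictly closer
than the window — 50 kbp by default, 75 kbp for the re-run on newly
prioritized diseases. The link table is monotone in the window.

Over-representation is the one-sided Fisher exact (hypergeometric
upper tail) per GO term, after propagating annotations up `is_a`
ancestors, against a user-supplied background; terms annotating fewer
than 5 background proteins are not tested and the significance cutoff
is p < 0.05. Study proteins outside the background are dropped with a
count. The classic test is the default; an optional `elim` pass
removes the study proteins of already-significant descendant terms
before testing ancestors, reducing hierarchy redundancy. This is a
simpler decorrelation than topGO's weight01 algorithm, so term-level
p-values are not expected to match a weight01 run; results carry the
method label. Shared pathways are the intersection over all nine
hallmark lists of significant terms whose names contain "pathway" or
"cascade" under the same token-boundary matching as the lexicon.

## Synthetic data

The generators are pure functions of their specs (seed included) and
record exact realized ground truth, so expected values downstream
never require re-reading the generated files.

- **Corpus** — per sentence, independent Bernoulli mention indicators
  per entity; a planted pair with lift L is sampled conditionally so
  the disease marginal is preserved while the joint equals
  `L p_H p_D`. Sentences are templated lists of synonyms, which is
  faithful to a co-mention pipeline but carries none of real text's
  negation, ambiguity, or synonym collisions — passing recovery tests
  shows the statistics behave as designed, not that the matcher would
  survive raw PubMed prose. Defaults mirror the study's shape at desk
  scale: 9 hallmarks at mention probability 0.02, 184 ARDs at 0.01,
  50,000 sentences — roughly 1,000 sentences per hallmark and 500 per
  disease, comfortably above the 250-sentence filter.
- **Networks** — Erdős–Rényi background (default edge probability
  0.05–0.1 in tests) with planted modules of higher internal edge
  probability; weights uniform on (0.05, 0.5] to mimic positive
  partial correlations. Real multimorbidity networks have degree
  heterogeneity and age-correlated structure that ER graphs lack; the
  permutation test is topology-agnostic, so calibration on ER graphs
  checks the estimator, not epidemiology.
- **Genetics** — genes of 20 kbp spaced 200 kbp apart on one synthetic
  chromosome (so distance windows never bridge neighbouring genes),
  per-disease causal genes with SNPs inside the gene, strictly inside
  50 kbp, and in the 50–75 kbp band (visible only to the wider
  window), plus sub-threshold and excluded-ancestry decoys; one GO
  term annotates ~60% of every hallmark's causal proteins, making it
  the unique universally enriched pathway, with randomly annotated
  decoy terms.

## Test problem sizes

Statistical acceptance checks run at sizes chosen to keep the suite
fast while leaving comfortable margins: corpus recovery 30 replicates
at the default 50,000-sentence spec; planted-module detection 100
replicates at K = 2,000 permutations; shared-pathway recovery 50
replicates; null calibration 200 replicates at K = 1,000 on 120-node
graphs (p-value granularity 1/1000 is fine for a 0.05 band). The
exhaustive permutation oracle uses a 6-node graph where all C(6,3)=20
top-sets can be enumerated.

## Known limitations

- The matcher does no abbreviation disambiguation; a dictionary
  containing short ambiguous synonyms will over-match on real text.
- Whether repeated boilerplate sentences should be deduplicated before
  counting is corpus-dependent and left to the caller.
- `elim` is not weight01; GO results are comparable within a method,
  not across methods.
- The permutation p-value is a Monte-Carlo estimate with resolution
  1/K; at K = 20,000 the smallest nonzero p is 5e-5.
- Trait-to-disease mapping for GWAS records is an input file; no
  ontology subclass closure is computed.
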