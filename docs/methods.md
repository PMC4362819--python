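# Methods

## The problem

Literature-mined gene–gene interaction networks annotate each
co-mentioned gene pair with the *type* of interaction stated in the
sentence (neutralization, cleavage, phosphorylation, …), resolved
against an interaction-type ontology whose terms carry surface-form
keyword lists. Given such a network for a whole corpus and for a
concept-restricted document subset (e.g. vaccine-related abstracts),
the question is which interaction types are used significantly more or
less often inside the concept subset than in the corpus at large.

## Pipeline

1. **Ontology** (`inoenrich.ontology`). The interaction branch is a
   rooted DAG over `is_a` edges only; other axioms are irrelevant to the
   statistics and are ignored. The exchange format is a flat OBO-subset
   dialect (term id, name, repeatable `is_a`, a
   `has_literature_mining_keywords` annotation with pipe-separated
   variants, optional `is_obsolete`). Obsolete terms are dropped at
   parse time; keywords are lowercased and deduplicated; colon-form IDs
   are normalised to underscore form. Multiple parents are supported
   and annotation flows along *all* parent paths, with set semantics so
   nothing is double-counted. Parsing restricts the file to the chosen
   root's branch, so sibling branches in a larger export are ignored
   rather than rejected.

2. **Tagging** (`inoenrich.tagging`). Tokens are maximal runs of
   `[A-Za-z0-9-]`, so hyphenated symbols (`IL-12`, `IFN-gamma`) are
   single tokens. Gene surface forms and interaction keywords are
   matched case-insensitively on token boundaries, longest match first,
   ties leftmost, each token consumed by at most one match per channel;
   the gene channel and the keyword channel are independent. A sentence
   containing ≥ 2 distinct canonical genes and ≥ 1 keyword emits one
   record per unordered gene pair, each carrying the full set of matched
   term IDs. Self-pairs are excluded. Cross-sentence coreference and
   gene-symbol disambiguation are out of scope; the lexicon is taken at
   face value. External sentence-classifier confidence scores can be
   attached per (document, sentence, pair); records with non-positive
   scores are dropped, unscored records pass through. Concept documents
   are those with any sentence containing a base concept variant (for
   the vaccine use case: vaccine/vaccines/vaccination/vaccinated) or
   any phrase from a specific concept-term list, matched the same way.

3. **Networks** (`inoenrich.network`). The counting unit is the unique
   unordered gene pair per term. Each record's pair is attached to every
   directly matched term and all of its ancestors (true-path rule), so a
   parent such as *cleavage reaction* aggregates all its descendant
   types; propagation is applied identically to the whole network and
   the concept sub-network before testing. Distinct supporting
   documents are counted per (term, pair) solely for the
   "most frequent gene pair" report column. The whole network includes
   the sub-network's records — the test below compares sub against
   whole, not sub against its complement.

4. **Enrichment** (`inoenrich.enrichment`). For each term the 2×2 table
   is (a = sub pairs with term, b = sub pairs without, A = whole pairs
   with, B = whole pairs without). The test is a one-sided Fisher's
   exact test made conservative EASE-style: for over-representation the
   evidence cell is shrunk to `a − 1` (so single-pair support can never
   be significant) and for under-representation symmetrically inflated
   to `a + 1`, capped at `min(a + b, A)`; the margins are recomputed
   from the shifted cell and the exact hypergeometric tail is summed in
   log space (gammaln-based log-pmf, log-add accumulation — never a
   chi-square or normal approximation). The under-direction shift is an
   interpretation: the published description defines the −1 device for
   over-representation only, and both the shift and the sidedness can
   be disabled/switched by flags (`modified`, `sided`). Folds are
   computed from raw counts, `(a/(a+b)) / (A/(A+B))`. Only terms with
   `a ≥ min_pairs` (default 5) enter testing and the BH correction, so
   the BH `m` is the size of the tested set. A term is called *over* at
   BH p < α (default 0.05) with fold ≥ 2, *under* at BH p < α with
   fold ≤ 0.5; otherwise *none*. The candidate direction for the
   one-sided p follows the raw fold (over iff fold > 1). Ties for the
   most frequent gene pair break lexicographically on the canonical
   pair string. P-values are kept at full precision throughout.

## The worked-example discrepancy

The documented worked example (30 of 180 sub-network pairs vs 1500 of
31500 whole-network pairs) is published with p = 6.9e-20. The faithful
computation on those cells gives 1.03e-08 (one-sided, −1 shift); the
two-sided and unmodified variants give 1.03e-08 and 2.9e-09, and no
exact-test construction of that 2×2 (sub vs whole, sub vs complement,
sampling, binomial, chi-square) yields 6.9e-20. The acceptance test
asserts the published value and therefore fails, printing all three
computed diagnostics; the implementation is not patched toward the
printed number. The likely explanation is that the published p was
taken from the real-corpus run rather than from the illustrative cells.

## Synthetic data

`inoenrich.simulate` generates the full input bundle: a random rooted
DAG of interaction types (each non-root term gets 1–2 earlier parents;
second parent with probability `dag_density`), 2–5 inflected keyword
variants per term derived from unique pseudo-verb labels, a gene
lexicon of unique uppercase symbols with one hyphenated synonym each,
and a template corpus: every background gene pair appears in exactly
one sentence `"<GENE1> <keyword> <GENE2> in <context>."`. Term usage is
Zipf-distributed (exponent 1) over non-root terms, one direct term per
pair; concept-subset pairs draw each planted term at `fold ×` its
background probability (others renormalised; infeasible folds are
rejected before generation). Concept sentences embed a base concept
variant or a specific concept phrase so document selection can recover
the subset exactly. Hard mode emits a fraction of two-keyword
sentences to exercise multi-term records.

Scale: the real analyses this emulates involve ~3×10⁵ background pairs
with a ~2% concept subset from tens of millions of abstracts. Defaults
use 5000 background pairs, concept fraction 0.02, 20 terms, 120 genes,
2000 documents — large enough for planted folds to be recoverable,
small enough that hundreds of seeded replicates run in seconds.

What the generator does **not** emulate: ambiguous or nested mentions,
synonymy beyond one hyphen variant, multi-sentence documents with
correlated pairs, classifier score distributions, or English syntax.
Passing tests therefore demonstrate the correctness of the counting and
the statistics, not robustness of the tagger to real abstracts.

Two deliberate consequences of the design are visible in the tests.
First, because the whole network contains the concept subset, a term
planted at fold *f* has a measurable enrichment fold of
`f / (1 + c(f − 1))` with concept fraction *c* (≈ 4.3 for f = 5,
c = 0.04); recovery is asserted on the run-mean against a ±20% band
around the target. Second, the −1 shift makes the null strictly
conservative: the observed null rejection rate sits far below the
nominal 0.05.

## Numerical choices

- Exact tails: log-pmf via a cached gammaln table, suffix/prefix
  accumulation with `logaddexp`; validated against integer enumeration
  (`math.comb` rationals) exhaustively for population totals ≤ 200 at
  ≤ 1e-12 relative error.
- Conservatism of the shift is checked exhaustively for totals ≤ 100
  through the margin parameterisation (the shifted table is a survival
  under margins reduced by one).
- BH adjustment delegates to `statsmodels.multipletests(method="fdr_bh")`
  after explicit range validation.
- Degenerate inputs: a = 0 gives p = 1 for over-representation; a term
  absent from the whole network has no defined fold and is excluded
  from calls; an empty sub-network is an error (CLI exit code 2).
- Determinism: all generation uses `numpy.random.default_rng(seed)`
  with draws vectorised up front; a fixed seed reproduces files
  byte-for-byte.

## Limitations

- Sentence-level co-occurrence overstates interactions in enumerative
  sentences and misses cross-sentence statements; direction of an
  interaction is not inferred.
- The statistical model treats pairs as exchangeable units; correlated
  evidence (one prolific gene pair across many terms) is not modelled.
- Real-corpus headline tallies require the full literature corpus and
  are out of desk-scale reach; the test surface covers the method's
  properties, not those totals.
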