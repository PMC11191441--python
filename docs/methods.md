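# Methods

## Model

`lexmap` treats variable harmonization as retrieval followed by pairwise
match classification over *sentences* — the concatenation of a variable (or
reference term) name with its description when one exists. The two stages
deliberately separate two different questions:

* **Retrieval** ("what could this be?") is a nearest-neighbour search in a
  Euclidean embedding space ℝ^d. The query sentence is embedded and the K
  closest reference-term sentences become candidates. The scan is exact; at
  the CDM scales this package targets (~10^2–10^3 terms) an approximate
  index would buy nothing and cost exactness.
* **Reranking** ("is this pair the same concept?") is a binary classifier
  applied to each (query, candidate) pair, producing a match probability.
  Candidates under the elimination threshold are dropped; the winner
  maximizes the blend `W1·p + W2·s`, where `s` is the case-folded,
  max-length-normalized Levenshtein similarity of the *names* (descriptions
  are deliberately excluded from the string channel — naming conventions,
  not prose, are what edit distance captures here).

Prior-knowledge expansion optionally widens the comparison set from the K
term sentences to all known aliases of those terms, resolving a winning
alias back to its parent term. This helps exactly when the incoming cohort
shares naming conventions with an already-mapped cohort and can hurt
otherwise, because aliases give the reranker more chances to prefer a
wrong-but-similar-looking item; both behaviours are visible in the shipped
benchmark (with-prior accuracy at K=5 trails without-prior by ~10 points
under default conditions).

## Assumptions

* Every cohort variable maps to exactly one reference term (many-to-one).
  Variables whose semantics straddle two terms are out of scope.
* A variable's modality equals its reference term's modality, and hard
  negatives are only meaningful within a modality, where naming conventions
  collide (left/right imaging variables being the canonical case).
* Harmonization reads data dictionaries only — variable names and
  descriptions — never participant-level values.

## Components and defaults

| parameter | default | meaning |
|---|---|---|
| `embedding_dim` (d) | 768 | hash buckets of the n-gram encoder / embedding dimension |
| `K` | 5 | retrieved candidates; benchmark runs show hit@K plateaus shortly after 5 |
| `threshold` | 0.5 | minimum match probability to survive elimination |
| `W1`, `W2` | 1.0, 0.0 | blend weights; `(0.8, 0.2)` is the recommended setting for unseen cohorts |
| class weights | 0.1 neg / 0.9 pos | per-pair loss weights in classifier training |
| split | 80/4/16 | train/test/validation fractions of the pair corpus |
| triplet margin | 1.0 | enforced gap between own-term and other-term distances |
| triplet epochs / lr | 30 / 0.5 | full-batch gradient descent schedule |

W1 and W2 are independent weights in [0,1] and are not forced to sum to 1.

**Encoder.** The default encoder hashes the lowercased character-3-gram
multiset of a sentence into d buckets (blake2b salted by the seed) and
L2-normalizes. It is deterministic, total, and training-free; its geometry
already places surface variants near each other. Any model exposing
`encode`/`transform` with a fixed dimension — e.g. a mean-pooled
transformer encoder — can be dropped in behind the same contract.

**Embedder (retrieval model).** A linear map W on top of the encoder,
identity-initialized, fitted by full-batch gradient descent on the triplet
hinge loss `max(0, margin + ‖W(a−p)‖ − ‖W(a−n)‖)` over (alias, own term,
random same-modality other term) triplets. This directly optimizes the
retrieval criterion (aliases close to their own term) while the identity
initialization guarantees the untrained embedder is exactly the raw
encoder (`epochs=0` is a strict no-op).

**Pair classifier (reranking model).** Logistic regression on the
concatenated pair features `[|a−b|, a⊙b]` of the two sentence embeddings,
fitted with per-pair sample weights. Positives are all unordered pairs
within a term's mapping cluster ({term} ∪ aliases); negatives are sampled
uniformly without replacement from same-modality, cross-term sentence
pairs, stratified per modality proportionally to the modality's positive
count, to the same total as the positives. No negative duplicates a
positive as an unordered sentence pair.

## Numerical and procedural choices

* **Determinism.** Every stochastic step (term sampling, variant drawing,
  negative sampling, splitting, training) is keyed to an explicit seed;
  repeated runs are bit-identical.
* **Ties.** Candidate retrieval breaks distance ties by lexicographic
  term_id. Winner selection breaks combined-score ties by lexicographic
  term_id first, then smaller embedding distance — the same rule the
  string-matching baseline uses, so the degenerate configuration
  (W1=0, W2=1, threshold 0, K=|terms|) reproduces the baseline *exactly*,
  tie-breaks included. This equivalence is asserted per-variable in the
  acceptance suite.
* **Degenerate inputs.** Whitespace-only descriptions count as absent;
  empty names are rejected at the single-variable API and recorded as
  error-status rows in batch mode rather than aborting the file; an empty
  candidate table is a state error; requesting more hard negatives than
  exist raises a capacity error reporting the true maximum.
* **Threshold semantics.** Elimination applies to the raw classifier
  probability, before blending; at threshold 0 every input yields a winner,
  and any threshold above the maximum observed probability abstains
  everywhere.
* **Accuracy definition.** A no-match counts as an error (conservative
  choice; the alternative of excluding abstentions would inflate scores).
  Accuracies are reported as percentages with two decimals.
* **Accuracy vs K.** hit@K is nondecreasing in K by construction. Top-1
  accuracy is *not*: widening K can surface a candidate the reranker
  wrongly prefers which narrow retrieval had excluded, so K=1 occasionally
  beats K=10. Users tuning K should look at both numbers.

## The synthetic benchmark

`lexmap.synthetic` generates CDMs from a built-in vocabulary of ~65
dementia-research concept phrases (demographics, cognitive instruments,
CSF and plasma markers, MRI volumes/thicknesses, PET measures, genetics),
each with a hand-written description and its natural modality. A
configurable fraction of terms is emitted as left/right pairs differing by
one character ("L hippocampus volume" / "R hippocampus volume") to
reproduce the lateralized hard-negative structure; vocabulary exhaustion is
handled with visit-qualified composites ("… at month 12"). Cohorts rename
every term through stochastic rules — initial-letter abbreviation,
truncation, case change, underscore style, cohort suffixes, vowel dropping,
synonym swaps — and descriptions are word-dropped or removed entirely
(30% by default), emulating dictionaries that ship no descriptions.

Default benchmark conditions: 150 terms, 4 training cohorts, 2 held-out
cohorts (300 evaluation queries), lateralized fraction 0.3, d=768. A full
train-and-evaluate run takes ~15 s on one CPU; the five-seed
pipeline-vs-baseline comparison in the test suite stays under a minute.

What passing on this benchmark shows: the cascade recovers mappings under
realistic *surface* perturbations of names and descriptions, and beats
name-only Levenshtein matching under those conditions. What it does not
show: performance on real cohorts, where descriptions are written by
different humans in different registers, vocabularies drift semantically
rather than orthographically (e.g. "schooling" vs "education" is as hard
as it gets here), and the reference model itself has curation errors. The
generator perturbs strings; it does not model genuine semantic synonymy
beyond a small fixed synonym table, so results here are an upper bound on
what a training-free encoder could do in the wild — a fine-tuned
biomedical transformer behind the same encoder contract is the intended
production configuration.

## Known limitations

* The linear triplet embedder can only reweight/mix the n-gram feature
  space; it cannot learn synonymy that shares no character n-grams.
* Logistic pair classification is calibrated only loosely; the 0.5
  threshold is a convention, not a calibrated operating point, and no
  probability calibration is asserted anywhere.
* One variable → one term is enforced structurally; composite variables
  (e.g. joint APOE allele encodings) must be split upstream.
* The model archive serializes only n-gram-backed components; custom
  encoder backends must be re-attached after loading.
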