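# lexmap

Semantic harmonization of cohort-study variable names against a common data
model (CDM).

## The problem

Observational cohort studies name the same measurement in incompatible ways:
participants' age appears as `age`, `PTAGE`, `samplingAge`, `age_at_visit`;
years of education as `Eduy`, `education`, `EDUC`; FreeSurfer pipelines emit
near-duplicate left/right variables like `Lhippo_FS_adj` / `Rhippo_FS_adj`.
Cross-cohort analysis requires mapping every such variable onto a canonical
*reference term* — a job usually done by hand from the cohorts' data
dictionaries (variable names + optional descriptions; no participant-level
data is touched). `lexmap` automates it for data curators and researchers
who need to pool dementia-style cohort datasets.

## The method

Given a CDM — reference terms, previously mapped cohort variables
("aliases" / prior known mappings), and a modality label per term — the
pipeline is a retrieve-and-rerank cascade:

1. **Sentences.** Each variable or term becomes the sentence
   `name ⊕ " " ⊕ description` (name alone when the description is absent).
2. **Retrieval (embedder).** Sentences are embedded in ℝ^d (default d = 768,
   hashed character-3-gram encoder, optionally refined by a triplet-loss
   linear map trained so each alias lies closer to its own term than to a
   same-modality competitor). The K reference terms nearest in Euclidean
   distance are the candidates (default K = 5).
3. **Optional prior-knowledge expansion.** Each candidate contributes all
   of its known aliases to the comparison set; a winning alias is resolved
   back to its parent term by reversing the known mapping.
4. **Reranking (pair classifier).** A binary classifier — logistic
   regression on the pair features `[|a−b|, a⊙b]`, trained on positive
   pairs (within a term's mapping cluster, class weight 0.9) and hard
   negatives (same modality, different term, class weight 0.1, equal count)
   with an 80/4/16 train/test/validation split — scores each (query,
   candidate) pair. Candidates with match probability below the threshold
   (default 0.5) are eliminated.
5. **Winner.** Among survivors, the item maximizing
   `W1 · p_match + W2 · sim_lev(query, candidate)` wins, where `sim_lev` is
   the case-folded Levenshtein similarity `1 − d/max(|a|,|b|)`. No
   survivors ⇒ no match.

A naive string-matching baseline (nearest term by `sim_lev` alone) is
included for comparison, plus a synthetic-CDM generator that emulates
multi-cohort naming conventions (abbreviation, truncation, case and
underscore changes, cohort suffixes, vowel dropping, synonym swaps,
dropped descriptions, lateralized near-duplicates) so everything runs and
is scored fully offline.

## Worked example

```python
from lexmap import Harmonizer, HarmonizationConfig
from lexmap.synthetic import make_benchmark

cdm, unseen = make_benchmark(n_terms=150, n_cohorts=4, n_unseen=2,
                             lateralized_fraction=0.3, seed=1)
cfg = HarmonizationConfig(K=5, W1=0.8, W2=0.2, threshold=0.5,
                          seed=1, embedding_dim=768)
h = Harmonizer(config=cfg).fit(cdm)

r = h.harmonize("MMSCORE", "Mini mental state examination score")
print(r.winner, h.cdm_.terms[r.winner].name, round(r.probability, 3))
```

prints

```
T0061 Mini-Mental State Examination (MMSE) 0.993
```

i.e. the unseen cohort spelling `MMSCORE` is mapped to the reference term
`Mini-Mental State Examination (MMSE)` with match probability 0.993. On the
full pair of held-out synthetic cohorts from the same run (300 variables),
the trained cascade reaches **74.33%** top-1 accuracy at K = 5 versus
**64.67%** for the string-matching baseline, with retrieval hit@5 at
91.33% — the correct term is almost always among the candidates, and the
reranker picks it out most of the time.

The same pipeline is scriptable from the shell:

```bash
lexmap benchmark results.csv --seed 1            # synthetic benchmark grid
lexmap map my_cdm.json PTAGE --description "Age at baseline"
lexmap map-file my_cdm.json dictionary.csv mapped.csv
```

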