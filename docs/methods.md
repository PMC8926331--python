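# Methods

This note records the model conventions, the numerical choices, and what
the synthetic-data tests do and do not establish.

## Text encoding

Tokenization keeps maximal alphabetic runs (punctuation, digits and other
special characters act as separators) and lowercases. Vocabulary filters
run in a fixed order — tokenize, minimum word length (default 3), minimum
corpus-wide occurrence count (default 7), stoplist — with all matching on
lowercased forms. The occurrence filter counts *total* occurrences in the
corpus; the idf statistic n_w counts *documents containing* the word; the
two are maintained separately. The stoplist resource holds prepositions,
pronouns and articles, and the drug names from the packaged drug table are
merged in at build time, so a drug's own name cannot masquerade as
experience vocabulary.

tf-idf uses the length-normalized term frequency and the smoothed inverse
document frequency idf(w) = log(N / (1 + n_w)) with the natural logarithm.
The base only rescales columns globally, and the downstream canonical
correlations are invariant to per-column scaling; the smoothing constant
implies a *negative* idf for a word present in every document, which is
preserved deliberately (it is what the formula says, and a
ubiquitous word carries anti-salience under this weighting).

Class imbalance between drugs is counteracted by sampling a fixed number
of reports per drug without replacement (default 300); drugs with fewer
reports contribute all of them, never duplicates.

## Latent semantic analysis

The tf-idf matrix (testimonials × words) is decomposed as M ≈ T R Wᵀ with
orthonormal testimonial weights T, positive nonincreasing relevances R
(singular values) and orthonormal word weights W. Conventions:

- **No centering.** Classical LSA decomposes the raw tf-idf matrix; the
  explained-variance denominator is accordingly the uncentered squared
  Frobenius norm. Centering would only shift the CCA input by a constant
  row, which CCA removes anyway.
- **Document coordinates** X = T·diag(R), the standard relevance-scaled
  embedding. The scaling is per-column and therefore also invisible to
  CCA; it is kept because it makes X·Wᵀ the rank-k reconstruction.
- **Sign convention:** each component is oriented so its largest-|weight|
  word is positive. Canonical correlations are invariant to these flips.
- **Solver:** exact dense LAPACK SVD up to 4M-entry matrices, else a
  seeded randomized SVD (7 power iterations). The dense path makes the
  oracle-equivalence tests exact; the randomized path is deterministic
  under the recorded seed.

## Receptor fingerprints

Ki values are declared in nM; pKi = 9 − log₁₀(Ki_nM) is the molar
negative log. npKi = 4 + (pKi − pKiMax) is computed over the measured
entries of each drug, with missing assays and non-significant binding
(Ki > 10,000 nM) at the floor value 0. The grouping (pKi − pKiMax) keeps
the per-drug ceiling at exactly 4.0 in floating point. A measured entry
more than four decades weaker than the drug's best target would go
negative and is floored at 0 (very low affinities are reported as zero).
Replicated assays for the same (drug, receptor) pair are combined by
geometric mean — the log-domain average consistent with pKi — with an
arithmetic option. The Cheng–Prusoff helper Ki = IC50/(1 + [A]/EC50)
converts functional IC50 readouts where needed.

## Canonical correlation analysis

Both blocks are centered (covariance, not correlation, form; a
standardized variant is a flag away by scaling inputs). Each block is
pseudo-whitened via its SVD with singular values truncated at
1e-10 × the largest — essential here because Y repeats one fingerprint
row per drug, so its centered rank is at most n_drugs − 1 — and the SVD
of the whitened cross-covariance yields ordered correlations and
canonical vectors. Variates are scaled to unit sample variance. An
optional ridge adds ε to the squared singular values during whitening
(units of XᵀX); the default is 0, and the unregularized solution matches
the textbook generalized-eigenvalue construction to 1e-8 (tested on 100
random instances). Factor signs at fit time make each factor's
largest-|weight| receptor coefficient positive; the anatomical anchor
rule below overrides this.

## Permutation inference

Significance is nonparametric: X held fixed, rows of Y re-paired with
testimonials uniformly at random, the model refitted, and the *maximum*
canonical correlation recorded per iteration (default 1000). Comparing
every observed factor against this single max-null controls the
family-wise error of searching across all factors and makes p-values
automatically nondecreasing down the factor order. P-values use the
add-one estimator (1 + #exceedances)/(n_perm + 1) — valid with a nonzero
floor — and ties count as exceedances (conservative). Per-iteration RNG
substreams are spawned from the master seed, so the null distribution is
reproducible and independent of execution order.

Unregularized refits reuse the observed whitening: permuting Y's rows
permutes its orthonormal variate basis identically and changes neither
column means nor singular values, so each iteration reduces to one small
SVD of Qxᵀ Qy[perm]. The shortcut is verified against explicit refits
shuffle-by-shuffle in the test suite.

A drug-block shuffle (permuting which drug gets which fingerprint) is
available off by default: repeated Y rows mean testimonial-wise shuffling
tests pairing exchangeability at the report level, which is the procedure
of record here, but users wanting drug-level exchangeability can opt in.

## Anatomical mapping

The region × receptor transcription table is preprocessed by z-scoring
each receptor across regions (population SD, ddof = 0 — a convention
flag) and then shifting the whole table by its single global minimum so
the smallest entry is exactly 0 (a per-column variant is available).
Factor scores are transcription · b, demeaned and variance-scaled per
factor across regions. Since a CCA factor's global sign is arbitrary,
each factor is oriented so the mean score over a designated anchor region
set (visual-cortex parcels in the reference setting; the generator's
tagged anchor block in synthetic studies) is nonnegative; the flip is
applied jointly to b, a, U, V and the regional scores, leaving every
canonical correlation bit-identical. An exact zero anchor mean keeps the
fit-time sign. Anchor sets are user-supplied label lists; a convenience
selector picks labels containing "Vis", matching the naming scheme of the
200-parcel atlas this analysis targets.

## Factor reports and sensitivity analyses

Figure-style summaries are operationalized as: word salience =
W·diag(R)·a (the factor's semantic vector pushed back to word space;
poles = sign), drug score = (npKi(d) − mean_Y)·b (the receptor variate at
each drug's fingerprint). Both are constructions of this package —
reasonable back-projections of quantities the reference figures display
without formal definition — and are labelled as such. Rankings break ties
lexicographically. Confound checks correlate each factor's variates with
distinct-word counts (language complexity) and per-drug typical duration;
a zero-variance confound yields NaN, reported as undefined. Note that
duration varies only between drugs, so its effective sample size is the
drug count: the test suite evaluates it against a drug-level permutation
null. Subgroup stability refits the entire pipeline per subgroup (median
age split or sex) and compares receptor-side vectors by sign-aligned,
greedily matched Pearson correlations.

## Synthetic study generator

The generator emulates the *statistical* structure of the real inputs,
not their content:

- **Panel:** Ki log-uniform over 1 nM–100 µM, 10% missing entries by
  default, one guaranteed strong target per drug.
- **Factors:** receptor-side directions are the leading right singular
  vectors of the drug-level centered npKi table, so per-drug receptor
  scores of different factors are exactly uncorrelated. Each report
  inherits its drug's receptor score v (constant within drug, mirroring
  the repeated fingerprint rows) and draws a semantic score
  u = ρv + √(1−ρ²)·ε. The planted canonical correlation is therefore
  realized marginally across reports — between-drug signal plus
  within-drug semantic noise.
- **Words:** each factor drives an opposing pair of topics whose mixture
  shares are *linear* in u (baseline × (1 ± c·u)); ε is a rescaled
  truncated normal and the gain c is set from the attainable score range,
  so shares never clip and expected word counts are an exactly linear
  function of the latent scores. This linearity is load-bearing: any
  nonlinearity whose drug-conditional mean varies between drugs would
  plant additional genuine canonical factors beyond the requested ones
  (Y's variate space contains *every* drug-level contrast). The opposing
  poles cancel in the mixture normalizer, which preserves the linearity;
  background topics carry bounded uniform share noise scaled by
  `noise_scale`. Topics own disjoint signature-word blocks (Dirichlet
  weights, 20% uniform background mass); counts are Poisson at document
  length × mixed word distribution; lengths are log-normal.
- **Noise dial:** `noise_scale = 0` freezes background topics, document
  lengths and count sampling (rounded expectations), so a planted ρ = 1
  makes same-drug reports identical and the pipeline recovers ρ = 1 to
  numerical precision.
- **Defaults** (chosen once as a realistic desk-scale stand-in): 27
  drugs × 200 reports, 40 receptors, 500-word vocabulary, 10 topics, mean
  document length 500 (real experience reports run to hundreds of words),
  `noise_scale` 1.

With planted (0.8, 0.6) at these defaults, the pipeline recovers
ρ̂ ≈ (0.74, 0.57): word-count noise attenuates the observable correlation
slightly below the latent value, partially offset by CCA's small-sample
optimism. Recovery of the planted receptor vectors is near-exact
(|r| > 0.9), and exactly the planted number of factors is declared
significant.

**What passing tests do not show about real data:** the generator's
"language" is structureless symbol blocks — no polysemy, no grammar, no
correlated topics, no heavy-tailed word frequencies — and its
within-drug noise is exchangeable, with no per-author or session-level
dependence. Real corpora also face scraping artifacts, dose and set/
setting confounds, and vocabulary two orders of magnitude larger. The
tests establish the *pipeline's* correctness and calibration, not the
robustness of conclusions drawn from any particular real corpus.

## Problem sizes and calibration checks

The test suite validates permutation calibration with 200 independent
datasets × 200 permutations (n = 200, 5 × 4 blocks): the family-wise
rejection rate at α = 0.05 must land in the exact binomial 95% interval.
End-to-end recovery runs 10 seeded replicates of the default 27 × 200
study (k = 50, 1000 permutations each), requiring in ≥ 8 seeds: exactly
two significant factors, ρ̂ within ±0.1 of planted, planted signature
words leading the first factor's saliences, and |r| > 0.8 to the planted
receptor vectors. These sizes keep the whole suite around a minute on one
CPU while leaving the statistical margins wide.

## Known limitations

- Functional pharmacology (agonism vs antagonism, functional selectivity)
  is outside the model: fingerprints are binding affinities only.
- The vocabulary filters reproduce the *procedure*, not any particular
  corpus's word list; published corpus-level counts are not reproducible
  without the original corpus.
- The transcription table is consumed as a plain region × receptor
  matrix; probe-to-parcel processing and donor aggregation are upstream
  concerns.
- CCA at large k without regularization can overfit; the ridge flag
  exists, defaults to 0 to match the reference procedure, and sensible k
  for synthetic studies is far below the matrix rank.
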