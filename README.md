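# psylink

Receptor-experience factor analysis: linking the words people use to
describe psychoactive drug experiences to the receptor pharmacology of the
drugs they took, and mapping the resulting factors onto the brain through
regional receptor gene transcription.

## The problem

Different hallucinogenic drugs bind different constellations of
neurotransmitter receptors — serotonin, dopamine, adrenergic, opioid,
muscarinic and histamine receptors, monoamine transporters, the NMDA
receptor — and people describe the resulting experiences in free text.
`psylink` implements a doubly multivariate pipeline that asks: which
patterns of word usage co-vary with which patterns of receptor binding
affinity, across thousands of reports and dozens of drugs?

The pipeline, for a corpus of reports each tagged with one drug:

1. **Bag of words + tf-idf.** Reports are tokenized (alphabetic runs,
   lowercased), filtered (length ≥ 3, corpus count ≥ 7, function-word and
   drug-name stoplist) into a sparse testimonial × word matrix *M*,
   reweighted entry-wise by

   tfidf(wᵢ, tⱼ) = [ f(wᵢ,tⱼ) / Σₖ f(wₖ,tⱼ) ] · log( |testimonials| / (1 + n_wᵢ) )

   where n_w counts the *documents* containing w.
2. **Latent semantic analysis.** A truncated SVD M ≈ T R Wᵀ gives each
   report k semantic coordinates X = T·diag(R).
3. **Receptor fingerprints.** Each drug's binding profile (Ki in nM over a
   40-target panel) is potency-normalized: pKi = −log₁₀ Ki (molar),
   npKi = 4 + pKi − pKiMax, with missing or weak (> 10 µM) entries at 0.
   Every report inherits its drug's fingerprint, giving Y.
4. **Canonical correlation analysis.** Paired projections U = Xa, V = Yb
   maximize ρ = corr(U, V), factor by mutually uncorrelated factor.
5. **Permutation inference.** Rows of Y are shuffled testimonial-wise
   (1000 iterations); the null distribution of the *maximum* canonical
   correlation gives family-wise-corrected p-values, and the significant
   factors are retained.
6. **Anatomical mapping.** Each factor's receptor vector b is projected
   onto a region × receptor gene-transcription table (z-scored, shifted to
   a zero minimum): genetic_factor_expression = transcription · b, with
   factor signs anchored so the pole expressed in visual-cortex regions is
   positive.

Because the original report corpus is not redistributable, the package
ships a synthetic study generator that plants known canonical correlations
between semantic topics and receptor fingerprints, with the ground truth
recorded — every stage is testable end to end, offline.

## Worked example

```python
import numpy as np
import psylink as pl

spec = pl.SyntheticCorpusSpec(n_drugs=27, n_reports_per_drug=200, seed=1)
panel = pl.generate_drug_panel(spec)
reports, truth = pl.generate_corpus(panel, spec, planted_rho=(0.8, 0.6))
result = pl.fit_pipeline(
    reports, panel,
    pl.PipelineConfig(k=50, per_drug=None, n_perm=1000, seed=1),
)
print(f"LSA variance at k=50: {result.lsa.explained_variance_fraction():.1%}")
for i in range(4):
    print(f"factor {i+1}: rho = {result.model.rho[i]:.3f}, "
          f"p = {result.permutation.p_values[i]:.4f}")
r = [abs(np.corrcoef(result.model.b[:, f], truth.true_b[:, f])[0, 1])
     for f in range(2)]
print(f"|r| to planted receptor vectors: {r[0]:.3f}, {r[1]:.3f}")
```

prints

```
LSA variance at k=50: 54.3%
factor 1: rho = 0.743, p = 0.0010
factor 2: rho = 0.576, p = 0.0010
factor 3: rho = 0.159, p = 0.4296
factor 4: rho = 0.145, p = 0.9920
|r| to planted receptor vectors: 0.994, 0.958
```

Exactly the two planted factors come out significant (p = 1/1001, the
permutation floor); their canonical correlations recover the planted
(0.8, 0.6) up to the expected small attenuation from word-count noise, and
the recovered receptor vectors are nearly collinear with the planted ones.
The remaining correlations sit at the overfitting noise floor and are
correctly rejected by the max-statistic test.

The same workflow is available from the shell:

```bash
psylink simulate --seed 1 --out-dir sim
psylink fit --corpus sim/corpus.jsonl --panel sim/panel.csv \
            --k 50 --n-perm 1000 --seed 1 --out-dir fit
psylink map-anatomy --fit-dir fit --expression sim/expression.csv \
            --anchors sim/anchor_regions.txt --out anatomy.tsv
psylink report --fit-dir fit --panel sim/panel.csv --out-dir reports
```

Packaged resources: the 40-target receptor panel, the 27-drug overview
table (testimonial counts and typical durations), and a function-word
stoplist. See `docs/methods.md` for the model conventions, the synthetic
generator's design, and known limitations.

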