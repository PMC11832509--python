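# sembeddings

Pre-data-collection screening of questionnaire measurement models from the
cosine similarities of item embeddings.

## The problem

Validating a new questionnaire is expensive: items are drafted, data are
collected from hundreds or thousands of respondents, a confirmatory factor
analysis (CFA) is fitted, and — quite often — the model does not fit, items
must be rewritten, and the collection has to be repeated. Sentence-embedding
models offer a shortcut for the *screening* part of this loop: embed each
item's text, compute the cosine similarity between every pair of items, and
treat the resulting matrix as a stand-in for the empirical item correlation
matrix. Any covariance-structure analysis that runs on a correlation matrix
can then be run *before a single respondent is recruited*: CFAs per scale,
fit indices, and modification indices that point at redundant item pairs.

`sembeddings` implements this workflow end to end for psychometricians and
scale developers:

- **I/O** for item tables, embedding matrices and labelled square matrices
  (plain CSV, item order preserved everywhere);
- a **cosine-similarity** step with a descriptive cross-loading screen
  (items more similar to a foreign scale than their own);
- a **maximum-likelihood CFA engine** for correlation-scale matrices with a
  nominal ("pseudo") sample size, fit indices, Heywood handling, and both
  score-based and refit-based **modification indices**;
- the two **validation batteries**: a unidimensional CFA per scale, and a
  deliberately misspecified single-factor model for every pair of scales;
- **comparison statistics** between similarity-derived and empirical
  results (lower-triangle correlation, per-index medians / correlations /
  absolute differences);
- a **synthetic-data module** that generates instruments with known factor
  structure, Likert response samples, and noisy "pseudo-similarity" proxies
  of controllable fidelity, so the whole pipeline is testable offline.

## The model

Each scale is modelled as a single-factor CFA. For items
$y_1,\dots,y_p$ with loadings $\Lambda$, factor correlations $\Phi$
(variances fixed to 1) and residual covariance $\Theta$:

$$\Sigma(\theta) = \Lambda \Phi \Lambda^\top + \Theta .$$

Given a unit-diagonal similarity matrix $S$ treated as a correlation matrix
observed on a pseudo-sample of size $N$ (default $N = 10{,}000$), parameters
minimize the ML discrepancy

$$F_{\mathrm{ML}} = \ln|\Sigma| - \ln|S| + \mathrm{tr}(S\Sigma^{-1}) - p,$$

giving $T = (N-1)F_{\mathrm{ML}}$ with $df = p(p+1)/2 - q$ free parameters
$q$. Fit is summarized by CFI, TLI (vs. an independence baseline fitted by
the same engine), RMSEA and SRMR; a model is declared a **misfit** when two
or more indices are poor (CFI or TLI < 0.90, SRMR or RMSEA > 0.08 by
default). Modification indices — the approximate $\chi^2$ gain from freeing
one fixed residual covariance or cross-loading — are available both as
expected-information score statistics and as exact refit differences.

## Worked example

Build a 4-scale instrument whose first scale hides two redundant item
pairs, degrade its population correlation matrix into a proxy with
agreement 0.9 (emulating an imperfect embedding model), and screen it:

```python
import sembeddings as se

sim = se.make_instrument(
    4, 4, loading_range=(0.5, 0.7),
    injected_pairs=[("s01_i1", "s01_i2", 0.25), ("s01_i3", "s01_i4", 0.25)],
    seed=42,
)
proxy = se.pseudo_similarity(sim.population_R, target_agreement=0.9, seed=42)
print(f"proxy agreement with population: {proxy.achieved_agreement:.3f}")
results = se.unidimensional_screen(proxy.matrix, sim.item_set)
print(se.screen_report(results, sim.item_set))
```

Output (abridged):

```
proxy agreement with population: 0.907
== s01: MISFIT ==
   CFI=0.686 TLI=0.057 SRMR=0.112 RMSEA=0.493 chisq=4857.62 df=2
   top modification indices:
     #1 MI=2672.84 residual s01_i2 ~~ s01_i4
        s01_i2: "People who know me say I take initiative about daily routines."
        s01_i4: "Even under pressure, I usually keep my word in matters of daily routines."
     ...
== s02: ADEQUATE ==
   CFI=0.989 TLI=0.968 SRMR=0.018 RMSEA=0.067 chisq=91.69 df=2
```

The corrupted scale is flagged as a misfit and its top modification indices
name the residual pairs (for four indicators, a residual pair and its
complement are equivalent models, hence tied MI values) — exactly the
information a developer needs to rewrite or drop items before collecting
data. The clean scales pass.

The same workflow is available from the shell:

```bash
sembeddings simulate --scales 24 --seed 1 --out simdir/
sembeddings screen  --matrix simdir/pseudo_sim.csv --items simdir/items.csv
sembeddings battery --matrix simdir/pseudo_sim.csv --items simdir/items.csv
sembeddings run --config run.yaml   # full pipeline with an output manifest
```

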