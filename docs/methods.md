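# Methods

This note documents the statistical machinery behind `sembeddings`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Similarity matrices as pseudo-correlations

The package takes the cosine-similarity matrix of item embeddings at face
value as a correlation matrix: unit diagonal, entries in [−1, 1], and — as
the Gram matrix of unit-normalized vectors — positive semidefinite by
construction. No Fisher transform or rescaling is applied, and negative
similarities are kept (CFA handles negative correlations). Embedding
models fine-tuned to predict item correlations produce similarities on the
correlation scale already; for other models the matrix is still a valid
input, only its calibration differs. Embedding computation itself sits
behind a provider contract (`embed_items(item_set, provider)`); the test
suite uses deterministic mock providers, and network-backed providers are
deliberately out of test scope.

The descriptive cross-loading screen flags an item whose mean similarity to
some foreign scale (mean over that scale's items) is at least its mean
similarity to its own scale mates (excluding itself). Ties between foreign
scales resolve to the earlier scale in instrument order, making reports
deterministic.

## CFA on a correlation-scale matrix

The measurement model is Σ(θ) = ΛΦΛᵀ + Θ with:

- factor variances fixed to 1 and **all loadings free** (identification by
  standardized factors rather than marker items — the natural convention
  when the input is on the correlation scale);
- free factor correlations, bounded in (−0.995, 0.995);
- free residual variances, box-bounded below at 1e−4; optionally freed
  residual covariances.

Because the matrix was not estimated from respondents, a nominal pseudo
sample size N (default 10,000) supplies the scale for χ²-based statistics:
T = (N−1)·F_ML. N only rescales T; judgements should read indices
continuously rather than as hypothesis tests.

**Optimization.** Newton-type iterations with analytic derivatives:
the general path uses Fisher scoring on the expected information
H_ts = tr(Σ⁻¹ ∂ₜΣ Σ⁻¹ ∂ₛΣ); the single-factor path (the workhorse for
screens and batteries) uses closed-form gradient and *observed* Hessian,
falling back to the expected information when the observed Hessian is not
positive definite. Steps are damped by halving against the discrepancy;
if scoring stalls (40 iterations) an L-BFGS-B fallback with the same
analytic gradient finishes the job. Convergence requires a projected
gradient below 1e−7 (projection accounts for active bounds). Start values:
λ = √(mean within-factor correlation), θ = 1 − λ², φ = 0.

**Degenerate inputs.** If the input matrix has an eigenvalue below 1e−8
(e.g. near-duplicate items), a diagonal ridge is added and the matrix
renormalized to unit diagonal; the applied delta is reported on the fit.
Residual variances that land on the 1e−4 bound are reported as Heywood
items; fits are returned (flagged), never aborted, because badly
misspecified models must still yield indices.

**Baseline and indices.** The independence baseline (Σ_b = diag of free
variances) is fitted by the same engine — started at its closed-form
optimum diag(S) — so T_b is internally consistent. Indices:

- CFI = 1 − max(T−df, 0) / max(T_b−df_b, T−df, 0), clamped to [0, 1] by
  construction;
- TLI = ((T_b/df_b) − (T/df)) / ((T_b/df_b) − 1), deliberately uncapped
  (it may exceed 1 or go negative);
- RMSEA = √(max(T−df, 0) / (df·(N−1)));
- SRMR = root mean square of the standardized residuals over the
  p(p+1)/2 unique entries **including the diagonal**. SRMR variants differ
  across software; the diagonal-inclusive form is fixed here so that all
  published numbers from this package are exactly defined. For
  unit-diagonal input with free residual variances the diagonal residuals
  are near zero, so the variant choice moves SRMR only in the third
  decimal.

TLI and RMSEA are undefined at df = 0 and reported as NaN, not 0; the
misfit rule then counts them as not-poor and flags them as not-applicable.

**Misfit rule.** A model is a misfit when at least two of the four indices
are poor (CFI, TLI < 0.90; SRMR, RMSEA > 0.08 by default; both cutoffs
configurable). This is a descriptive screening rule, not a test.

## Modification indices

Candidates are all fixed-to-zero residual covariances, plus cross-loadings
in multi-factor models. Two routes:

- **refit**: free the candidate, refit, report the exact χ² drop. Slow but
  definitionally correct; non-convergent refits are flagged in the table
  rather than dropped.
- **score**: the expected-information score (Lagrange-multiplier)
  statistic MI = (N−1)·g_c² / (2·h̃_c), where g_c is the discrepancy
  gradient in the candidate direction at the restricted optimum and h̃_c
  the expected Hessian of F after concentrating out the free parameters
  (Schur complement). It converges to the refit value as the freed
  parameter's true value shrinks; on synthetic misfits with injected
  residual correlations around 0.1 the two agree within ~10%, with the
  score form biased slightly upward for larger misspecifications. The
  observed-information variant was evaluated and tracks the refit value
  *worse* on these problems, so the expected form is used.

No multiple-testing correction is applied: MIs are ranked descriptively
and reported with verbatim item texts so a researcher can judge whether a
suggestion is substantively meaningful.

A structural caveat for four-indicator scales: freeing a residual pair and
freeing its complementary pair are equivalent models, so their MIs tie
exactly. Reports therefore surface the whole tied set; tests and the
acceptance script treat "recovered" as the injected pair sitting at the
tied top value (five-indicator constructions are used where a unique top
is needed).

## Screening batteries

- **Unidimensional screen**: one single-factor CFA per scale on that
  scale's submatrix; scales with fewer than three items are skipped with a
  warning. MI tables (with item texts) are attached to misfitting scales.
- **Wrong-model battery**: for every unordered pair of scales, one single
  factor forced over both scales' items — k(k−1)/2 models, 276 for 24
  scales. These models are wrong by construction whenever the scales are
  distinct, so the battery measures the screen's sensitivity to
  misspecification. When two scales share a factor (φ = 1) the pair model
  is correct and fits perfectly; fit degrades monotonically as φ falls.
- **Battery summary**: per-index min/max, the fraction of models with
  SRMR under the cutoff, and the misfit fraction; non-convergent fits
  count as misfits (conservative) and are reported separately.

## Comparison statistics

Agreement between a similarity-derived matrix and an empirical one is the
Pearson correlation of the p(p−1)/2 lower-triangle entries (Spearman
available as an option). Matched lists of fits are compared per index by
medians with SDs, cross-method Pearson correlation, and median / SD / max
absolute differences; signed differences follow the convention
first-list-minus-second-list (similarity minus empirical).

## Synthetic data

`make_instrument` builds a multi-scale instrument with one factor per
scale: loadings uniform on (0.5, 0.85) by default — the typical range for
reasonably written items — four items per scale, and factor correlations
drawn through a single higher-order dimension (Φ_ab = √(u_a·u_b), u
uniform on the requested range). The higher-order construction keeps every
pairwise factor correlation inside the requested range while guaranteeing
Φ is positive semidefinite for any number of scales, which independent
uniform draws would not. Injected residual correlations model
redundant-wording pairs; they must leave Θ positive semidefinite or the
generator refuses. Item texts are template-generated English sentences —
enough to exercise reporting, with no claim of semantic realism.

`sample_responses` draws multivariate-normal latent scores with the
population correlation and, for 5-point Likert output, discretizes at
equal-probability quintile cuts of the standard normal (a symmetric
default; custom thresholds accepted).

`pseudo_similarity` emulates an imperfect embedding model: seeded Gaussian
noise is added to the off-diagonal, with the noise scale tuned by a secant
search so that the lower-triangle correlation between the *final* matrix
and the truth lands within 0.03 of the requested fidelity. The final
matrix is the unit-diagonal PSD projection (eigenvalue clipping plus
renormalization) of the noisy one; tuning on the post-projection agreement
matters because clipping removes part of the noise and would otherwise
bias fidelity upward. Additive Gaussian noise is the simplest model with a
controllable agreement knob; real embedding error is surely structured
(e.g. inflated similarity for shared surface wording), so fidelity, not
noise shape, is the claim being modelled.

`verdict_agreement_experiment` cross-classifies screen verdicts on
replicated pseudo-similarity draws against verdicts on the population
truth. At fidelity 1.0 the verdicts coincide exactly; observed
disagreement shrinks as fidelity rises. On the default experiment (8
scales, 3 corrupted, 50 replications) false-adequate calls — a corrupted
scale passing on the proxy — are rare to absent, while false-misfit calls
dominate the disagreement: the proxy errs on the conservative side.

## Problem sizes and limitations

Test and acceptance runs use instruments up to 24 scales × 4 items
(96 items, 276 battery models — a few hundred milliseconds end to end)
and 50-replication fidelity experiments on 8-scale instruments; these
sizes make every experiment exact enough to be assertable while keeping
the full suite in seconds.

What the synthetic experiments show: the engine is exact on population
matrices, agrees with an independent ML factor-analysis implementation on
noisy matrices, and the screening logic behaves monotonically in proxy
fidelity. What they cannot show: that any particular embedding model
reaches a given fidelity on real items, how semantic similarity mis-tracks
response-driven correlations (method variance, acquiescence, genuinely
non-semantic covariation), or how the procedure behaves for scales much
longer than the 3–8-item range exercised here. Robust/categorical
estimators (e.g. WLSMV, polychoric input), standard errors, and
multi-group invariance are out of scope.
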