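# Methods

This note documents the statistical models implemented in `mirtarget`, the
parameters that matter, the numerical conventions, and what the synthetic
fixtures do and do not establish about real data.

## Setting and assumptions

All three analyses assume *matched* profiling: the miRNA and mRNA matrices
cover the same biological samples, aligned by sample id (intersection, in
miRNA-matrix order, at least three shared samples). Expression values are
non-negative and carry a declared unit (counts, CPM, TPM or RPKM); fold
changes are log2-scale outputs of an upstream differential-expression tool —
the package deliberately does not compute fold changes itself, so any DE
method (DESeq2, edgeR, limma, microarray pipelines) can feed Parts 2 and 3.
Candidate pairs may be the full miRNA × mRNA cross product or the subset
present in a sequence-based prediction table; ids are matched
case-sensitively with no namespace mapping.

## Part 1: per-pair regression with AIC family selection

For each pair, mRNA expression Y is regressed on one miRNA predictor
(univariate), two (multivariate), or two plus their product (interaction).
Predictors are the miRNA values multiplied by `scale` (default 1.0; useful
for TPM/RPKM inputs where rescaling, e.g. ×10, puts coefficients on a
readable scale — `scale` commutes exactly with rescaling the input, so
inference is unchanged).

Families and links:

| family | response | mean link | extra free parameters |
|---|---|---|---|
| gaussian | continuous | identity | σ |
| poisson | counts | log | — |
| negative_binomial | counts (NB2) | log | dispersion α |
| zero_inflated_poisson | counts | log | inflation logit constant |
| zero_inflated_negative_binomial | counts | log | α + inflation constant |

Zero inflation is a constant (logit-linked) structural-zero probability, not
regressed on the miRNA — the smallest model that accommodates excess zeros;
extending the inflation design is a one-line change at the fit site. The NB
dispersion is estimated by maximum likelihood jointly with the mean, so it
is counted in k. Count families require integer responses and refuse
non-integer input (no silent rounding corrupting likelihoods); an explicit
`round_counts` escape hatch exists for near-integer matrices.

AIC is computed as 2k − 2 ln L with k the full free-parameter count,
including the Gaussian σ. Library defaults (statsmodels OLS) omit σ from k,
which would bias comparisons against the ML count families; computing AIC
explicitly keeps all five families on one scale. `family="auto"` fits every
applicable family (count families are skipped for non-integer responses) and
keeps the converged fit with the smallest AIC, ties broken simplest-first
(gaussian < poisson < NB < ZIP < ZINB) for determinism.

Coefficient p-values are Wald tests (t for Gaussian, z for ML fits) on the
coefficient of interest — β₁ for univariate/multivariate, β₃ for interaction;
a likelihood-ratio alternative is available via `pvalue_method="lrt"`.
Benjamini–Hochberg adjustment is applied once across all pairs in a run, the
standard transcriptome-wide convention. A pair is reported significant when
it converged, its adjusted p is below α, and the coefficient's sign matches
the requested direction (`negative` for canonical repression, `positive` for
sponge-like relationships, `both`). The reported R² is the squared Pearson
correlation between fitted and observed response — not the Gaussian
variance-explained decomposition, but the one definition that is comparable
across all five families.

Degenerate inputs: a constant predictor or constant response yields a
flagged fit with the non-intercept coefficients exactly zero, p-values 1 and
AIC = +∞ (so auto-selection never prefers it); a non-converged fit is
flagged and excluded from BH; per-pair failures never abort a batch.

## Parts 2 and 3: resampled background nulls

Both fold-change analyses compare an observed statistic against a background
of randomly drawn cross-pairs from the same tables ("random miRNA against
random mRNA"), with add-one rank p-values: p = (1 + #{null at least as
extreme}) / (n_perm + 1). The add-one correction makes p = 0 impossible; the
attainable floor is 1/(n_perm + 1), so n_perm bounds the resolution of small
p-values. The CLI default n_perm = 100 is cheap and adequate for screening;
≥ 1000 is recommended whenever BH-adjusted tail decisions matter.

Part 2 requires at least three comparison columns and skips pairs with a
constant vector (correlation undefined; skipped pairs are logged, not
dropped silently). The default alternative is `negative` (repression);
`positive` and `two_sided` are exposed. Part 3 requires exactly one
comparison column; multiple intervals are separate runs. The Part 3
regulation class is a pure sign-pattern function of the two fold changes,
reported alongside the p-value, never folded into it — divergent and
coregulated pairs can both be significant. `zero_tol` (default 0) maps
|log2FC| at or below the tolerance to "no change", for shrunken-FC inputs
where tiny non-zero estimates are noise. Because published usage of the
labels "inverse" vs "negative" regulation is inconsistent, the enum is
sign-descriptive (`mirna_up_mrna_down`, …) and display labels are a
configurable serialization mapping (`DISPLAY_LABELS`).

**Null construction (design choice).** Two modes exist. `per_pair` (default)
draws a fresh n_perm-sized cross-pair null for every tested pair, at
O(n_pairs × n_perm) vectorized cost. `shared` reuses one null for the whole
run, at O(n_perm) cost. The shared mode is the cheaper, historically common
construction, but all its p-values inherit the *same* realization of null
sampling error: across a run they are positively dependent, and with m pairs
≫ n_perm the empirical p distribution under a global null deviates from
uniform by roughly 0.87/√n_perm in sup norm — enough to fail a
Kolmogorov–Smirnov uniformity check at conventional sizes (n_perm = 200,
m = 2000). Per-pair nulls make global-null p-values independent and
uniform, which is what BH's guarantees are usually stated for; hence the
default. For very large candidate sets (millions of pairs) `shared` remains
available and its BH-significant fraction is still controlled, only the
joint uniformity is lost.

## Prediction-table filtering

miRanda-style tables carry one row per (miRNA, gene) pair after
canonicalization: duplicate rows (multiple predicted sites) collapse to the
maximum score, the deterministic "best site" convention. Filtering is either
an inclusive absolute floor (`min_score`, e.g. 140) or a strict percentile
cutoff (`percentile`, e.g. 99 — keep strictly above the 99th percentile of
all scores in the table, linear-interpolation percentile over the full score
vector, duplicates included). Positive folding energies are physically
implausible and warn but are kept — the score column, not energy, drives
filtering. TargetScan tables are adapted by mapping the context score
percentile (0–100) into the score column.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their seed (no global RNG state).

*Paired matrices* (Part 1 fixtures): miRNA baselines are log-normal
(meanlog 3, sdlog 1), mimicking the right-skewed scale heterogeneity of
CPM/TPM data; count-family matrices are integer-rounded. A planted pair
generates its mRNA through the family's canonical link with the stated
coefficients; for Gaussian plantings the default intercept is raised until
the noiseless response is comfortably positive, preserving the
non-negativity invariant without truncation bias on the slope. Background
mRNAs are independent of every miRNA. Zero-inflated fixtures default to a
structural-zero probability of 0.3, large enough that ZI families are
AIC-distinguishable from their non-inflated counterparts at n = 100.

*Fold-change tables* (Parts 2–3): background features are i.i.d. normal with
sd 0.5 — the bulk of moderated/shrunken log2FC estimates concentrates near
zero; strongly differential features enter as planted effects. Planted
correlations are constructed exactly (the mRNA vector is a linear
combination of the standardized miRNA vector and an orthogonalized noise
vector, so the realized sample r equals the target to machine precision).
Planted differences split the divergence symmetrically (miRNA at +d/2, mRNA
at −d/2 around a common base), so no single planted row dominates the
resampled null on its own.

*Prediction tables*: planted pairs receive scores uniform in [140, 189], the
span observed for real miRanda totals in matched-expression studies; decoy
records added by the `simulate` command pair *background* features only, so
every decoy is a true null and empirical FDR against the truth table is a
fair measurement.

Default fixture scales (e.g. 50 planted pairs among 50 decoys; Part 2 over
six comparison columns; Part 3 tables of 200 × 1000 features) come from two
design considerations. First, granularity: empirical FDR from a single run
is FP/(TP+FP), so with only ~10 true positives one chance false discovery
already shifts it by ~0.1; 50 planted pairs make the single-run FDR a
meaningful estimate of the quantity BH controls. Second, null contamination:
planted rows participate in the resampled background, so planted effects
must be sparse relative to background features — at the default scales a
random cross-pair hits two planted features with probability ≤ 2.5 × 10⁻³.
Six comparisons for Part 2 reflect the resolution limit of correlations on
very short vectors: at three comparisons the null distribution of the sample
correlation is so heavy-tailed (arcsine-law-like) that |r| ≥ 0.99 occurs in
~4.5% of random pairs, and no method can separate planted near-perfect
correlations from that background; at six comparisons the same event has
probability ~5 × 10⁻⁵.

What passing these fixtures does **not** show: real libraries have
library-size and batch effects, count overdispersion that varies across
genes, correlated co-expression modules (the generators draw background
features independently), and fold-change estimates whose errors correlate
across comparisons. Recovery rates on fixtures are upper bounds on real
sensitivity, and the type-I calibration holds for the permutation machinery
itself, not for misspecified upstream fold changes.

## Numerical conventions

- ML fits are capped at 200 iterations; a non-converged or non-finite fit is
  flagged, never silently reported.
- AIC ties break by fixed family order, simplest first.
- Result TSVs serialize numerics at 10 significant digits (lossless round
  trip for every statistic the package reports; exact values like p = 1
  serialize without noise).
- Output tables sort by adjusted p, then raw p, then ids — stable and
  deterministic.
- Every run is reproducible from its emitted `run_config.yaml`: all
  randomness flows from explicit integer seeds, and re-running a subcommand
  from its config reproduces output tables byte for byte.

## Known limitations

- Zero-inflation is intercept-only; inflation covariates are an extension
  point.
- Multivariate/interaction designs take exactly two miRNA predictors; larger
  covariate sets (and sparse partial-correlation approaches such as
  elastic-net co-expression models) are out of scope, as is spline-based
  longitudinal modelling.
- The package never computes differential expression; garbage fold changes
  in, garbage interrelations out.
- Wald p-values can be anti-conservative in far tails when the family is
  misspecified for heavy-tailed expression data (e.g. Gaussian fits on raw
  log-normal-like responses at moderate n); the `auto` family and the `lrt`
  option mitigate but do not remove this.
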