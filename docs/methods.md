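# Methods

## Model and test

Each gene is tested as a unit. Sample *k*'s burden score is the weighted
dosage sum `S_k = Σ_i s_i x_ik` over the gene's variants. The test
dichotomizes the scores at a threshold *t* and compares the exceedance
proportions of cases and controls through a Bernoulli likelihood ratio:
the numerator fits separate case and control proportions (`p̂_A`,
`p̂_U`, the MLEs), the denominator pools them (`p̂`). Natural logarithms
are used throughout, with the convention `0·log 0 = 0` applied factor by
factor. The statistic is maximized over the grid of unique observed
score values; "exceeds" is strict (`score > t`), so every threshold
between consecutive unique values is equivalent to a grid member, and
the all-exceed configuration (any *t* below the minimum) gives Λ = 0
because numerator and denominator coincide. Ties in the maximum are
broken toward the smallest threshold, for determinism. Because
significance is assessed purely by permutation of the same statistic,
the log base and any monotone rescaling of the scores are inert; only
the score ordering matters (a tested invariant).

### Statistic modes

Three forms of the statistic are implemented:

- **plain** — the likelihood ratio above, at every grid point. It is
  nonnegative, zero exactly when `T_A/m = T_U/l`, and symmetric under
  swapping the case and control roles, so it measures *unevenness* of
  the score distributions in either direction.
- **symmetric** — an alias of the plain form used with weighted scores;
  named separately so configurations are explicit about the choice
  below.
- **direction-adjusted** — when `p̂_A ≤ p̂_U` the numerator is evaluated
  with the two group estimates swapped (case counts under `p̂_U`,
  control counts under `p̂_A`). Since the swapped values are not the
  MLEs, this branch is ≤ the plain value and ≤ 0, so it actively
  penalizes control-side enrichment rather than rewarding it; a strictly
  positive count under a zero swapped estimate evaluates to −∞, which is
  representable and simply never wins the maximization.

The direction weights give `s_i = +1` when a variant's minor-allele
frequency in cases is at most its frequency in controls (ties, including
monomorphic variants, fall in the `+1` branch) and `−1` otherwise. This
convention orients every aligned effect toward *low* case scores. As a
consequence, combining it with the direction-adjusted statistic would
park all true signal on the penalized branch and leave the test with no
power — the two conventions are individually sensible but mutually
incompatible. The package therefore defaults LRT-DIR and LRT-BS to the
symmetric statistic, which scores the same departure regardless of which
side it lands on, and keeps the direction-adjusted form available via
`mode="direction-adjusted"` for users who specifically want one-sided
(case-enrichment) behavior with case-oriented weights. LRT-BS uses
annotation magnitudes only; an optional flag
(`bs_combine_direction=True`) compounds the per-replicate direction sign
onto the magnitudes, off by default.

The per-variant frequency reading of the direction rule is itself a
choice: the sign is indexed per variant and must be computable before
any burden score exists, so variant-level allele frequencies
(allele count / 2·group size) are used rather than gene-level exceedance
proportions.

## Permutation p-values

Significance is by gene-specific permutation of the case/control labels
over all samples, which preserves the linkage structure among a gene's
variants and is robust to departures from the Bernoulli model
(heterogeneous gene sizes, allele frequencies, dependence among
variants). Every replicate re-runs the full pipeline on the permuted
labels: threshold maximization is redone, and for LRT-DIR the direction
signs are recomputed from the permuted labels. Freezing the observed
signs would be anti-conservative — the signs are chosen to make the
observed labeling look extreme — and the test suite contains a
regression contrast demonstrating exactly that failure mode.

The p-value uses the add-one estimator `(1 + #{Λ_perm ≥ Λ_obs})/(1+B)`,
which is valid (never anti-conservative) at any B; ties count toward the
numerator, with a 1e−9 floating-point slop treated as a tie. To bound
the cost over thousands of genes, permutation is two-stage: after `B1`
replicates (default 1,000) the loop continues to `B2` total (default
10,000) only if the interim p-value is below the gate (default 0.1).
Stage-1 replicates are the prefix of the stage-2 stream, so a gene that
passes the gate reports exactly the single-stage p-value at `B2`. With
the defaults the smallest attainable p-value is 1/10001 ≈ 1.0e−4.
Per-gene seeds are derived by hashing the master seed with the gene
symbol, making results independent of processing order and giving every
method — including the comparators — the identical permutation stream
for a given gene and seed. For cohorts small enough to enumerate, an
`exact=True` mode replaces sampling with exhaustive enumeration of all
distinct label assignments.

Degenerate genes (constant scores under every labeling) report p = 1
with a flag, without spending replicates.

## Comparators

**CMC**: variants with sample MAF below a cutoff (default 1%,
flag-controlled; the value is a convention of the collapsing literature)
are pooled into a carrier indicator; commoner variants keep individual
dosage columns; constant columns are dropped. The statistic is
Hotelling's T² between case and control mean vectors with the pooled
within-group covariance (computed from the fixed total second moment, so
permutations only require group means). A singular covariance with a
mean difference outside its column space — perfect separation — is
scored +∞, which permutes correctly as a maximal tie. The p-value is by
the shared permutation engine, keeping all five methods on one
null-calibration footing.

**C-alpha**: with `n_i` minor-allele copies of variant *i* overall and
`y_i` in cases, `p0 = m/(m+l)`,
`T = Σ_i [(y_i − n_i p0)² − n_i p0(1−p0)]` measures over-dispersion of
the case/control allele split and is sensitive to mixed-direction
effects. The binomial variance normalizer `c` (grouped over distinct
copy totals) and `Z = T/√c` are computed, and the one-sided normal
p-value is attached for reference, but the primary p-value is
permutation-based: the binomial variance model treats the `n_i` copies
as independent Bernoulli draws, which label permutation does not (a
dosage-2 carrier moves two copies together, and the finite population
shrinks the variance), so the normal approximation is reported, never
used for ranking.

## Input handling

Genotypes are read from VCF v4.x (GT fields only; multi-allelic records
split into one column per alternate allele; half-calls and `./.` are
missing) or from a TSV matrix dialect (`variant_id chrom pos ref alt
gene` + one column per sample, cells `0/1/2/.`) that round-trips
exactly. Dosages always count the minor allele: columns whose alt
frequency exceeds 0.5 are flipped (`x → 2−x`) on read, with the flip
list logged. Gene assignment is consumed as input (TSV column, VCF INFO
tag, or an external map), never computed. Missing genotypes are resolved
when gene units are built: the default `as-ref` policy sets them to zero
minor alleles, which is conservative for burden scores and keeps
unit-weight scores integer-valued; `mean-impute` substitutes the
per-variant observed mean. Samples present on only one side of the
genotype/phenotype join are dropped with a logged count, never imputed.
Case status is read directly (0/1) or derived from blood pressure as
SBP ≥ 140 or DBP ≥ 90.

## Synthetic cohorts

The simulator emulates a modest exome case-control cohort. Per variant,
a MAF is drawn from Beta(0.5, 8) truncated to (0.001, 0.05) — a
rare-variant spectrum with most mass below 2% — and dosages are
Binomial(2, MAF), i.e. Hardy–Weinberg with linkage equilibrium between
variants. Disease status is Bernoulli with
`logit P = intercept + Σ β_i x_i` over the causal variants; the default
intercept −1.56 puts the baseline case fraction near 17%, typical of a
hypertension-style dichotomized cohort. Gene archetypes fix per-causal
effects at β = −ln 3 (strong protective), +ln 1.3 (weak), +ln 3 (strong
deleterious) or none (null); explicit per-variant β vectors express
mixed-direction genes. To emulate incomplete functional annotation, only
the first `n_annotated` (default 10) causal variants by position are
labeled `functional` in the emitted annotation table; everything else is
`rest`. The weight-scheme grid pairs functional weights {2, 5, 10} with
rest weights {1, −1} plus an unweighted baseline.

What the simulator does *not* model: linkage disequilibrium between
variants (real exomes have LD, which the permutation test accommodates
but the generator does not produce), population structure, relatedness,
covariates, genotyping error, or longitudinal phenotype structure.
Passing power and calibration results on these cohorts therefore
demonstrate the statistical machinery under idealized sampling, not
robustness to those real-data complications.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use desk-scale versions of
the studies: calibration uses 200–400 null genes of 10 variants in
1,000-sample cohorts with B1 = 200 / B2 = 999 (type-I error at α = 0.05
checked against the exact binomial 99% band); power contrasts use
800-sample cohorts and 100 replicates. Exhaustive checks of the
statistic run over all count configurations with m, l ≤ 8 against an
independent direct-substitution oracle at 1e−12; permutation exactness
is verified against brute-force enumeration on ≤ 8-sample cohorts.
Typical measured values at these sizes: type-I error 0.03–0.07 for every
method, null λ ≈ 0.8–1.0, plain-LRT power ≈ 0.2–0.4 on a balanced
5-protective/5-deleterious gene versus ≈ 0.95 for LRT-DIR, and the
(10, 1) annotation scheme at or above the unweighted test on a fully
annotated deleterious gene.

Other fixed conventions: competition ranks with ties sharing the
minimum rank (so several genes can all be rank 1 at the permutation
floor); genomic inflation by the median-χ²₁ definition
`λ = median(χ²_obs)/0.4549` (a regression-based λ would differ
slightly); the top-gene report defaults to the p ≤ 1.55e−4 cutoff with
nesting under cutoff growth; QQ expected quantiles `(i−0.5)/G`. The
permutation tie slop (1e−9), the threshold tie-break, and the add-one
estimator are all deliberately conservative choices.

## Known limitations

- The direction-adjusted statistic is one-sided by construction and
  incompatible with the default direction-weight orientation (see
  above); it is provided for completeness and explicit opt-in.
- P-value resolution is bounded by 1/(1+B2); genes at the floor tie at
  rank 1.
- No covariate adjustment and no quantitative-trait likelihood; the
  framework is case/control only.
- CMC is realized as Hotelling's T² with permutation p-values; the
  original's asymptotic variants are out of scope.
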