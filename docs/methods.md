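# Methods

## Model

A basket dataset is n samples; each sample carries a set of items.  For
gene expression, the items are (gene, level) pairs with level in
{−1, 0, +1}, plus one phenotype class per sample.  A rule A → B has

* support s = n_AB/n, the joint frequency of antecedent and consequent;
* confidence c = n_AB/n_A, the frequency of the consequent among samples
  matching the antecedent (undefined when n_A = 0).

Under the null hypothesis that antecedent and consequent occur
independently — indicator of A ~ Bernoulli(p₁), indicator of B ~
Bernoulli(p₂) — the joint indicator is Bernoulli(p₁p₂), so

* n_AB ~ Bin(n, p₁p₂) and the support's one-sided (1−α) upper bound is the
  **minimum support** s_min = p₁p₂ + z_α √(p₁p₂(1−p₁p₂)/n), using the
  normal approximation of the binomial (appropriate for the n of
  expression studies; an exact-binomial-quantile variant is available as
  `minimum_support(..., exact_binomial=True)`);
* the confidence is the ratio C = X/Z with X = #A∩B, Z = #A ~ Bin(n, p₁),
  and X | Z = z ~ Bin(z, p₂) under independence, giving
  P(C = c) = Σ_z Bin(z, cz, p₂) Bin(n, z, p₁).  The variance of C does not
  exist (E(1/Z) diverges), so the **minimum confidence** c_min must be the
  (1−α) upper quantile of this exact discrete distribution, computed
  numerically.

C is defective at Z = 0; the implementation conditions on Z ≥ 1 and
renormalises by 1 − (1−p₁)ⁿ so that a proper distribution is quantiled
(the truncation is numerically negligible except at tiny n·p₁, where it is
exactly what one wants).  p₁ = 0 is rejected as degenerate; p₂ = 0 and
p₂ = 1 short-circuit to c_min = 0 and 1.

A rule is **meaningful** iff support > s_min AND confidence > c_min,
strictly, with the thresholds evaluated at the rule's own estimated
marginals p̂₁ = n_A/n and p̂₂ = n_B/n (the consequent marginal is the class
frequency among all samples).  Strictness matters in discrete small-n
settings: a rule sitting exactly on a threshold does not pass.

### Quantile reporting conventions

The null confidence distribution is discrete on the achievable ratios
x/z, so "the (1−α) upper quantile" needs a reporting convention.  Two are
implemented, and the difference is deliberate:

* **`convention="exact"`** (used per rule during mining): let u be the
  smallest achievable ratio with CDF(u) ≥ 1−α; c_min is the midpoint
  between u and the next achievable ratio.  Strictly exceeding c_min is
  then exactly the event {C > u}, whose null probability is ≤ α — the
  sharpest threshold with a guaranteed type-I bound.  At n = 16,
  p₁ = 0.625, p₂ = 0.5 this gives c_min = (10/13 + 7/9)/2 = 0.7735 at the
  95 % level and (7/10 + 5/7)/2 = 0.707 at 90 %.
* **`convention="grid"`** (default, used for reference tables): achievable
  ratios are binned half-up to the nearest multiple of `grid_step`
  (default 0.001) and c_min is the midpoint between the last grid value
  whose CDF is below 1−α and the first at or above it — hence every
  reported value ends half-way between grid points (…25, …75 at the fourth
  decimal for step 0.001).  This is the convention critical-value tables
  are printed in; it was fixed by calibration, as the only variant among
  the natural candidates (CDF at grid points with and without atom
  rounding) that regenerates all 100 reference cells at n = 1000 exactly.
  At coarse grids it can sit up to half a bin below the exact threshold,
  so its exceedance probability can marginally exceed α; for per-rule
  decisions use `"exact"`.

The exact convention enumerates all ~n²/2 atoms and is capped at
n ≤ 4000; equal ratios (1/3 vs 333/999) are merged by exact integer
arithmetic on gcd-reduced pairs, never by float comparison.  The grid
convention evaluates the rounded-atom CDF directly as
Σ_z w_z · BinCDF(z, ⌊((2k+1)z−1)/2000⌋, p₂) with the Z-range truncated to
Bin(n, p₁) mass above 1e−15, and binary-searches the grid; it is used for
arbitrary n (the n = 10⁵ normal-limit check runs in milliseconds).
CDF comparisons use a 1e−12 tolerance.

### z_α convention

z_α is the one-sided upper standard-normal quantile, full precision by
default (1.6449 at α = 0.05).  `rounded_z=True` uses the 3-decimal tabled
value (1.645) that printed worked examples plug in; at 4-decimal output
the two agree for all documented cases.

### Back-solving the support bound

Setting s_min(p) = s with p = p₁p₂ and squaring gives
(n + z²)p² − (2ns + z²)p + ns² = 0; `back_solve_joint_probability` returns
the smaller root p\* ≤ s (the larger root is an artefact of squaring), and
plugging p\* back into the bound recovers s to < 1e−9.  The discriminant
4nsz²(1−s) + z⁴ is positive for all s ∈ (0, 1), so a real root always
exists.  Use: with a pre-specified support floor s, a consequent with
p̂₂ < p\*/p̂₁ has expected null support so far below s that reaching it has
probability below α; `mine_rules(..., mode="fixed", prune_backsolve=True)`
skips such consequents before counting the joint tally.  This is a
probabilistic speed-up: on null-like data the meaningful rule set is
unchanged (asserted over 100 seeded datasets at n = 200), but a true
association with small marginals sitting exactly at the floor could in
principle be skipped, which is why pruning is off by default and
unavailable in dynamic mode (where no support floor exists).

## Discretisation

Five schemes map expression values to {−1, 0, +1}; each case-study
pipeline is exactly one normalisation followed by one labelling.

| preset | normalisation | labelling | boundaries |
|---|---|---|---|
| `threshold` | MA-plot lowess (two-colour log ratios) | value ≥ +1 → +1, ≤ −1 → −1 | inclusive |
| `fold2` | none | ratio to baseline-group mean > 2 → +1, < 0.5 → −1 | strict |
| `fold1.5` | none | ratio > 1.5 → +1, < 2/3 → −1 | strict |
| `maqc-log` | none (log2 data) | difference to baseline mean > +1 / < −1 | strict |
| `tsd` | per-sample (x − median)/IQR | per-gene z-score, ≥ +1 / ≤ −1 | inclusive |

Choices made where the schemes are conventionally underspecified:

* boundary strictness follows each scheme's own definition (≥/≤ for the
  fixed-cutoff and TSD schemes, >/< for the fold-change schemes) rather
  than being unified;
* the lowess span is 2/3 (the smoother's conventional default), exposed as
  a parameter; lowess is the statsmodels implementation;
* TSD (Transitional State Discrimination) uses the sample (n−1) standard
  deviation, switchable to population sd via `ddof=0`; constant rows
  label 0;
* fold-change baselines are the per-gene mean over the designated baseline
  group; a zero linear-scale baseline is an error by default, or
  label-0-with-warning via `on_zero_baseline="skip"`;
* missing values always label 0 ("not differentially expressed" — level 0
  is read uniformly as that, never as "no expression"), keeping basket
  semantics total.

Every labelling operation is order-preserving within a gene; note the
`tsd` *preset* composes a per-sample normalisation before the per-gene
z-score, and the composition need not preserve within-gene order.

## Mining and screening

Candidates are every (gene, level) → class pair, or every unordered pair
of items over two distinct genes → class for the double-antecedent
analysis (run separately, as is conventional; a sample cannot carry two
levels of one gene).  Levels mined default to {−1, +1}, with 0 optional.
Candidates whose antecedent matches no sample are dropped.  Dynamic
thresholds depend only on (n, n_A, n_B, α) — never on n_AB — and are
cached per margin pair.  No multiple-testing correction is applied, by
design; the miner logs the number of candidates tested so the implied
family-wise error is visible.  Meaningful sets are nested in α.

Screening removes *all* members of a conflicting group (no tie-break):
consequent conflicts (identical antecedent itemset, different consequents)
and level conflicts (same gene at +1 and −1 toward the same consequent,
single-antecedent rules only — interaction rules are exempt, since a gene
can genuinely act in both directions conditional on a partner; level-0
rules conflict with nothing).  Conflicts between a single- and a
double-antecedent rule over overlapping items are not treated as
ambiguous: only identical itemsets conflict.  Screening is idempotent and
never alters a rule's fields beyond the `ambiguous` flag.

## Synthetic data

`simulate_two_group_matrix` draws a log-scale genes × samples matrix:
null genes Normal(0, noise_sd) in both groups, planted genes shifted by
±effect·noise_sd in the case group.  Defaults (100 genes, 8 vs 8 samples,
5 up + 5 down planted, effect 4, noise_sd 1) mirror the small balanced
two-group designs of knockout-style microarray studies.  A linear-scale
variant (100·2^value) exercises the fold-change presets.  The generator is
`numpy.random.default_rng` (PCG64) with explicit seeding; identical seeds
give bitwise-identical matrices.

Deliberately not modelled: probe/dye effects, intensity-dependent
variance, negative-binomial RNA-seq counts, batch structure, correlated
genes.  Passing tests on this generator therefore demonstrate the
statistical machinery (calibration, recovery of clean additive signal),
not robustness to real microarray noise.

`simulate_independent_baskets` draws the antecedent and class indicators
independently — the exact null of the threshold derivation — and backs the
calibration tests: over 50,000 replicates at n = 200, p₁ = 0.3, p₂ = 0.5,
the observed probability of beating s_min (or the exact-convention c_min)
stays within α + 3 Monte-Carlo standard errors.

## Known limitations

* **TSD with balanced groups saturates below its own cutoff.**  For a
  gene whose two groups of equal size m separate completely with shift d,
  the pooled per-gene z-score of every sample tends to
  ±(d/2)/((d/2)·√(2m/(2m−1))) ≈ ∓0.97 as d grows — *below* the ±1 TSD
  cutoff.  Only noise pushes individual samples past the cutoff (with
  probability saturating near 0.4 per sample at sample sd, 0.5 at
  population sd), so at 8 vs 8 samples even an arbitrarily strong planted
  effect yields n_A ≈ 3 of 8, while at n = 16, α = 0.05 a rule needs
  n_A ≥ 6 before its confidence threshold is beatable at all
  (P(C = 1) ≤ α requires (1 − p̂₁(1−p̂₂))¹⁶ small).  End-to-end recovery
  of planted genes through the `tsd` preset on balanced 8 vs 8 designs is
  therefore near zero at any effect size — the corresponding recovery
  test documents this honestly and fails.  TSD is better matched to
  unbalanced cohorts (where minority-group z-scores clear the cutoff) or
  larger n; for balanced designs use the `threshold` or fold-change
  presets.
* The grid quantile convention is a reporting convention (see above); its
  type-I error can marginally exceed α at coarse grid/n combinations.
* Dynamic thresholds control the per-rule type-I error only; with
  thousands of candidates the expected number of false meaningful rules
  is α per candidate (logged, not corrected).
* The exact confidence quantile is O(n²) in memory and capped at
  n ≤ 4000 samples; beyond that the grid convention is the fallback.

## Problem sizes used by the test suite

Simulation-backed tests use 50,000 replicates for calibration checks,
200,000 for the PMF-vs-Monte-Carlo agreement check, 100 seeds for the
recovery and null-recovery experiments, and 1,000 random triples for the
back-solve inverse property; the whole suite runs in well under a minute
on one CPU.
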