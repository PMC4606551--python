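# dar — dynamic association rules for gene expression data

`dar` mines association rules of the form *expression level of a gene (or
gene pair) → phenotype class* from discretised expression matrices, and
decides which rules are statistically meaningful **without user-chosen
support/confidence cutoffs**.  Instead of fixing thresholds arbitrarily, it
derives them per rule from the null distributions of support and confidence
under independence — the "dynamic" in dynamic association rules (DAR).

It is aimed at transcriptomics users (two-colour or single-channel
microarrays, RNA-seq FPKM) who want a causally readable alternative to
t-test gene lists, and at anyone mining basket data who wants principled
thresholds.

## The statistics

For a rule A → B over n baskets with antecedent indicator ~ Bernoulli(p₁)
and consequent indicator ~ Bernoulli(p₂), independent under the null:

* **Support** s = n_AB/n is Bin(n, p₁p₂)/n, so the minimum support is its
  one-sided (1−α)·100 % upper bound

  s_min = p₁p₂ + z_α √(p₁p₂(1−p₁p₂)/n).

* **Confidence** c = n_AB/n_A is a ratio C = X/Z of two dependent binomials
  whose variance does not exist (E(1/Z) diverges), so no formula like the
  above is possible.  The minimum confidence c_min is instead the (1−α)
  upper quantile of the exact discrete null distribution

  P(C = c) = Σ_z Bin(z, cz, p₂) · Bin(n, z, p₁),

  conditioned on Z ≥ 1 (C is defective at Z = 0) and renormalised by
  1 − (1−p₁)ⁿ.

A rule is **meaningful** iff its estimated support and confidence both
*strictly* exceed s_min and c_min computed from the rule's own marginals
p̂₁ = n_A/n, p̂₂ = n_B/n.  Meaningful rules that conflict — the same
antecedent implying two classes, or one gene implying the same class at
both the +1 and −1 level — are *ambiguous* and removed; the genes in the
surviving antecedents are the final gene set.

Expression matrices enter the miner after discretisation to
{−1, 0, +1} (under-, not-, over-expressed); five standard schemes are
built in (MA-plot lowess + fixed cutoffs, two fold-change presets, log-ratio
cutoffs, and median/IQR + TSD z-scores).  See `docs/methods.md` for every
convention and default.

## Worked example

Thresholds for a rule observed in n = 1000 baskets with n_A = 300 and
n_B = 700 at the 95 % level:

```
$ dar thresholds --n 1000 --p1 0.3 --p2 0.7 --alpha 0.05
s_min   0.2312
c_min   0.7425
```

Any rule with these marginals must beat support 0.2312 **and** confidence
0.7425 to be meaningful.  A full pipeline run on simulated data — 50 genes,
8 control vs 8 case samples, 3 planted up-regulated genes — looks like:

```
$ dar simulate --genes 50 --per-group 8 --planted-up 3 --planted-down 0 \
      --effect 6 --noise-sd 0.25 --seed 13 --out expr.tsv --groups-out groups.tsv
$ dar run --input expr.tsv --groups groups.tsv --discretize threshold \
      --alpha 0.05 --out-rules final_rules.tsv --out-genes genes.txt
candidate rules: 200
meaningful rules: 3
ambiguous removed: 0
screen rules: 3
final genes: 3
$ cat genes.txt
up_01
up_02
up_03
```

The three planted genes are recovered exactly; `final_rules.tsv` shows why —
each carries support 0.5 > s_min 0.428 and confidence 1.0 > c_min 0.806:

```
antecedent  consequent  n   n_A  n_B  n_AB  support   confidence  s_min     c_min     meaningful  ambiguous  final
+1:up_01    case        16  8    8    8     0.500000  1.000000    0.428061  0.806250  1           0          1
```

`dar table --n 1000 --out table.tsv` regenerates the reference table of
minimum confidences, and the library surface (`dar.minimum_support`,
`dar.minimum_confidence`, `dar.mine_rules`, …) exposes everything the CLI
does.

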