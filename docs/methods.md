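# Methods

This note records the statistical models, the numerical choices behind their
implementations, and the assumptions of the synthetic-data generator.

## 1. Differential expression (module `expression`)

Raw counts are normalized with median-of-ratios size factors: for sample *j*,
`sf_j = median_g (y_gj / geomean_g)` over genes with a positive geometric
mean across samples. Note that the per-gene geometric means tie the factors
together: rescaling one sample by *c* changes the whole factor vector, but
the *ratios* between factors shift exactly by *c* — which is the property
the normalization needs.

Per MA line, each gene is tested against the pooled ancestor replicates with
a negative-binomial Wald test:

- per-gene dispersions by the method of moments on normalized counts, floored
  at one tenth of a fitted mean–dispersion trend, then shrunk on the log
  scale toward the trend (weight 0.8 trend / 0.2 gene) — at three replicates
  per group the per-gene moment estimate alone is far too noisy;
- a two-column design (intercept, line indicator) fitted by vectorized IRLS
  across all genes at once;
- Wald *p*-values from the normal reference (a *t* reference with the tiny
  residual degrees of freedom destroys power at 3 vs 3);
- Benjamini–Hochberg control at `alpha = 0.05`.

Low-expression genes are removed before testing by ranking genes on total
normalized counts and keeping the top fraction (default 95% of the signal).
Replicate agreement is summarized as the mean inter-replicate Pearson
correlation of log2(FPKM + 1); lines below 0.96 are flagged.

Measured on the simulator at the default desk scale: recall ≈ 0.94 at an
observed false-discovery proportion ≈ 0.07, and ~2·10⁻⁴ significant calls
under a global null.

## 2. Mutational variance (module `mutvar`)

Per gene, counts follow a Poisson generalized linear mixed model

```
ln E[Y_ij] = beta0 + beta1 * x_i + u_i * x_i + b_ij + offset_ij
```

with `x_i` the line's covariate (generations since the ancestor, or mutation
count), a per-line random slope `u_i ~ N(0, sigma2_u)`, an observation-level
random effect `b_ij ~ N(0, sigma2_b)` absorbing extra-Poisson noise, and
`offset = -ln(size factor)` (the sign is switchable). The ancestor enters as
a line with `x = 0`. Reported quantities: `V_m = 2 * Var(u)` per covariate
unit, `V_e = sigma2_b`, and `h²_m = V_m / V_e`.

The marginal likelihood is Laplace-approximated: the joint mode over
`(u, b)` is found by a damped Newton iteration (the Hessian is diagonal plus
rank-per-line, solved in closed form), and the outer optimization over
`(beta0, beta1, ln sigma_u, ln sigma_b)` uses Nelder–Mead. Numerical guards:
`ln sigma` is floored at −14 to keep the Hessian finite when a variance
collapses, and the linear predictor is clipped at ±40 inside the inner
objective so overshooting line-search trials cannot overflow `exp`.

`variance_table` fits every gene for one strain, flags non-converged genes
instead of raising, and supports excluding lines (systematic leave-one-out).

## 3. Distribution of expression effects (module `dee`)

Each line contributes a pair `(m, d)`: mutation count and DEG count. The
model treats `d` as the integer part of a sum of `m` independent
per-mutation effects `X`:

- `gamma`: `X ~ Gamma(shape, scale)`;
- `zero_gamma`: `X = 0` with probability `pi0`, else `X = 1 + Gamma`;
- `zero_one_gamma`: additionally `X = 1` exactly with probability `pi1`.

Since a sum of `j` Gammas is `Gamma(j*shape, scale)`, the line likelihood is
a binomial convolution over the number `j` of non-null mutations (and, for
the three-spike model, the split `s` of exact-ones among them), with the
continuous part integrated over `[d - j, d - j + 1)`. Numerics:

- interval probabilities use both the lower and upper regularized incomplete
  gamma functions and keep the larger difference — at `shape ≪ 1` one tail
  saturates and its difference cancels catastrophically;
- spike weights use `xlogy`, so the boundary cases `pi0 ∈ {0, 1}` stay
  finite (`0 · log 0 = 0`);
- the convolution is flattened over `(line, j[, s])` index arrays built once
  per dataset, and summed by a segment log-sum-exp.

Fitting maximizes the likelihood with seeded `scipy.optimize.dual_annealing`,
restarted over five `pi0` intervals of width 0.2 (the surface is ridged along
`shape · scale`; the restarts plus the local polish find the ridge top
reliably at the default budget of `maxiter = 60`). Models are compared by
AIC (BIC disagreement is flagged). Closed-form summaries: the mean effect
`(1 − pi0 − pi1) (1 + shape·scale) + pi1` and the probabilities of a mutation
perturbing 0, exactly 1, or ≥ 2 genes. Forward simulation of per-line DEG
totals yields the null distribution of the mutation-count/DEG-count
correlation.

## 4. Colocalization (module `colocalization`)

Coordinates are 0-based half-open throughout; GFF3 (1-based inclusive) and
VCF (1-based) are converted at the I/O boundary. The mutation–gene distance
is the number of bases strictly between the mutation and the nearest gene
edge; intragenic mutations get distance 1. The cis test counts
mutation–DEG pairs within a 100 bp window (including intragenic) and
compares against DEG-set labels resampled uniformly from the gene universe;
the SV test does the same for the proportion of DEGs overlapped by the
line's structural variants. Both report the add-one permutation *p*-value
`(b + 1) / (n + 1)`. UTR enrichment compares the fraction of intragenic
mutations falling in annotated UTRs with the UTR base-pair fraction of the
gene models (or of the genome).

Permutation tests on discrete counts are conservative when the null
statistic has heavy ties at the rejection threshold; calibration studies
should use DEG sets and mutation counts large enough that the count
statistic is well spread (the acceptance suite uses 150–200-gene DEG sets
over a 600-gene universe, where the measured null rejection at 5% is
0.040–0.044).

## 5. Co-expression (module `coexpression`)

The network is weighted: adjacency `|r|^beta` (default `beta = 2`), the
standard topological overlap matrix, average-linkage hierarchical clustering
of `1 − TOM` cut to a target module count, eigengene (first principal
component) merging of modules correlated ≥ 0.75, and hub genes as the top
5% (by ceiling) of intramodular connectivity per module. For path-based
statistics, edges with `|r|` below a floor (default 0.1) are removed and the
rest get length `1/|r|`; all-pairs shortest paths are computed once with
`scipy.sparse.csgraph.dijkstra` and cached.

The DEG-clustering test compares the observed median pairwise path distance
among a line's DEGs with sets resampled within ancestral-expression strata
(five quantile bins, top bin split in two, so highly expressed genes are
matched). *p* is add-one; results with fewer than two connected DEG pairs
are reported as undefined rather than 1.0.

## 6. Fitness correlates (module `correlates`)

Genes are binned into expression percentiles by rank (stable ties, sizes
differing by at most one, invariant to monotone transforms). Group
comparisons use the Brunner–Munzel studentized rank statistic with
Satterthwaite degrees of freedom plus the stochastic-superiority estimate
`P(X < Y) + 0.5 P(X = Y)`; complete separation (degenerate rank variances
with superiority 0 or 1) returns `statistic = ±inf, p = 0` with the exact
superiority, and two identical degenerate samples return `(0, 1, 0.5)`.
Relative fitness is regressed on the per-line DEG count or summed |log2
fold change| by OLS, with a leave-one-out refit per line to surface
influential points.

## 7. Synthetic-data generator (module `simulate`)

The generator draws, per line: generations in 800–1100; Poisson mutation
counts at per-strain means (defaults 112.1 and 76.2 for 13 + 15 lines);
per-mutation DEG effects from the configured DEE (defaults `pi0 = 0.42`,
`shape = 0.0118`, `scale = 2005`); target genes that are cis (within the
100 bp window of the mutation, default fraction 0.9) or trans (drawn from
one synthetic co-expression module); log2 effect sizes `N(0, 1.5²)`;
structural variants with realistic type frequencies and lengths; relative
fitness `1 + slope · #perturbed genes + noise`; and counts
`Poisson(sf · exp(eta))` with a module-structured baseline, observation-level
log-normal noise, and per-sample size factors. Reproducibility comes from
`zlib.crc32`-labeled `SeedSequence` children, so each generation stage has
an independent, stable stream.

Known limitations, deliberate for a desk-scale generator: gene models are
intron-free (exonic length = span); trans-target draws are capped at the
module size, so a very heavy-tailed per-mutation effect cannot recruit more
targets than its module holds (DEE recovery experiments therefore draw
totals directly from the DEE, bypassing the cap); and fitness depends on the
number of perturbed genes, not on their effect sizes.

## 8. Problem sizes

Default scales are chosen so the full test suite runs on one CPU in minutes:
120–600-gene genomes, 3–15 lines per strain, 3 replicates, `maxiter = 60`
annealing for DEE fits (seconds per fit on 28 lines), and 199–499
permutations for the resampling tests. All of these are parameters, not
constants; the same code runs at transcriptome scale (~17,000 genes) when
given the time.
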