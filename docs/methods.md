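# Methods note

## Feature-level model

Log-scale expression of feature *g* in sample *k* is modelled as
`y_gk = mu_g + beta_g * x_k + e_gk`, with `x_k` the group indicator
(group 1 = reference) and `e_gk ~ N(0, sigma_g^2)`.  The two-group fit
gives `diff_g = mean(group 2) - mean(group 1)` and the pooled variance
`s_g^2` on `d = n1 + n2 - 2` degrees of freedom.

Residual variances receive a scaled inverse-chi-square prior
`sigma_g^2 ~ d0 s0^2 / chi^2(d0)`.  The hyperparameters are estimated
by moment matching on `e_g = log s_g^2`:

```
Var(e) = trigamma(d/2) + trigamma(d0/2)
E(e)   = log s0^2 + digamma(d/2) - digamma(d0/2) + log(d0/d)
```

`trigamma` is inverted by Newton iteration started from the
large-argument expansion.  If the observed spread of `e` does not
exceed `trigamma(d/2)`, `d0 = +inf` (posterior variances collapse to
`s0^2` and the t reference becomes normal); `d0 = 0` recovers the
classical pooled t.  With

```
s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)
t_g    = diff_g / sqrt(s~_g^2 (1/n1 + 1/n2))
```

`t_g` is referred to Student t on `d0 + d` df.  One unit test verifies
agreement with Bioconductor limma's `eBayes` (d0, s0^2, t, p) to
~1e-10 on a heteroscedastic fixture.

Directional convention throughout: "up" means a higher mean in group 2;
`p_up = P(T >= t)`, `p_down = 1 - p_up`.

## Gene-set tests

Each test maps one miRNA's target set to directional p-values
(`p_set_up`, `p_set_down`) against the measured mRNA universe.

**Ranks.** Per direction, genes are ranked 1..p by ascending one-sided
p-value, ties broken by feature id, so `rank_up + rank_down = p + 1`
without ties.

* **wilcoxon** (competitive): normal-approximation rank-sum of member
  ranks, no continuity correction, so the two directional p-values sum
  to exactly 1 (complementary).
* **ks** (competitive): one-sided one-sample Kolmogorov-Smirnov toward
  low ranks, `p = exp(-2 m D+^2)` — conservative, not complementary.
* **fisher_exact** (competitive): 2x2 enrichment of one-sided DE calls
  at threshold `tau` (default 0.05) vs. set membership; hypergeometric
  upper tail.
* **globalq** (self-contained): quadratic-form statistic
  `Q = sum_g ((y_g - y_bar_g) . (x - x_bar))^2` with label-permutation
  null; applied separately to the subset of member genes whose observed
  difference is positive (for `p_set_up`) and negative (`p_set_down`).
* **roast / romer** (rotation tests): each gene's sample vector is
  projected onto an orthonormal basis whose first coordinate carries
  the normalized group contrast and whose remaining `d = n - 2`
  coordinates span the residual space.  A rotation draws one random
  unit `(d+1)`-vector *shared by all genes* (preserving inter-gene
  correlation) and recomputes every gene's moderated t with the prior
  held at its observed estimate.  `roast` (self-contained) compares the
  set's mean normal score against its rotation distribution; `romer`
  (competitive) compares the set's mean *rank* among all genes.  Both
  report `(1 + b) / (B + 1)`.  Ranks are computed on the moderated t
  directly — the t-to-normal-score map is strictly increasing, so the
  ranks are identical and the distribution-function evaluations can be
  skipped (about a 2x speedup for romer).

Tests are looked up through a registry (`register_set_test`) so
external tests can be plugged in.

## Combination and selection

A differential miRNA is expected to shift its targets the opposite
way, so `p_mir_up` is combined with `p_set_down` and vice versa.
Complementary set tests (wilcoxon, roast, romer) use Stouffer's
inverse-normal method; the others use Fisher's method against
chi-square(4).  The per-miRNA score is
`min(1, 2 min(p_comb_up, p_comb_down))`, adjusted across miRNAs by
Benjamini-Hochberg; selection reports all miRNAs with adjusted score
<= alpha (default 0.05).  p-values are clipped at 1e-300 before logs
and normal quantiles.

## Simulation generator

A two-group microarray-like experiment on the log scale:

* Mean vectors `mu ~ lognormal(meanlog 2, sdlog 0.5)` per feature,
  redrawn every run.
* Noise is multivariate normal with covariance `sigma^2 * C`, where
  `C` is one of: block-diagonal (blocks of 10, within-block correlation
  0.5), AR(1) (rho 0.5), or unstructured (correlation of a Wishart draw
  with df = dim + 10).  The covariance (and its Cholesky factor) and the
  target-set allocation are drawn once per study and reused across runs;
  everything else is redrawn per run.
* 10% of miRNAs and 5% of mRNAs are differential: +delta on the group-2
  mean for half of them, -delta for the other half, delta in {0..6}.
* miRNA-to-target coupling: `mu'_j = mu_j - beta * sum_i a_ij c_i mu_i^mir`
  with `beta = 0.5` and per-miRNA factors `c_i ~ N(1, 0.1)`, applied in
  both groups, so only a differential miRNA induces a group-differential
  target shift (of size `beta * c_i * delta`).  Degraded means are
  floored at 0.05; the floor can attenuate the induced shift for genes
  targeted by several miRNAs.
* Target-set topology: *disjoint* — sets of 10 genes partitioning the
  2000-gene universe (200 x 10 = 2000); *overlapping* — a circular
  chain of sets of 20 in which each set shares 10 genes with the next.
  Sizes are config-exposed (`set_size_range`); disjoint demands that
  total size not exceed the universe and raises otherwise.  A size
  range of 10-30 is infeasible for 200 disjoint sets in 2000 genes
  (expected demand ~4000), hence the fixed default sizes.

### Parameter defaults and rationale

| parameter | default | rationale |
|---|---|---|
| n_per_group | 10 | typical two-group microarray study size |
| p_mir / p_mrna | 200 / 2000 | panel-vs-genome-wide scale ratio |
| sigma_sq | 4.0 | chosen once, before any acceptance run, so delta/sigma spans 0-3 over the fold-change grid 0-6 and power curves separate across the whole grid instead of saturating early |
| de proportions | 10% miRNA, 5% mRNA | consistent with an FDR ceiling of 0.9 when all 200 miRNAs are called at 10% true DE |
| beta, c_i | 0.5, N(1, 0.1) | moderate coupling with mild per-miRNA heterogeneity |
| n_runs / n_rot / n_perm | 100 / 500 / 200 | Monte-Carlo error ~ +-0.02-0.04 on a mean FDR near 0.05; rotation floor 1/501 well below the working p-values |
| alpha | 0.05 | conventional BH level |

Metrics per run: false-discovery proportion `FDP = FP / max(1, FP+TP)`
(so 0/0 := 0) and average power rate `APR = TP / #truly-DE`; the study
reports their means per method and delta, plus a min-median-max summary
over the grid.

### Generator scope and limitations

* The generator emulates log-scale microarray data only; no counts, no
  missing values, no batch structure.
* The coupling is linear in the miRNA *mean*, not the realized
  expression; run-to-run coupling noise enters only through `c_i`.
* The circular-chain overlap is one concrete topology; real target
  networks overlap irregularly.
* **Overlapping sets and the FDR bound.** With overlapping sets a null
  miRNA adjacent in the chain to a differential miRNA shares half of
  its set, and those genes carry an induced shift of `beta * delta` (up
  to 3 log-units against noise sd 2).  Its competitive set p-value can
  reach ~1e-3, and combining with a uniform miRNA p-value then clears
  the BH threshold for a noticeable fraction of null neighbours: the
  mean FDR of the competitive combined procedures rises to ~0.15-0.35
  at delta >= 3 instead of staying near 0.08.  The inflation scale is
  governed by `beta * delta / sigma` and the overlap topology.  The
  qualitative ordering is robust: the self-contained global test
  inflates far more (~0.9 at delta 6) than the competitive combined
  procedures, and all procedures are exact at delta = 0.  Self-contained
  tests (roast, globalq) are anti-conservative under inter-gene
  correlation when used on overlapping or correlated sets; this is the
  known competitive/self-contained trade-off.

## Numerical choices

* Trigamma inversion: Newton with analytic derivative (tetragamma),
  initialised at `0.5 + 1/y`; bisection-style halving guards against
  non-positive iterates.
* Rotation tests cache the rotated statistics and the joint rank matrix
  across sets within one analysis, so a 200-set study performs one
  `genes x rotations` computation, not 200.
* With near-homoscedastic data the prior degenerates to `d0 = inf`;
  rotated statistics then scale with each gene's total sum of squares
  and strongly shifted genes saturate the rank extremes under every
  rotation, costing romer power (calibration is unaffected: observed
  and rotated columns remain exchangeable under the null).  Real data
  with heterogeneous variances keeps `d0` finite.
* The romer p-value floor is not exactly `1/(B+1)` under extreme
  shifts: a rotation whose contrast component is large carries the
  whole shifted block back to the top ranks, so a few rotations tie or
  beat the observed mean rank.  The self-contained roast floor is exact.
* BH adjustment via reverse cumulative minimum on the sorted scaled
  p-values; cross-checked against statsmodels in the tests.
* p-values are clipped at 1e-300 (logs) and 1 - 1e-16 (normal
  quantiles) to keep the combiners finite.
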