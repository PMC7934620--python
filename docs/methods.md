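# Methods

## Indices

The core quantities are computed from a per-genotype means table (x̄_lf,
x̄_hf in g plant⁻¹, pooled over years, replicates and plants):

* **Percent reduction** PR = (1 − x̄_lf/x̄_hf) × 100. Defined only for
  x̄_hf > 0; negative PR (better performance under stress) is reported, not
  clipped.
* **Stress (soil fertility) intensity** SI = 1 − Ȳ_lf/Ȳ_hf, where the grand
  means Ȳ are *unweighted means of the per-genotype means*. This convention
  reproduces the "Mean" row of a genotype-means table; with unbalanced data
  it differs from a plot-weighted grand mean, which is why it is fixed here
  explicitly. SI must be strictly positive — an unstressed population makes
  the susceptibility index meaningless, and the package raises rather than
  returning signed nonsense.
* **SFSI** = PR/100/SI per genotype, so `sfsi × si × 100 = pr` holds as an
  exact algebraic identity, and all three quantities are invariant to
  rescaling the trait. The SFSI column mean is close to, but not exactly, 1
  (mean of ratios vs ratio of means); on the packaged reference tables it is
  0.979 (tuber yield) and 0.993 (shoot dry weight).

Pooling choice: per-genotype means are plain pooled means over all
non-missing observations. With the balanced reference design (3 plants × 2
replicates × 2 years, n = 12) this equals the mean of year means; the choice
only matters for unbalanced data and is documented so results stay
reproducible there. Missing values are excluded pairwise per trait and every
exclusion is logged in the dataset's validation report; nothing is imputed.

Report rounding is half-away-from-zero — means and PR at 1 decimal, SFSI at
2 — applied only at the output boundary; all internal computation is full
precision. SFSI-sorted output breaks ties by (sfsi, genotype id) with a
stable sort.

## Tolerance classification

The reference study names its tolerant and susceptible sets but no closed
rule, so the classifier makes the implied rule explicit and configurable:

* *tolerant*: SFSI below the check's **and** (by default) PR below the table
  mean PR — low relative and absolute loss;
* *susceptible*: SFSI ≥ `susceptible_sfsi_min` (default 1.25, which cleanly
  separates the three susceptible entries from the rest of the reference
  trial on both traits);
* the check is labeled *check*; everything else *intermediate*.

Labels are exhaustive and mutually exclusive; susceptibility is tested
before tolerance, though the two cannot overlap while the check's SFSI is
below the susceptibility threshold.

## Reference tables and their internal inconsistencies

The packaged tables carry the published LF/HF genotype means together with
the published PR, p-value and SFSI columns (sha256-checksummed CSVs). The
tuber table is fully self-consistent: recomputing PR and SFSI from its LF/HF
columns reproduces every printed cell to the printed precision. The shoot
table contains four SFSI cells that contradict their own row's printed PR
divided by the table's SI — most obviously the check's printed 0.08, which
recomputes to 0.886 (the accompanying text reports 0.88), and more subtly
R125 (0.64 vs 0.651), R060 (0.89 vs 0.905) and R100 (0.97 vs 0.994). The
reproduction pipeline detects inconsistency cell-by-cell via the
`printed_sfsi ≈ printed_pr/(100·SI)` identity, validates such cells against
the recomputed value, and flags each one in the run log and summary.
Recomputation from the means is treated as the oracle throughout. Related
text-vs-table discrepancies (a reported shoot-SFSI range of 0.60–1.30 vs the
table-derived 0.65–1.29, and a reported lowest shoot reduction of 29.2% vs
the table's 22.6%) are resolved in favor of the tables; the published
shoot–tuber SFSI correlation of 0.71 recomputes to 0.69 from the tables,
within the ±0.03 comparison tolerance used for correlations (the precision
of the underlying data being unknown beyond 1 dp).

## Split-plot inference

The mixed model mirrors the trial layout: fixed effects year (Y), fertility
treatment (T), genotype (G) and all interactions; random intercepts for the
block (year × replicate) and for the main plots (treatment within block),
the two error strata of a split-plot design. Term significance is reported
as Wald chi-square with the term's degrees of freedom. Numerical choices:

* sum-to-zero contrasts, so with a balanced design the term-wise Wald tests
  coincide with Type II tests;
* the response is scaled to unit variance before fitting (Wald statistics
  are invariant); the saturated 84-parameter fixed design is otherwise
  ill-conditioned enough to break gradient-based optimizers, so the fit uses
  Powell's method;
* if the main-plot fit fails (singular or non-convergent), the model is
  refit with the block-only random structure and the result is flagged
  (`simplified=True`) — never silently.

Caveats: with two replicates there are only four blocks and eight main
plots, so the variance components are estimated on very few degrees of
freedom and Wald p-values for the *whole-plot* terms (Y, T, Y×T) are
approximate. The within-plot terms (G and its interactions) are tested
against the rich residual stratum and are well calibrated — the null
simulations in the test suite check exactly these.

Per-genotype LF-vs-HF comparisons use the two-sided Welch (unequal-variance)
t-test on plot-level values, with a strict p < α significance flag (α = 0.05
by default) and no multiplicity correction across genotypes, matching common
reporting practice for such tables. Genotypes with fewer than two
observations per treatment are flagged untestable. Comparisons against the
check under one treatment level use the multivariate-t Dunnett adjustment
(scipy), two-sided by default, with the figure-convention significance bands
(*** p<0.001, ** p<0.01, * p<0.05, + p<0.1).

## Synthetic trial generator

`simulate_trial` emulates the reference design: per-genotype HF means and
reduction fractions define the true cell means; additive Gaussian effects
for year, year×treatment (applied with opposite signs to the two
treatments), block, main plot, and a per-plant residual generate the
observations. Year and year×treatment effect vectors are centred to mean
zero so pooled genotype means are unbiased for the configured truth, which
keeps the true PR/SI/SFSI analytic (computed from the configuration through
the same index code, never from a sample). Negative draws are clipped at
zero — the traits are masses — with a logged count. Seeding uses a single
root `SeedSequence` with fixed spawn keys per stratum and per genotype, so
adding genotypes to a configuration leaves existing genotypes' draws
untouched.

Default calibration (`reference_tuber_config`): HF means and reduction
fractions read from the tuber reference table; residual sd 500 g plant⁻¹,
main-plot sd 100, block sd 50, year effects ±150, year×treatment ±50. The
residual sd was chosen so that per-genotype Welch tests at the design's
n = 12 land in the p-value range the reference trial prints (borderline
p ≈ 0.05–0.18 for the genotypes with the smallest gaps). What the generator
does **not** emulate: spatial field trend, sett-sprouting-time variability,
virus load, year-specific weather beyond an additive shift, or
non-Gaussian/heteroscedastic noise. Passing recovery tests therefore show
the estimator chain is correct under the stated error model, not that real
trials are this well behaved.

A consequence worth stating plainly: at the calibrated noise level the
standard error of a per-genotype SFSI estimate is ≈ 0.18, comparable to the
gaps between the tolerant entries and the check. Exact recovery of the full
tolerant/susceptible sets from a single n = 12 trial is therefore
essentially impossible even though each individual label is recovered well
above chance; the test suite demonstrates ≥ 90% joint set recovery once the
per-plot noise is an order of magnitude smaller, isolating estimation noise
(not the pipeline) as the binding limit. Selection decisions from a trial of
this size should treat the index ranking, not the hard labels, as the
signal.

## Problem sizes used in the validation suite

Simulation-based tests run at sizes chosen to exercise the statistics
properly while keeping the suite quick: 200 replicate null trials (6
genotypes × 4 replicates) for the deviance-table uniformity check, 500
null simulations with 8 comparators for the Dunnett family-wise error check,
1,000 random tables for the SFSI identity/scale-invariance sweep, 200
simulations per arm for RMSE-vs-replication, and 60 per arm for the
set-recovery contrast. The Dunnett family size of 8 (rather than the
reference trial's 20) keeps the multivariate-t integrations cheap; the
family-wise error property being tested is size-agnostic.

## Errors and degenerate inputs

Zero HF means make PR undefined (`UndefinedRateError`; in table computation
the row is flagged and excluded from grand means). SI ≤ 0 raises
`StressOrientationError`, including for a simulation configuration whose
truth is unstressed — the truth object then exists but refuses to produce
SFSI values. Schema and design violations (missing mapped columns, ≠ 2
treatment levels, negative trait values, replicate < 1) raise typed errors
at the reading/validation boundary; unparseable trait values are converted
to missing and logged, never dropped silently.
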