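# Methods

This note documents the statistical model behind `mcbsurv`, the choices we
made where the design was genuinely open, and what the synthetic cohorts do
and do not emulate.

## β values and probe-level filtering

The methylation fraction at probe *i* is
β = max(y_methy, 0) / (max(y_methy, 0) + max(y_unmethy, 0) + ε),
with normalized allele intensities that may be negative after background
correction (hence the clipping) and a constant offset ε > 0 (default 100,
the array vendor's recommendation). β therefore always lies in [0, 1), and
is monotone nondecreasing in the methylated intensity and nonincreasing in
the unmethylated one.

Filtering removes probes flagged as overlapping a known SNP (genetic
variation under the probe confounds the methylation signal) and probes with
a missing fraction ≥ 0.30. The threshold is deliberately "≥": a probe with
*a few* gaps — strictly below 30 % — is imputable, anything at or above is
not. Surviving gaps are filled with the probe's mean over its non-missing
samples, computed within the current dataset only so that imputation never
leaks information across training and validation cohorts. Observed values
are never altered. Upstream array preprocessing (noob background
correction, dye-bias correction, batch adjustment) is out of scope: users
supply normalized β values.

## Block partitioning

Within each chromosome, probes are ordered by position and every
*consecutive* pair is tested: a boundary is declared when the gap exceeds
`max_gap` (default 1000 bp) **or** the squared Pearson correlation of the
two probes' β values across training samples falls below `r2_cutoff`
(default 0.8). Maximal boundary-free runs with ≥ `min_cpgs` (default 2)
probes become methylation-correlated blocks. We use the adjacent-pair rule
rather than all-pairs-within-1-kb because boundaries are transition spots
*between neighbouring markers*; a linear chain of adjacency decisions is
what makes "maximal boundary-free run" well defined.

Numerical choices:

* A zero-variance probe has undefined correlation with both neighbours; we
  treat undefined r as a boundary on both sides (conservative — no spurious
  merging) and log the count.
* Pearson r needs ≥ 3 samples; fewer is an error.
* Block length is end − start + 1 (inclusive 1-based coordinates), so the
  smallest possible 2-CpG block — an adjacent CpG dinucleotide pair — has
  length 3 bp. Emitted BED intervals are 0-based half-open.
* Partitioning uses training samples only; validation/testing data never
  influence block boundaries.
* Raising the r² cutoff can only add boundaries, so blocks split or shrink
  but never merge (property-tested).

Gene linking: a block's candidate genes are the union of its member probes'
annotated symbols; expression counts are transformed as log2(count + 1)
(the pseudocount of 1 handles zeros), and the candidate with the largest
absolute Pearson correlation against the block's per-sample mean β wins.
Blocks without candidates or expression keep no gene.

## Block selection and base learners

Feature selection operates on block mean β values (unweighted arithmetic
mean over member CpGs). Blocks with fewer than 5 CpGs are dropped, then an
L1-penalized Cox model is fitted along a decreasing penalty path (features
standardized internally, glmnet convention, path down to 0.01·λ_max), and
blocks with a nonzero coefficient at the **fixed** penalty λ = 0.01 are
retained. The fixed-λ rule, rather than CV-minimal λ, makes selection
reproducible and matches the intended stringency; selection is empirically
monotone along the path (a larger λ selects a subset).

Three base learners per selected block, all on the member-CpG β matrix:

* **Cox PH** — risk is the linear predictor. Zero-variance CpGs are
  dropped pre-fit (coefficient 0, warned); the CpG count may not exceed
  half the sample count to avoid wildly overparameterized fits;
  non-convergence flags the model and the block is excluded from ranking.
* **Linear ε-SVR** — the regression target is the *observed* follow-up
  time (censoring is ignored at fit time — a documented simplification;
  log(time + 1) is available as an alternative target). Predictions are
  negated so that higher score = worse prognosis. Defaults C = 1, ε = 0.1.
* **Elastic-net Cox** — partial likelihood with mixed L1/L2 penalty
  (mixing fraction 0.5 by default, exposed), coefficients taken at the
  smallest penalty of a 100-step log-spaced path from λ_max down to
  0.01·λ_max: the block's CpGs are retained wholesale except those with the
  weakest effects. The pure-ridge limit (mixing 0) is fitted directly as a
  ridge-penalized Cox model and agrees with a direct penalized-likelihood
  optimizer to < 1e-3.

Training-set risk scores come from k-fold CV (default k = 10) stratified by
event status; folds are redrawn under a different derived seed (capped)
until every training split has ≥ 2 events, and k = n degenerates to
leave-one-out. All fold draws are deterministic given the seed (default 42).

## Feature-weighted linear stacking

The blended score is d(x) = Σᵢ wᵢ(x) gᵢ(x) with weights linear in
meta-features, wᵢ(x) = Σⱼ vᵢⱼ fⱼ(x), i.e. a linear model over the product
columns fⱼ·gᵢ solved by least squares against a target y(x). Two open
choices had to be fixed:

* **Target y(x).** Least squares needs a numeric label; on right-censored
  data we default to the 0/1 event indicator (consistent with the "higher
  score = worse outcome" orientation). Martingale residuals from a
  covariate-free Cox model are available as an alternative
  (`target_mode="martingale"`); they penalize early events more smoothly
  but are less interpretable. Treating censored samples as label 0 is a
  known bias of the default and is the main caveat of the stacking stage.
* **Meta-features fⱼ.** Default is the constant function 1 alone, which
  reduces FWLS to classical linear stacking; additional per-sample
  meta-features (e.g. clinical covariates) can be registered, in which case
  the model weights vary across samples.

Rank-deficient designs (e.g. duplicated base models) resolve to the
minimum-norm solution, which splits weight equally across duplicates and is
deterministic; an optional nonnegativity constraint switches to NNLS.
Ensemble training scores are themselves out-of-fold: within each CV
iteration the stacking weights are fitted on the other folds' base scores
only.

## Evaluation

* **Time-dependent AUC** at horizon t (default 1826 days = 5 years) uses
  the cumulative-case / dynamic-control definition with inverse probability
  of censoring weights from the Kaplan–Meier censoring estimator
  (case weight 1/G(tᵢ⁻), control weight 1/G(t)); tied scores count 0.5.
  With no censoring this reduces exactly to the empirical case/control AUC,
  and it matches scikit-survival's estimator to machine precision (tested).
  No cases or no controls at the horizon yields a missing value, never 0.
* **Harrell's C-index** over comparable pairs, ties 0.5.
* **Rank product**: within each (model × split) column, blocks are ranked
  by AUC descending (average ranks on ties) and RPᵢ = Σⱼ ln Rᵢⱼ. The log
  base only rescales RP, so ranking is base-invariant; we use natural log.
  Blocks missing an AUC in any ranked column are excluded and logged. The
  column set is caller-supplied, so both a train+validation ranking and a
  training-only ranking (combined-split study design) are expressible.
* **Kaplan–Meier / log-rank** at the training-median risk cutoff (score
  strictly above the cutoff = high risk; the median splits the training set
  into groups differing by ≤ 1).
* **Bootstrap AUC comparison**: percentile CI of the per-replicate AUC
  difference; replicates with an undefined AUC are redrawn and counted;
  two-sided p = 2·min(P(Δ ≤ 0), P(Δ ≥ 0)) clipped to (1/n_boot, 1).
* **Paired t-tests** across blocks per model pair with Benjamini–Hochberg
  adjustment; differences that are constant up to float cancellation give
  t = 0, p = 1 with a warning.
* **Multivariate Cox adjustment** of the dichotomized risk group (matching
  deployment; continuous mode available) plus clinical covariates,
  complete-case; separation or collinearity flags the result rather than
  raising.

## Synthetic cohorts

`synthetic_data` generates what the pipeline assumes about real arrays:

* Per block, a latent Gaussian field √ρ·shared + √(1−ρ)·idiosyncratic gives
  exchangeable pairwise correlation exactly ρ, and a logistic link around
  logit(mean β) maps it to (0, 1). We chose latent-Gaussian-plus-link over
  direct beta-distribution sampling because Pearson correlation on β is the
  partitioning statistic and the monotone link approximately preserves the
  latent correlation. `latent_scale` = 0.6 yields a per-CpG β SD of ≈ 0.15
  at mid methylation, comparable to variable array probes.
* Block mean levels cycle through low/mid/high (0.15 / 0.5 / 0.85),
  mirroring the trimodal β landscape of array data; noise CpGs are
  independent, drawn around the same three levels, and spaced 2 kb apart so
  they can never link.
* Event times are exponential with hazard
  baseline·exp(effect·(centered causal-block mean β)); defaults: baseline
  1/1500 per day (median time to event ≈ 3 years at the baseline),
  effect = ln 2 per 0.1 β (hazard doubles per 0.1 increase in block mean),
  independent exponential censoring at rate 1/3000 per day plus an
  administrative cutoff at 10 years — roughly 60 % observed events,
  typical of multi-year disease-free-survival follow-up.
* Expression counts are built so log2(count + 1) has a prescribed Pearson
  correlation with the block mean β.

The standard fixture design used by the tests and the acceptance script is
300 samples, 21 blocks of 5 CpGs (ρ = 0.95), one causal block, 100 noise
CpGs, split 60/20/20 into training/validation/testing. These sizes keep a
full pipeline run under a second while leaving the causal effect strong
enough to be detected reliably.

What the simulator does **not** emulate: probe-type (Infinium I/II) biases,
batch effects, cell-type heterogeneity, spatially decaying (rather than
exchangeable) intra-block correlation, non-proportional hazards, and
informative censoring. Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not field performance on
real cohorts.

## Known limitations

* The SVR learner ignores censoring in its regression target; heavily
  censored cohorts will bias it toward censoring times.
* The stacking target treats censored samples as non-events.
* The L1 selection penalty is a fixed value on a standardized-feature path;
  cohorts with very different effect scales may need a different λ.
* Partitioning assumes probes are dense enough that adjacency is
  meaningful; sparse regions produce few blocks by construction.
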