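# mcbsurv

Survival prediction from DNA methylation arrays using **methylation-correlated
blocks** (MCBs) and a stacked ensemble of per-block survival models.

Adjacent CpG sites on the same DNA strand tend to be modified together by
methyltransferases and demethylases, so their array β values are tightly
correlated over short genomic distances — much like linkage-disequilibrium
blocks of neighbouring SNPs. `mcbsurv` exploits this: instead of modelling
half a million individual 450K probes, it partitions each chromosome into
maximal runs of co-methylated adjacent CpGs and treats each block as one
candidate prognostic signature for right-censored survival (e.g.
disease-free survival of cancer cohorts).

## Method

Given a β-value matrix (CpGs × samples, β = fraction of methylated alleles,
computed as `max(y_m,0) / (max(y_m,0) + max(y_u,0) + ε)` with offset
ε = 100), the pipeline:

1. **Filters** probes overlapping known SNPs and probes with ≥ 30 % missing
   samples; remaining gaps are mean-imputed per probe.
2. **Partitions** each chromosome: a boundary is declared between adjacent
   CpGs whenever their distance exceeds 1 kb or the squared Pearson
   correlation of their β values falls below r² = 0.8; boundary-free runs of
   ≥ 2 CpGs become MCBs. Blocks can be linked to the gene whose log2
   expression correlates most strongly (largest |r|) with the block mean β.
3. **Selects** prognostic blocks: block mean β values feed an L1-penalized
   Cox model along a regularization path, keeping blocks with a nonzero
   coefficient at the fixed penalty λ = 0.01 (blocks with < 5 CpGs are
   dropped first).
4. **Fits three base learners** per selected block on its member-CpG β
   values: a Cox proportional-hazards model `G_COX`, a linear-kernel
   ε-support-vector regression `G_SVR` (negated predicted time as risk), and
   an elastic-net penalized Cox model `G_EN` (coefficients at the minimum
   penalty of the path). Training risk scores are out-of-fold from 10-fold
   CV stratified by event status.
5. **Stacks** the base scores by feature-weighted linear stacking: the
   blended score is d(x) = Σᵢⱼ v·fⱼ(x)·gᵢ(x), with the weights v solved by
   (minimum-norm) least squares; with the default constant meta-feature this
   is classical linear stacking.
6. **Ranks** blocks by the rank product RPᵢ = Σⱼ ln Rᵢⱼ of their
   time-dependent AUC ranks across models and data splits (small = 
   consistently good), and **evaluates** the winner with 5-year IPCW AUC,
   Harrell's C-index, Kaplan–Meier curves split at the training-median risk
   score with a log-rank test, bootstrap AUC comparisons, paired t-tests
   with Benjamini–Hochberg adjustment, and multivariate Cox adjustment for
   clinical covariates.

A seed-deterministic synthetic-data module generates 450K-like cohorts with
planted correlated blocks, proportional-hazards event times driven by a
causal block, right censoring and optionally correlated expression, so the
whole pipeline is testable without any downloads.

## Worked example

Run the full pipeline on a synthetic cohort (300 samples, 21 planted blocks
of 5 CpGs, one block driving the hazard, 100 noise CpGs; 60/20/20
training/validation/testing split):

```python
import mcbsurv as M
from mcbsurv.pipeline import SimulateConfig

cfg = M.RunConfig(seed=1, out_dir="example_run", simulate=SimulateConfig())
report = M.run_pipeline(cfg)
print("discovered blocks:", report.n_mcbs_discovered)
print("selected by L1-Cox:", report.selected_mcb_ids)
print("top block:", report.top_mcb_id)
```

prints

```
discovered blocks: 21
selected by L1-Cox: [1]
top block: 1
```

All 21 planted blocks are recovered by the partitioner; L1-Cox selection at
λ = 0.01 keeps only block 1 — the causal block — which therefore tops the
rank-product ranking. Its stacked-ensemble time-dependent AUC at 5 years is
0.792 (training, out-of-fold), 0.788 (validation) and 0.918 (testing), and
splitting the testing samples at the training-median ensemble score gives a
log-rank χ² of 26.3 (p ≈ 3e-07): high-scoring samples progress markedly
earlier. Artifacts (`report.json`, `mcbs.bed`, `auc.tsv`, `cindex.tsv`,
`provenance.json`) land in `example_run/`.

The same stages are exposed on the command line:

```bash
mcbsurv simulate --seed 1 --out-dir fixtures/
mcbsurv discover --beta fixtures/beta.tsv --manifest fixtures/manifest.csv --out mcbs.bed
mcbsurv train --beta fixtures/beta.tsv --mcbs mcbs.bed --clinical fixtures/clinical.tsv --out scores.tsv
mcbsurv run --config config.yaml
```

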