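# batchbench

A simulation benchmark of batch-effect correction strategies for gene
expression studies, built for statisticians and bioinformaticians deciding
how to handle hybridization batches in population-scale transcriptomics —
and whether paying for QC technical replicates buys anything.

Expression profiling of hundreds of samples cannot be run in one go; batch
effects (systematic, non-biological shifts shared by samples processed
together) can exceed the biological signal of interest. This package
simulates cohorts with known injected batch effects and treatment effects
and scores four per-gene analysis strategies:

* **LM** — OLS of expression on the covariate, ignoring batch (control);
* **LMBatch** — OLS with batch fixed effects
  (y = β0 + β1·T + Σ_j α_j 1{batch=j} + ε);
* **LMM** — random-intercept mixed model, y = β0 + β1·T + u_batch + ε with
  u ~ N(0, σ_u²), fitted by maximum likelihood;
* **EB+LM** — parametric empirical-Bayes location/scale batch adjustment
  (standardize per gene, shrink per-batch shifts γ*_ij and scales δ*_ij
  toward normal / inverse-gamma priors, remove them), then OLS.

Each arm runs with or without **QC calibration**: per-gene, per-batch
factors QC_ij = mean_k(q_ijk) / mean_jk(q_ijk) computed from technical
replicates of one reference sample placed in every batch.

A simulated dataset is s_ijl = x_ijl [+ q_ij − τ_i] + r_j + T_l·1{i ≤ 500}
[+ e_ijl], with r_j ~ N(0, γ²) per batch (γ = 2.72 log2 units by default),
T_l ~ N(0, SD²) per subject, SD ∈ {0.1, …, 3}, and optional per-gene noise
e ~ N(0, σ_ei²). Detection is scored against the known 500 effect genes by
TP/FP at Benjamini–Hochberg FDR 5%, mean adjusted p, and ROC AUC; matrix
diagnostics cover PC–batch adjusted R² and QC profile correlations.
See `docs/methods.md` for the full model and all estimators.

## Worked example

```python
import numpy as np
from batchbench import (CohortConfig, SimulationScenario, calibrate,
                        generate_base_cohort)
from batchbench.pipeline import run_replicate

base = generate_base_cohort(CohortConfig(n_genes=2000, seed=3))   # 251 subjects, 14 batches, 27 QCs
stats = calibrate(base)
scenario = SimulationScenario(effect_sd=0.3, n_effect_genes=500, gamma=2.72)
for res in run_replicate(base, stats, scenario,
                         ("lmm", "lm", "lm_batch", "eb_lm"),
                         np.random.default_rng(6)):
    print(f"{res.method:>8}: TP {res.tp:3d}  FP {res.fp:3d}  AUC {res.auc:.3f}")
```

```
     lmm: TP 500  FP  18  AUC 1.000
      lm: TP   0  FP   0  AUC 0.979
lm_batch: TP 500  FP  18  AUC 1.000
   eb_lm: TP 500  FP  15  AUC 1.000
```

With a modest effect (SD 0.3) under a large batch effect (γ = 2.72), every
batch-aware method finds all 500 effect genes with ~15–18 false positives
(close to the BH 5% target for ~518 calls), while uncorrected OLS finds
none in this replicate: the batch variance it fails to model inflates every
residual, drowning the signal. Averaged over replicates (driver `03`),
uncorrected OLS at SD 0.3 recovers only a fraction of the effect genes.

The numbered drivers under `analysis/` walk the full study: `01` generates
the cohort, `02` estimates the deconvolution parameters (γ, residual SDs,
QC factors), `03` runs the effect-size × QC-arm grid, `04` the
error/reduced/unbalanced design variants and the decile sweep of
confounding, `05` the denoising diagnostics (PC–batch R² drops from ≈ 1 to
the null −(b−1)/(m−b) ≈ −0.055; QC correlations rise from 0.977 to 0.997),
and `06` the saturation benchmark. Each prints what it found and writes
tables under `results/`.

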