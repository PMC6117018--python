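"""Design-variant simulations: residual error, reduced cohort, unbalanced.

Three add-on grids over the same machinery as the main grid:
  * error arm — per-observation noise at each gene's estimated residual SD;
  * reduced design — only the first 4 batches (85 subjects);
  * unbalanced design — treatment sorted across batches, 20% re-randomized,
    plus a sweep of the re-randomized fraction over deciles.
Writes tables under results/designs/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from batchbench import (CohortConfig, Design, RunConfig, SimulationScenario,
                        balance_anova, calibrate, generate_base_cohort,
                        inject_effects, run_study)
from batchbench.pipeline import run_replicate

ROOT = Path(__file__).resolve().parents[1] / "results"


def decile_sweep(args) -> pd.DataFrame:
    """TP/FP and ANOVA confounding p-value vs the re-randomized fraction."""
    base = generate_base_cohort(CohortConfig(n_genes=args.genes, seed=17))
    stats = calibrate(base)
    rows = []
    for frac in np.arange(0.0, 1.01, 0.1):
        sc = SimulationScenario(effect_sd=0.5, n_effect_genes=500, gamma=2.72,
                                design=Design(kind="unbalanced",
                                              random_fraction=float(frac)))
        tp, fp, pvals = [], [], []
        for rep in range(args.replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([args.seed, 50, rep]))
            sim = inject_effects(base, sc, stats, rng)
            pvals.append(balance_anova(sim.treatment.to_numpy(),
                                       sim.study_batch.to_numpy()))
            res = run_replicate(base, stats, sc, ("lmm",),
                                np.random.default_rng(
                                    np.random.SeedSequence([args.seed, 51, rep])),
                                replicate=rep)[0]
            tp.append(res.tp)
            fp.append(res.fp)
        rows.append({"random_fraction": round(float(frac), 1),
                     "mean_anova_p": float(np.mean(pvals)),
                     "mean_tp_lmm": float(np.mean(tp)),
                     "mean_fp_lmm": float(np.mean(fp))})
    return pd.DataFrame(rows)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--replicates", type=int, default=10)
    parser.add_argument("--genes", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    scenarios = []
    for sd in (0.1, 0.5, 1.0, 3.0):
        scenarios += [
            SimulationScenario(effect_sd=sd, n_effect_genes=500, gamma=2.72,
                               with_error=True, n_replicates=args.replicates,
                               label=f"error_sd{sd:g}"),
            SimulationScenario(effect_sd=sd, n_effect_genes=500, gamma=2.72,
                               design=Design(kind="reduced", first_k_batches=4),
                               n_replicates=args.replicates,
                               label=f"reduced_sd{sd:g}"),
            SimulationScenario(effect_sd=sd, n_effect_genes=500, gamma=2.72,
                               design=Design(kind="unbalanced"),
                               n_replicates=args.replicates,
                               label=f"unbalanced_sd{sd:g}"),
        ]
    cfg = RunConfig(cohort=CohortConfig(n_genes=args.genes),
                    scenarios=scenarios, output_dir=ROOT / "designs",
                    master_seed=args.seed)
    summary, _ = run_study(cfg)
    wide = summary.pivot(index="scenario", columns="method",
                         values=["mean_tp", "mean_fp"]).round(1)
    print(wide.to_string())

    sweep = decile_sweep(args)
    sweep.to_csv(ROOT / "designs" / "unbalanced_decile_sweep.tsv", sep="\t",
                 index=False, float_format="%.4g")
    print("\nRe-randomized fraction sweep (effect SD 0.5, LMM):")
    print(sweep.to_string(index=False))
    print("\nPattern check: sorted designs give ANOVA p ~ 0 and fewer TPs; "
          "randomization restores both.")


if __name__ == "__main__":
    main()
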