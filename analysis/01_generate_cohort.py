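"""Generate the desk-scale synthetic base cohort and describe its structure.

Emulates the study layout — 251 subjects in 14 batches with 27 QC technical
replicates (one batch holds a single QC) — at 2,000 genes, and writes the
expression matrix plus sample metadata as TSV under results/cohort/.
"""

from pathlib import Path

import numpy as np

from batchbench import CohortConfig, generate_base_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = CohortConfig(seed=20180830)
    cohort = generate_base_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, OUT / "expression.tsv", OUT / "samples.tsv")

    study = cohort.study()
    print(f"cohort: {cohort.n_genes} genes x {cohort.values.shape[1]} samples "
          f"({study.values.shape[1]} study, {cohort.qc().values.shape[1]} QC)")
    print(f"batches: {len(cohort.batches)}, sizes "
          f"{study.samples.groupby('batch', sort=False).size().tolist()}")
    vals = study.values.to_numpy()
    print(f"log2 intensity: mean {vals.mean():.2f}, per-gene SD "
          f"median {np.median(vals.std(axis=1)):.3f}")
    print(f"wrote {OUT}/expression.tsv and samples.tsv")


if __name__ == "__main__":
    main()
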