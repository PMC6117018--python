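"""Injection of known batch effects, treatment effects and noise into a cohort.

Each simulated dataset starts from a fixed base expression matrix and adds,
on the log2 scale:

* a per-batch shift ``r_j ~ N(0, gamma^2)`` shared by every sample in batch j
  (QC columns travel with their batch and receive it too);
* a per-subject treatment covariate ``T_l ~ N(0, SD^2)`` added with unit
  slope to a fixed set of "effect genes" (the first ``n_effect_genes`` rows)
  and with slope zero elsewhere — the same vector is later used as the
  regression covariate, so null genes have a true slope of exactly 0;
* optionally the QC drift term ``q_ij - tau_i`` measured on the base cohort
  (the arm in which QC calibration is part of the analysis);
* optionally per-observation noise ``e ~ N(0, sigma_ei^2)`` using the
  per-gene residual SDs from calibration.

Design variants rearrange the subject-to-batch assignment (treatment sorted
across batches with a fraction re-randomized), subset to the first k batches,
or regenerate the cohort on a per-batch-size grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import CalibrationStats
from .cohort import CohortConfig, ExpressionMatrix, generate_base_cohort

__all__ = [
    "Design",
    "SimulationScenario",
    "SimulatedDataset",
    "draw_batch_effects",
    "draw_treatment",
    "inject_effects",
    "make_unbalanced",
    "balance_anova",
    "subset_cohort",
]


@dataclass
class Design:
    """Subject-to-batch design variant.

    ``kind``: one of ``balanced``, ``unbalanced``, ``reduced``,
    ``batch_size_grid``.  ``random_fraction`` applies to ``unbalanced``
    (fraction of samples re-randomized after sorting treatment across
    batches); ``first_k_batches`` to ``reduced``; ``per_batch_size`` to
    ``batch_size_grid``.
    """

    kind: str = "balanced"
    random_fraction: float = 0.2
    first_k_batches: int = 4
    per_batch_size: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("balanced", "unbalanced", "reduced", "batch_size_grid"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if not 0.0 <= self.random_fraction <= 1.0:
            raise ValueError(f"random_fraction must be in [0,1], got {self.random_fraction}")


@dataclass
class SimulationScenario:
    """One cell of the simulation study."""

    effect_sd: float = 1.0
    n_effect_genes: int = 500
    gamma: float = 2.72
    with_error: bool = False
    with_qc_term: bool = False
    design: Design = field(default_factory=Design)
    n_replicates: int = 50
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.effect_sd < 0 or self.gamma < 0:
            raise ValueError("effect_sd and gamma must be >= 0")
        if self.n_effect_genes < 0:
            raise ValueError("n_effect_genes must be >= 0")


@dataclass
class SimulatedDataset:
    """A simulated matrix plus the ground truth that produced it."""

    matrix: ExpressionMatrix
    treatment: pd.Series            # indexed by study sample id
    effect_genes: pd.Index
    batch_effects: pd.Series        # indexed by batch label
    study_batch: pd.Series          # analysis batch label per study sample


def draw_batch_effects(gamma: float, n_batches: int,
                       rng: np.random.Generator | int) -> np.ndarray:
    """``n_batches`` iid N(0, gamma^2) batch shifts."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return rng.normal(0.0, gamma, size=n_batches)


def draw_treatment(m: int, sd: float, rng: np.random.Generator | int) -> np.ndarray:
    """Per-subject treatment values, N(0, sd^2); doubles as the covariate."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if m < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return rng.normal(0.0, sd, size=m)


def make_unbalanced(treatment: np.ndarray, batch_sizes: list[int],
                    batch_labels: list[str], fraction: float,
                    rng: np.random.Generator | int) -> np.ndarray:
    """Confound treatment with batch, then partially re-randomize.

    Samples sorted by treatment descending are assigned block-wise to
    batches (the first batch gets the highest values, the last the lowest;
    ties broken by a stable sort).  A uniformly chosen fraction of samples
    is then re-assigned by randomly permuting their labels among themselves.
    Returns one batch label per sample, aligned to ``treatment``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    m = len(treatment)
    if sum(batch_sizes) != m:
        raise ValueError("batch sizes must sum to the number of samples")
    order = np.argsort(-treatment, kind="stable")
    assignment = np.empty(m, dtype=object)
    pos = 0
    for size, label in zip(batch_sizes, batch_labels):
        assignment[order[pos:pos + size]] = label
        pos += size
    n_rand = int(round(fraction * m))
    if n_rand >= 2:
        chosen = rng.choice(m, size=n_rand, replace=False)
        assignment[chosen] = assignment[rng.permutation(chosen)]
    return assignment


def balance_anova(treatment: np.ndarray, batch_assignment: np.ndarray) -> float:
    """One-way ANOVA p-value of treatment grouped by batch."""
    groups = [treatment[batch_assignment == b]
              for b in pd.unique(pd.Series(batch_assignment))]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 batches, each with >= 1 sample")
    if np.ptp(treatment) == 0:
        return 1.0  # constant treatment: F = 0
    res = sps.f_oneway(*groups)
    if not np.isfinite(res.pvalue):
        raise ValueError("ANOVA undefined: zero within-group variance")
    return float(res.pvalue)


def subset_cohort(base: ExpressionMatrix, design: Design,
                  config: CohortConfig | None = None) -> ExpressionMatrix:
    """Apply a reduced or batch-size-grid design to the base cohort.

    ``reduced``: keep the first ``first_k_batches`` batches (study samples
    and QCs).  ``batch_size_grid``: regenerate the cohort with the same
    gene-level parameters but ``per_batch_size`` subjects in every batch
    (requires the originating config).  Other designs return the input.
    """
    if design.kind == "reduced":
        batches = base.batches
        k = design.first_k_batches
        if k > len(batches):
            raise ValueError(f"requested {k} batches, cohort has {len(batches)}")
        return base.subset_batches(batches[:k])
    if design.kind == "batch_size_grid":
        if config is None:
            raise ValueError("batch_size_grid requires the cohort config")
        import dataclasses
        new = dataclasses.replace(
            config,
            batch_sizes=[design.per_batch_size] * config.n_batches,
            seed=config.seed + 104729,  # distinct deterministic stream
        )
        return generate_base_cohort(new)
    return base


def inject_effects(base: ExpressionMatrix, scenario: SimulationScenario,
                   stats: CalibrationStats,
                   rng: np.random.Generator | int | None = None) -> SimulatedDataset:
    """Build one simulated replicate from the base cohort.

    The treatment is drawn first; under an unbalanced design the study
    samples are then re-assigned to batches so that batch order tracks
    treatment rank, before batch shifts are added.  QC columns keep their
    physical batch and receive its shift (no treatment, no subject error).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(scenario.seed if rng is None else rng)
    w = base.n_genes
    if scenario.n_effect_genes > w:
        raise ValueError(
            f"n_effect_genes={scenario.n_effect_genes} exceeds {w} genes")
    if not base.gene_ids.equals(stats.qc_batch_mean.index):
        raise ValueError("base cohort and calibration stats are misaligned")

    batches = base.batches
    study_mask = base.study_mask()
    study_ids = base.samples.index[study_mask]
    m = int(study_mask.sum())

    treatment = draw_treatment(m, scenario.effect_sd, rng)
    r = draw_batch_effects(scenario.gamma, len(batches), rng)
    r_series = pd.Series(r, index=batches, name="batch_effect")

    # analysis batch per study sample (possibly re-assigned)
    study_batch = base.samples.loc[study_mask, "batch"].to_numpy(dtype=object)
    if scenario.design.kind == "unbalanced":
        sizes = [int((study_batch == b).sum()) for b in batches]
        study_batch = make_unbalanced(treatment, sizes, batches,
                                      scenario.design.random_fraction, rng)

    values = base.values.to_numpy().copy()
    batch_of_col = base.samples["batch"].to_numpy(dtype=object)
    col_batch = batch_of_col.copy()
    col_batch[study_mask] = study_batch  # QCs keep physical batch

    batch_index = pd.Index(batches)
    col_j = batch_index.get_indexer(col_batch)
    values += r[np.newaxis, col_j]

    if scenario.with_qc_term:
        offset = stats.qc_log_offset().to_numpy()  # w x b
        values += offset[:, col_j]

    effect_genes = base.gene_ids[: scenario.n_effect_genes]
    study_cols = np.flatnonzero(study_mask)
    values[: scenario.n_effect_genes, study_cols] += treatment[np.newaxis, :]

    if scenario.with_error:
        if stats.residual_sd is None:
            raise ValueError("error arm requires residual SDs in the stats")
        sd = stats.residual_sd.to_numpy()[:, np.newaxis]
        values[:, study_cols] += rng.standard_normal((w, m)) * sd

    samples = base.samples.copy()
    samples["batch"] = col_batch
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=base.gene_ids, columns=base.values.columns),
        samples,
    )
    return SimulatedDataset(
        matrix=matrix,
        treatment=pd.Series(treatment, index=study_ids, name="treatment"),
        effect_genes=effect_genes,
        batch_effects=r_series,
        study_batch=pd.Series(study_batch, index=study_ids, name="batch"),
    )
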