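"""Synthetic log2 expression cohorts with batch structure and QC technical replicates.

The generator emulates a quantile-normalized two-color microarray study in
which hundreds of subjects are hybridized in batches, and a single reference
individual's blood sample ("QC subject") is re-measured once or twice per
batch as a technical replicate.  It stands in for real cohort data used to
parameterize downstream simulations: per-gene baseline means and residual
noise, a latent per-(gene, batch) technical offset, and near-duplicate QC
columns that differ only by technical noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ExpressionMatrix",
    "generate_base_cohort",
    "default_batch_sizes",
    "study_batch_sizes",
    "write_cohort",
    "read_cohort",
]

QC_SUBJECT_ID = "QC_subject"


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def default_batch_sizes(n_subjects: int = 251, n_batches: int = 14) -> list[int]:
    """Split ``n_subjects`` across ``n_batches`` as evenly as possible."""
    base = n_subjects // n_batches
    rem = n_subjects - base * n_batches
    return [base + 1] * rem + [base] * (n_batches - rem)


def study_batch_sizes() -> list[int]:
    """The emulated study layout: 251 subjects in 14 batches, front-loaded so
    the first four batches hold 85 subjects (the cohort's reduced design)."""
    sizes = [22, 21, 21, 21] + [17] * 6 + [16] * 4
    assert sum(sizes) == 251
    return sizes


@dataclass
class CohortConfig:
    """Parameters of the synthetic base cohort.

    Attributes
    ----------
    n_genes
        Number of probes (rows).
    batch_sizes
        Subjects per batch; the number of batches is ``len(batch_sizes)``.
    n_qc_per_batch
        QC technical replicates per batch (default 2).
    deficient_qc_batch
        Index of a batch that receives only a single QC (``None`` disables);
        default is the last batch, reproducing a study plan in which one
        batch lost a QC to quality filtering.
    gene_mean_mu, gene_mean_sd
        Normal parameters of per-gene baseline means (log2 units).
    gene_sd_logmu, gene_sd_logsigma, gene_sd_min, gene_sd_max
        Log-normal parameters of per-gene residual SDs, truncated to
        ``[gene_sd_min, gene_sd_max]`` (log2 units).
    latent_batch_sd
        SD of per-(gene, batch) technical offsets baked into the base data.
    qc_tech_sd
        SD of QC replicate technical noise.
    seed
        Seed for the generator; the cohort is a deterministic function of
        the full config.
    """

    n_genes: int = 2000
    batch_sizes: list[int] = field(default_factory=study_batch_sizes)
    n_qc_per_batch: int = 2
    deficient_qc_batch: int | None = -1
    gene_mean_mu: float = 7.0
    gene_mean_sd: float = 2.0
    gene_sd_logmu: float = float(np.log(0.25))
    gene_sd_logsigma: float = 0.5
    gene_sd_min: float = 0.05
    gene_sd_max: float = 1.0
    latent_batch_sd: float = 0.3
    qc_tech_sd: float = 0.1
    seed: int = 0

    @property
    def n_batches(self) -> int:
        return len(self.batch_sizes)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.batch_sizes))

    def qc_counts(self) -> list[int]:
        """QC replicates per batch, honouring the deficient batch."""
        counts = [self.n_qc_per_batch] * self.n_batches
        if self.deficient_qc_batch is not None:
            counts[self.deficient_qc_batch] = 1
        return counts

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_batches < 2:
            raise ConfigurationError(
                f"need >= 2 batches, got batch_sizes={self.batch_sizes}"
            )
        if any(s < 1 for s in self.batch_sizes):
            raise ConfigurationError(
                f"every batch needs >= 1 subject, got batch_sizes={self.batch_sizes}"
            )
        if self.n_qc_per_batch < 1:
            raise ConfigurationError(
                f"n_qc_per_batch must be >= 1, got {self.n_qc_per_batch}"
            )
        for name in ("latent_batch_sd", "qc_tech_sd", "gene_mean_sd",
                     "gene_sd_min", "gene_sd_max"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.gene_sd_min > self.gene_sd_max:
            raise ConfigurationError(
                f"gene_sd_min={self.gene_sd_min} exceeds gene_sd_max={self.gene_sd_max}"
            )
        if self.deficient_qc_batch is not None and not (
            -self.n_batches <= self.deficient_qc_batch < self.n_batches
        ):
            raise ConfigurationError(
                f"deficient_qc_batch={self.deficient_qc_batch} out of range "
                f"for {self.n_batches} batches"
            )


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensity matrix with per-sample metadata.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``samples`` is a DataFrame indexed by sample id with columns
    ``batch`` (str), ``is_qc`` (bool) and ``subject_id`` (str), in the same
    order as the value columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata must match value columns in order")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def batches(self) -> list[str]:
        # preserve first-appearance order
        return list(dict.fromkeys(self.samples["batch"]))

    def study_mask(self) -> np.ndarray:
        return (~self.samples["is_qc"]).to_numpy()

    def study(self) -> "ExpressionMatrix":
        """Sub-matrix of study (non-QC) samples."""
        keep = self.study_mask()
        return ExpressionMatrix(self.values.loc[:, keep], self.samples.loc[keep])

    def qc(self) -> "ExpressionMatrix":
        keep = ~self.study_mask()
        return ExpressionMatrix(self.values.loc[:, keep], self.samples.loc[keep])

    def subset_batches(self, batches: list[str]) -> "ExpressionMatrix":
        keep = self.samples["batch"].isin(batches).to_numpy()
        return ExpressionMatrix(self.values.loc[:, keep], self.samples.loc[keep])


def generate_base_cohort(config: CohortConfig) -> ExpressionMatrix:
    """Draw a base cohort from the generative model.

    Per gene i: baseline mean ``mu_i ~ N(gene_mean_mu, gene_mean_sd^2)`` and
    residual SD ``sigma_i`` from the truncated log-normal.  Per (gene, batch):
    a latent technical offset ``o_ij ~ N(0, latent_batch_sd^2)``.  A study
    sample in batch j is ``mu_i + o_ij + N(0, sigma_i^2)``; a QC replicate is
    ``mu_i^QC + o_ij + N(0, qc_tech_sd^2)`` where ``mu_i^QC = mu_i +
    N(0, sigma_i^2)`` is the single shared QC-subject profile (one draw from
    the same subject population, measured repeatedly).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w = config.n_genes
    b = config.n_batches

    mu, sigma = draw_gene_params(config, rng)
    offsets = rng.normal(0.0, config.latent_batch_sd, size=(w, b))
    mu_qc = mu + rng.standard_normal(w) * sigma

    qc_counts = config.qc_counts()
    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    batch_lab: list[str] = []
    is_qc: list[bool] = []
    subject: list[str] = []
    subj_counter = 0
    for j, (n_sub, n_qc) in enumerate(zip(config.batch_sizes, qc_counts)):
        batch_name = f"B{j + 1:02d}"
        for _ in range(n_sub):
            subj_counter += 1
            cols.append(mu + offsets[:, j] + rng.standard_normal(w) * sigma)
            sample_ids.append(f"S{subj_counter:04d}")
            batch_lab.append(batch_name)
            is_qc.append(False)
            subject.append(f"subj{subj_counter:04d}")
        for k in range(n_qc):
            cols.append(mu_qc + offsets[:, j]
                        + rng.standard_normal(w) * config.qc_tech_sd)
            sample_ids.append(f"QC_{batch_name}_{k + 1}")
            batch_lab.append(batch_name)
            is_qc.append(True)
            subject.append(QC_SUBJECT_ID)

    values = pd.DataFrame(
        np.column_stack(cols),
        index=pd.Index([f"gene{i + 1:05d}" for i in range(w)], name="gene_id"),
        columns=sample_ids,
    )
    samples = pd.DataFrame(
        {"batch": batch_lab, "is_qc": is_qc, "subject_id": subject},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(values, samples)


def draw_gene_params(config: CohortConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene baseline means and residual SDs for a cohort config.

    Exposed so ground-truth parameters can be reproduced from the seed
    (``generate_base_cohort`` draws these first from a fresh generator).
    """
    mu = rng.normal(config.gene_mean_mu, config.gene_mean_sd, size=config.n_genes)
    sigma = _truncated_lognormal(
        rng, config.n_genes, config.gene_sd_logmu, config.gene_sd_logsigma,
        config.gene_sd_min, config.gene_sd_max,
    )
    return mu, sigma


def _truncated_lognormal(rng: np.random.Generator, n: int, logmu: float,
                         logsigma: float, lo: float, hi: float) -> np.ndarray:
    """Log-normal draws rejected into [lo, hi] (clipping would pile mass at
    the bounds and bias downstream SD-recovery checks)."""
    if lo == hi:
        return np.full(n, lo)
    out = np.exp(rng.normal(logmu, logsigma, size=n))
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.exp(rng.normal(logmu, logsigma, size=int(bad.sum())))
        bad = (out < lo) | (out > hi)
    return out


def write_cohort(matrix: ExpressionMatrix, values_path: str | Path,
                 samples_path: str | Path) -> None:
    """Write the matrix and metadata as tab-delimited text (6 decimals)."""
    matrix.values.to_csv(values_path, sep="\t", float_format="%.6f")
    matrix.samples.to_csv(samples_path, sep="\t")


def read_cohort(values_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    samples["is_qc"] = samples["is_qc"].astype(bool)
    return ExpressionMatrix(values, samples)
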