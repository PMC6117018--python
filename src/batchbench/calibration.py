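"""QC technical-replicate calibration and deconvolution parameter estimation.

A reference sample measured in every batch exposes batch-to-batch drift.  Per
gene i and batch j the calibration factor is the ratio of that batch's QC
mean to the all-batch QC mean (raw intensity scale), or equivalently on the
log2 scale the difference ``q_ij - tau_i`` between the batch QC mean and the
grand QC mean.  Applying the factor to study samples removes the drift the
QCs witnessed.

From a QC-corrected cohort we then deconvolve the quantities that drive the
simulation engine: per-(gene, batch) means, per-gene grand means, the
batch-effect SD ``gamma`` (root mean square of batch-mean deviations from the
grand mean across all genes and batches), and per-gene residual SDs of
subject-level deviations about their batch means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix

__all__ = [
    "CalibrationStats",
    "CalibrationError",
    "compute_qc_stats",
    "apply_qc_calibration",
    "compute_batch_means",
    "estimate_gamma",
    "estimate_residual_sd",
    "calibrate",
]


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationStats:
    """Per-gene calibration factors and deconvolution estimates.

    ``qc_batch_mean`` (genes x batches): batch mean of QC log2 values.
    ``qc_grand_mean`` (genes): mean over all individual QC measurements.
    ``qc_factor_raw`` (genes x batches): raw-intensity-scale ratio factor.
    ``batch_mean`` (genes x batches): per-batch mean of QC-corrected study
    samples.  ``grand_mean`` (genes): unweighted mean of batch means.
    ``gamma``: scalar batch-effect SD (log2).  ``residual_sd`` (genes):
    SD of subject residuals about batch means (log2).
    """

    qc_batch_mean: pd.DataFrame
    qc_grand_mean: pd.Series
    qc_factor_raw: pd.DataFrame
    batch_mean: pd.DataFrame | None = None
    grand_mean: pd.Series | None = None
    gamma: float | None = None
    residual_sd: pd.Series | None = None

    @property
    def batches(self) -> list[str]:
        return list(self.qc_batch_mean.columns)

    def qc_log_offset(self) -> pd.DataFrame:
        """Log2-scale correction term ``q_ij - tau_i`` (genes x batches)."""
        return self.qc_batch_mean.sub(self.qc_grand_mean, axis=0)

    def to_files(self, long_path: str | Path, scalars_path: str | Path) -> None:
        """Serialize to a long-format TSV plus a JSON scalar block."""
        frames = {"qc_batch_mean": self.qc_batch_mean,
                  "qc_factor_raw": self.qc_factor_raw}
        if self.batch_mean is not None:
            frames["batch_mean"] = self.batch_mean
        long = pd.concat(
            {k: v.stack() for k, v in frames.items()}, axis=1
        ).reset_index()
        long.columns = ["gene_id", "batch", *frames.keys()]
        per_gene = pd.DataFrame({"qc_grand_mean": self.qc_grand_mean})
        if self.grand_mean is not None:
            per_gene["grand_mean"] = self.grand_mean
        if self.residual_sd is not None:
            per_gene["residual_sd"] = self.residual_sd
        long = long.merge(per_gene.reset_index(names="gene_id"), on="gene_id")
        long.to_csv(long_path, sep="\t", index=False, float_format="%.8g")
        scalars = {"gamma": self.gamma, "b": len(self.batches),
                   "w": int(self.qc_batch_mean.shape[0])}
        Path(scalars_path).write_text(json.dumps(scalars, indent=2))


def compute_qc_stats(matrix: ExpressionMatrix) -> CalibrationStats:
    """Per-batch QC means, the grand QC mean, and raw-scale factors.

    The grand mean ``tau_i`` averages over all individual QC measurements
    (so a batch with one QC contributes one value, not a half-weighted
    pair).  The raw-scale factor divides the arithmetic mean of raw
    (``2**log2``) batch QC intensities by the arithmetic mean over all QCs;
    on data with identical replicates within a batch the log of this ratio
    equals the log2-mean difference, otherwise the two differ by the
    arithmetic-vs-geometric mean gap.
    """
    qc = matrix.qc()
    if qc.values.shape[1] == 0:
        raise CalibrationError("no QC samples in matrix")
    batches = matrix.batches
    present = set(qc.samples["batch"])
    missing = [b for b in batches if b not in present]
    if missing:
        raise CalibrationError(f"batch(es) without any QC sample: {missing}")

    grouped = qc.values.T.groupby(qc.samples["batch"], sort=False)
    q_batch = grouped.mean().T[batches]
    tau = qc.values.mean(axis=1)

    raw = np.power(2.0, qc.values)
    raw_batch = raw.T.groupby(qc.samples["batch"], sort=False).mean().T[batches]
    raw_grand = raw.mean(axis=1)
    factor = raw_batch.div(raw_grand, axis=0)

    q_batch.columns.name = "batch"
    factor.columns.name = "batch"
    return CalibrationStats(qc_batch_mean=q_batch, qc_grand_mean=tau,
                            qc_factor_raw=factor)


def apply_qc_calibration(matrix: ExpressionMatrix, stats: CalibrationStats,
                         scale: str = "log") -> ExpressionMatrix:
    """Apply the QC calibration to every sample (study and QC columns).

    ``scale="log"``: subtract ``q_ij - tau_i`` from each batch-j column.
    ``scale="raw"``: divide raw intensities by the ratio factor and re-log.
    """
    if scale not in ("log", "raw"):
        raise ValueError(f"scale must be 'log' or 'raw', got {scale!r}")
    missing = [b for b in matrix.batches if b not in stats.batches]
    if missing:
        raise CalibrationError(f"no calibration stats for batch(es): {missing}")
    if not matrix.gene_ids.equals(stats.qc_batch_mean.index):
        raise CalibrationError("gene universe mismatch between matrix and stats")

    batch_of = matrix.samples["batch"].to_numpy()
    if scale == "log":
        offset = stats.qc_log_offset().loc[:, batch_of].to_numpy()
        corrected = matrix.values.to_numpy() - offset
    else:
        factor = stats.qc_factor_raw.loc[:, batch_of].to_numpy()
        corrected = np.log2(np.power(2.0, matrix.values.to_numpy()) / factor)
    values = pd.DataFrame(corrected, index=matrix.gene_ids,
                          columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples)


def compute_batch_means(matrix: ExpressionMatrix,
                        stats: CalibrationStats | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-batch means of QC-corrected study samples and their grand mean.

    Each batch mean divides by that batch's own subject count (a true mean);
    the grand mean is the unweighted average of batch means, so deviations
    from it sum to zero over batches for every gene.  With ``stats=None``
    the QC correction is skipped, giving raw batch means — the quantity to
    use when the drift of interest is itself visible to the QCs (QC
    correction absorbs any batch shift the technical replicates share, so
    corrected batch means measure only the drift the QCs missed).
    """
    if stats is not None:
        matrix = apply_qc_calibration(matrix, stats, scale="log")
    corrected = matrix.study()
    if corrected.values.shape[1] == 0:
        raise CalibrationError("no study samples present")
    counts = corrected.samples["batch"].value_counts()
    empty = [b for b in matrix.batches if counts.get(b, 0) == 0]
    if empty:
        raise CalibrationError(f"batch(es) without study samples: {empty}")
    mu = (corrected.values.T.groupby(corrected.samples["batch"], sort=False)
          .mean().T[matrix.batches])
    mu.columns.name = "batch"
    return mu, mu.mean(axis=1)


def estimate_gamma(batch_mean: pd.DataFrame, grand_mean: pd.Series) -> float:
    """Batch-effect SD: RMS of batch-mean deviations pooled over genes.

    gamma = sqrt( (1/(b*w)) * sum_i sum_j (mu_ij - mu*_i)^2 ), the population
    form with no degrees-of-freedom correction.
    """
    b = batch_mean.shape[1]
    if b < 2:
        raise CalibrationError("gamma is undefined with a single batch")
    dev = batch_mean.sub(grand_mean, axis=0).to_numpy()
    return float(np.sqrt(np.mean(dev ** 2)))


def estimate_residual_sd(matrix: ExpressionMatrix,
                         stats: CalibrationStats | None = None,
                         batch_mean: pd.DataFrame | None = None) -> pd.Series:
    """Per-gene SD of subject residuals about their batch means.

    Residual = (optionally QC-corrected) study value minus its batch mean;
    the SD is the population SD (divide by m) of those residuals about
    their own mean, per gene.  Centering about batch means keeps batch
    structure out of the residual noise, which the simulator later adds on
    top of fresh batch effects.
    """
    if stats is not None:
        matrix = apply_qc_calibration(matrix, stats, scale="log")
    corrected = matrix.study()
    m = corrected.values.shape[1]
    if m < 2:
        raise CalibrationError(f"need >= 2 study samples, got {m}")
    if batch_mean is None:
        batch_mean, _ = compute_batch_means(matrix, stats=None)
    batch_of = corrected.samples["batch"].to_numpy()
    resid = corrected.values.to_numpy() - batch_mean.loc[:, batch_of].to_numpy()
    resid = resid - resid.mean(axis=1, keepdims=True)
    return pd.Series(np.sqrt(np.mean(resid ** 2, axis=1)),
                     index=matrix.gene_ids, name="residual_sd")


def calibrate(matrix: ExpressionMatrix) -> CalibrationStats:
    """Full deconvolution: QC stats, batch/grand means, gamma, residual SDs."""
    stats = compute_qc_stats(matrix)
    stats.batch_mean, stats.grand_mean = compute_batch_means(matrix, stats)
    stats.gamma = estimate_gamma(stats.batch_mean, stats.grand_mean)
    stats.residual_sd = estimate_residual_sd(matrix, stats, stats.batch_mean)
    return stats
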