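"""Turning per-gene p-values and ground truth into study summary metrics.

Given a known effect-gene set, a replicate's per-gene p-values become: BH
(step-up) adjusted p-values, true/false positive counts at the 5% FDR
threshold, mean adjusted p among the called genes, and the ROC AUC of the
p-value ranking against the effect labels.  Matrix-level diagnostics
measure how much batch structure a correction left behind: adjusted R^2 of
a one-way batch fit on each leading principal component, and pairwise
Pearson correlation of the QC technical-replicate profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionMatrix

__all__ = [
    "bh_adjust",
    "score_detection",
    "roc_auc",
    "pc_batch_association",
    "qc_pearson_matrix",
    "ReplicateResult",
    "summarize_replicates",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    NaN entries are excluded from the ranking and returned as NaN.
    """
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        vals = p[ok]
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(vals, method="fdr_bh")[1]
    return out


@dataclass
class DetectionScore:
    tp: int
    fp: int
    mean_fdrval_tp: float
    mean_fdrval_fp: float


def score_detection(adjusted: np.ndarray, effect_mask: np.ndarray,
                    alpha: float = 0.05) -> DetectionScore:
    """TP/FP counts at threshold ``alpha`` and mean adjusted p per call set."""
    adjusted = np.asarray(adjusted, float)
    effect_mask = np.asarray(effect_mask, bool)
    if adjusted.shape != effect_mask.shape:
        raise ValueError("adjusted p and effect mask must align")
    called = adjusted < alpha
    tp_set = called & effect_mask
    fp_set = called & ~effect_mask
    return DetectionScore(
        tp=int(tp_set.sum()),
        fp=int(fp_set.sum()),
        mean_fdrval_tp=float(adjusted[tp_set].mean()) if tp_set.any() else float("nan"),
        mean_fdrval_fp=float(adjusted[fp_set].mean()) if fp_set.any() else float("nan"),
    )


def roc_auc(p: np.ndarray, effect_mask: np.ndarray) -> float:
    """AUC of the ranking by ascending p-value (ties count half).

    Equals the normalized Mann–Whitney U statistic.  Failed fits (NaN p)
    are ranked last, i.e. least significant.
    """
    p = np.asarray(p, float)
    effect_mask = np.asarray(effect_mask, bool)
    if effect_mask.all() or not effect_mask.any():
        raise ValueError("AUC needs both effect and null genes")
    score = np.where(np.isfinite(p), -p, -np.inf)
    return float(roc_auc_score(effect_mask, score))


def _adjusted_r2_oneway(y: np.ndarray, batch_idx: np.ndarray, b: int) -> float:
    m = len(y)
    grand = y.mean()
    sst = ((y - grand) ** 2).sum()
    if sst == 0:
        return float("nan")
    means = np.bincount(batch_idx, weights=y, minlength=b) / np.bincount(
        batch_idx, minlength=b)
    ssb = (np.bincount(batch_idx, minlength=b) * (means - grand) ** 2).sum()
    r2 = ssb / sst
    return float(1.0 - (1.0 - r2) * (m - 1) / (m - b))


def pc_batch_association(matrix: ExpressionMatrix, n_pcs: int = 5,
                         study_only: bool = True) -> pd.Series:
    """Adjusted R^2 of a one-way batch fit on each leading PC score vector.

    PCA is on gene-wise-centered values (no variance scaling; expression is
    already on a common log2 scale).  Under no association the adjusted R^2
    is negative with expectation -(b-1)/(m-b); values near 1 mean a PC is
    essentially a batch readout.
    """
    mat = matrix.study() if study_only else matrix
    Y = mat.values.to_numpy()
    batch = mat.samples["batch"].to_numpy()
    labels = list(pd.unique(pd.Series(batch)))
    b = len(labels)
    m = Y.shape[1]
    if m <= b:
        raise ValueError(f"need more samples ({m}) than batches ({b})")
    n_pcs = min(n_pcs, min(Y.shape))
    centered = Y - Y.mean(axis=1, keepdims=True)
    # scores = right singular vectors scaled by singular values
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = (s[:n_pcs, None] * vt[:n_pcs]).T          # m x n_pcs
    idx = pd.Index(labels).get_indexer(batch)
    vals = [_adjusted_r2_oneway(scores[:, k], idx, b) for k in range(n_pcs)]
    return pd.Series(vals, index=[f"PC{k + 1}" for k in range(n_pcs)],
                     name="adjusted_r2")


def qc_pearson_matrix(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, dict]:
    """All pairwise Pearson correlations between QC expression profiles.

    Returns the correlation matrix and a summary (mean and min over the
    off-diagonal pairs).  Zero-variance profiles yield NaN entries, which
    are excluded from the summary.
    """
    qc = matrix.qc()
    n = qc.values.shape[1]
    if n < 2:
        raise ValueError("need >= 2 QC columns")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(qc.values.to_numpy().T)
    frame = pd.DataFrame(corr, index=qc.values.columns, columns=qc.values.columns)
    pairs = corr[np.triu_indices(n, k=1)]
    finite = pairs[np.isfinite(pairs)]
    summary = {
        "mean": float(finite.mean()) if finite.size else float("nan"),
        "min": float(finite.min()) if finite.size else float("nan"),
        "n_pairs": int(pairs.size),
        "n_nan_pairs": int(pairs.size - finite.size),
    }
    return frame, summary


@dataclass
class ReplicateResult:
    """Evaluation of one method on one simulated replicate."""

    scenario: str
    method: str
    replicate: int
    tp: int
    fp: int
    mean_fdrval_tp: float
    mean_fdrval_fp: float
    auc: float
    n_effect_genes: int
    n_genes: int


def summarize_replicates(results: list[ReplicateResult]) -> pd.DataFrame:
    """Average TP/FP/mean-FDR/AUC over replicates per (scenario, method)."""
    if not results:
        raise ValueError("no replicate results to summarize")
    rows = []
    for r in results:
        if not 0 <= r.tp <= r.n_effect_genes:
            raise ValueError(
                f"TP={r.tp} outside [0, {r.n_effect_genes}] in {r.scenario}/{r.method}")
        if not 0 <= r.fp <= r.n_genes - r.n_effect_genes:
            raise ValueError(
                f"FP={r.fp} outside [0, {r.n_genes - r.n_effect_genes}]"
                f" in {r.scenario}/{r.method}")
        rows.append(vars(r))
    frame = pd.DataFrame(rows)
    grouped = frame.groupby(["scenario", "method"], sort=False)
    out = grouped.agg(
        mean_tp=("tp", "mean"),
        mean_fp=("fp", "mean"),
        mean_fdrval_tp=("mean_fdrval_tp", lambda s: s.dropna().mean()),
        mean_fdrval_fp=("mean_fdrval_fp", lambda s: s.dropna().mean()),
        auc=("auc", "mean"),
        n_replicates=("replicate", "size"),
    ).reset_index()
    return out


def format_results_table(summary: pd.DataFrame, meta: dict) -> pd.DataFrame:
    """Pivot a summary into the wide layout of the study's result tables.

    One row per scenario with columns Norm, QCs, Subjects, N Batches,
    Effect, N effect genes, Gamma, Error, then TP/FP per method.
    """
    wide = summary.pivot(index="scenario", columns="method",
                         values=["mean_tp", "mean_fp"])
    wide.columns = [f"{'TP' if a == 'mean_tp' else 'FP'}_{b}" for a, b in wide.columns]
    front = pd.DataFrame(meta).set_index("scenario")
    return front.join(wide).reset_index()
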