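import numpy as np
import pandas as pd
import pytest

from batchbench import CohortConfig, ExpressionMatrix, calibrate, generate_base_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for fast unit tests: 120 genes, 4 batches of 6."""
    cfg = CohortConfig(n_genes=120, batch_sizes=[6, 6, 6, 6], seed=101)
    return generate_base_cohort(cfg)


@pytest.fixture(scope="session")
def full_cohort():
    """Desk-scale cohort with the full study layout: 251 subjects, 14 batches,
    27 QCs (one batch has a single QC)."""
    cfg = CohortConfig(n_genes=300, seed=202)
    return generate_base_cohort(cfg)


@pytest.fixture(scope="session")
def full_stats(full_cohort):
    return calibrate(full_cohort)


def make_matrix(values, batches, is_qc, gene_ids=None):
    """Assemble an ExpressionMatrix from plain arrays (tests' hand cases)."""
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[1]
    ids = [f"s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "batch": list(batches),
            "is_qc": list(is_qc),
            "subject_id": ["QC_subject" if q else f"subj{i}"
                           for i, q in enumerate(is_qc)],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    frame = pd.DataFrame(
        values,
        index=gene_ids if gene_ids is not None
        else [f"g{i}" for i in range(values.shape[0])],
        columns=ids,
    )
    return ExpressionMatrix(frame, samples)
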