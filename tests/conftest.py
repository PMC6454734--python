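import numpy as np
import pandas as pd
import pytest

from cometa import ExpressionStudy, SyntheticConfig, generate_disease, meta_analyze
from cometa.studies import METADATA_COLUMNS


def make_study(
    values: np.ndarray,
    groups: list[str],
    study_id: str = "s0",
    gene_ids: list[str] | None = None,
    patient_ids: list[str] | None = None,
    platform: str = "continuous",
    sample_ids: list[str] | None = None,
    sexes: list[str] | None = None,
) -> ExpressionStudy:
    """Construct a small study with minimal boilerplate."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"{study_id}_x{i}" for i in range(n_samples)]
    patient_ids = patient_ids or [f"p{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "group": groups,
            "age": 30.0,
            "sex": sexes if sexes else (["M", "F"] * n_samples)[:n_samples],
            "pmi": 15.0,
            "batch": study_id,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )[METADATA_COLUMNS]
    return ExpressionStudy(
        study_id, pd.DataFrame(values, index=gene_ids, columns=sample_ids), meta, platform
    )


@pytest.fixture(scope="session")
def planted_disease():
    """One default-condition disease with planted truth (seed 0), reused."""
    studies, truth = generate_disease(SyntheticConfig(seed=0), disease_id="dz")
    return studies, truth


@pytest.fixture(scope="session")
def planted_meta(planted_disease):
    studies, truth = planted_disease
    return meta_analyze(studies, disease_id="dz"), truth


@pytest.fixture(scope="session")
def null_meta():
    """Meta-analysis of a disease with no planted signal."""
    studies, _ = generate_disease(
        SyntheticConfig(seed=0, frac_de=0.0), disease_id="null_dz"
    )
    return meta_analyze(studies, disease_id="null_dz")
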