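import numpy as np
import pandas as pd
import pytest

from regionsig import ExpressionCohort, SignatureModel


def build_cohort(matrix: dict, samples: list, tpm: dict | None = None) -> ExpressionCohort:
    """Build a cohort from {gene: [values per sample]} and
    [(sample_id, patient_id, region_id), ...]."""
    sample_ids = [s[0] for s in samples]
    mat = pd.DataFrame(matrix, index=sample_ids).T
    sheet = pd.DataFrame(
        {"patient_id": [s[1] for s in samples], "region_id": [s[2] for s in samples]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    tpm_df = pd.DataFrame(tpm, index=sample_ids).T if tpm is not None else None
    return ExpressionCohort(mat, sheet, tpm_df)


@pytest.fixture
def simple_signature() -> SignatureModel:
    return SignatureModel(
        name="toy",
        genes=("A", "B", "C"),
        weights=(1.0, 2.0, -0.5),
        risk_threshold=5.0,
    )


@pytest.fixture
def two_patient_cohort() -> ExpressionCohort:
    samples = [
        ("s1", "p1", "R1"),
        ("s2", "p1", "R2"),
        ("s3", "p2", "R1"),
        ("s4", "p2", "R2"),
    ]
    matrix = {
        "A": [1.0, 2.0, 3.0, 4.0],
        "B": [2.0, 2.0, 1.0, 1.0],
        "C": [0.0, 2.0, 4.0, 6.0],
    }
    return build_cohort(matrix, samples)
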