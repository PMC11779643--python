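"""Expression cohorts: a genes x samples matrix plus region/patient mapping."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["ExpressionCohort", "read_matrix", "read_sample_sheet"]


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples matrix (first column gene id; TSV or CSV)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    mat = pd.read_csv(path, sep=sep, index_col=0)
    mat.index = mat.index.astype(str)
    return mat


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet with columns sample_id, patient_id, region_id."""
    sep = "," if str(path).endswith(".csv") else "\t"
    sheet = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "patient_id", "region_id"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet.set_index("sample_id")


@dataclass
class ExpressionCohort:
    """Normalized expression for tumor regions across patients.

    Attributes
    ----------
    matrix : pd.DataFrame
        Genes (rows) x samples (columns), normalized expression values.
    samples : pd.DataFrame
        Indexed by sample_id, with columns ``patient_id`` and ``region_id``.
    tpm : pd.DataFrame, optional
        Same shape as ``matrix``; used only by the low-expression filter.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    tpm: pd.DataFrame | None = None

    def __post_init__(self):
        if not {"patient_id", "region_id"}.issubset(self.samples.columns):
            raise ValidationError("samples needs patient_id and region_id columns")
        sample_ids = list(self.samples.index)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids in sample sheet")
        missing = set(sample_ids) - set(self.matrix.columns)
        if missing:
            raise ValidationError(f"samples missing from matrix: {sorted(missing)[:5]}")
        # align column order to the sample sheet
        self.matrix = self.matrix[sample_ids]
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values")
        pairs = list(zip(self.samples["patient_id"], self.samples["region_id"]))
        if len(set(pairs)) != len(pairs):
            raise ValidationError("(patient_id, region_id) pairs must be unique")
        if self.tpm is not None:
            tpm_missing = set(sample_ids) - set(self.tpm.columns)
            if tpm_missing:
                raise ValidationError("tpm layer missing samples present in matrix")
            self.tpm = self.tpm.reindex(index=self.matrix.index, columns=sample_ids)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def patients(self) -> list:
        return list(pd.unique(self.samples["patient_id"]))

    def regions_of(self, patient_id) -> list:
        mask = self.samples["patient_id"] == patient_id
        return list(self.samples.index[mask])

    def multiregion_patients(self) -> list:
        counts = self.samples.groupby("patient_id", sort=False).size()
        return list(counts.index[counts >= 2])

    def subset_genes(self, genes) -> "ExpressionCohort":
        genes = [g for g in genes if g in self.matrix.index]
        if not genes:
            raise ValidationError("no requested genes present in matrix")
        tpm = self.tpm.loc[genes] if self.tpm is not None else None
        return ExpressionCohort(self.matrix.loc[genes], self.samples.copy(), tpm)

    @classmethod
    def from_files(cls, expr_path, samples_path, tpm_path=None) -> "ExpressionCohort":
        matrix = read_matrix(expr_path)
        samples = read_sample_sheet(samples_path)
        tpm = read_matrix(tpm_path) if tpm_path is not None else None
        return cls(matrix, samples, tpm)

    def to_files(self, expr_path, samples_path, tpm_path=None):
        self.matrix.to_csv(expr_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")
        if tpm_path is not None and self.tpm is not None:
            self.tpm.to_csv(tpm_path, sep="\t", index_label="gene")


def _ensure_cohort(obj) -> ExpressionCohort:
    if not isinstance(obj, ExpressionCohort):
        raise TypeError("expected an ExpressionCohort")
    return obj
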