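"""Region-level risk scoring, batch correction and risk-class aggregation.

Scores are weighted sums of signature-gene expression. A fixed threshold
dichotomizes corrected scores into low/high risk per region; a patient whose
regions carry both labels is discordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .exceptions import CoverageError, ValidationError
from .signature import SignatureModel

__all__ = [
    "RiskProfile",
    "filter_low_expression",
    "score_regions",
    "apply_batch_correction",
    "classify_and_aggregate",
    "score_cohort",
    "LOW",
    "HIGH",
    "CONCORDANT_LOW",
    "CONCORDANT_HIGH",
    "DISCORDANT",
]

logger = logging.getLogger(__name__)

LOW = "low"
HIGH = "high"
CONCORDANT_LOW = "concordant-low"
CONCORDANT_HIGH = "concordant-high"
DISCORDANT = "discordant"


@dataclass
class RiskProfile:
    """Per-region scores/classes and the per-patient aggregate.

    ``region_scores`` is indexed by sample_id with columns ``patient_id``,
    ``region_id``, ``raw_score`` and, once the respective steps have run,
    ``corrected_score`` and ``risk_class``. ``patient_summary`` is indexed by
    patient_id with columns ``mean_score``, ``n_regions``, ``risk_class``.
    """

    signature: SignatureModel
    region_scores: pd.DataFrame
    coverage: float
    missing_genes: tuple = ()
    patient_summary: pd.DataFrame | None = None

    @property
    def scores(self) -> pd.Series:
        """Corrected scores if available, else raw scores."""
        if "corrected_score" in self.region_scores:
            return self.region_scores["corrected_score"]
        return self.region_scores["raw_score"]


def filter_low_expression(
    cohort: ExpressionCohort, min_tpm: float = 1.0, max_low_fraction: float = 0.2
) -> ExpressionCohort:
    """Drop genes whose TPM falls below ``min_tpm`` in at least
    ``max_low_fraction`` of samples.

    A gene is retained iff the fraction of samples with TPM < ``min_tpm``
    is strictly below ``max_low_fraction``. The sample set is unchanged.
    """
    if cohort.tpm is None:
        raise ValidationError(
            "cohort has no TPM layer; skip filter_low_expression or supply one"
        )
    if not min_tpm > 0:
        raise ValidationError("min_tpm must be positive")
    if not 0 < max_low_fraction <= 1:
        raise ValidationError("max_low_fraction must lie in (0, 1]")
    low_frac = (cohort.tpm < min_tpm).mean(axis=1)
    keep = low_frac.index[low_frac < max_low_fraction]
    if len(keep) == 0:
        raise ValidationError("low-expression filter removed every gene")
    tpm = cohort.tpm.loc[keep]
    return ExpressionCohort(cohort.matrix.loc[keep], cohort.samples.copy(), tpm)


def score_regions(cohort: ExpressionCohort, sig: SignatureModel) -> RiskProfile:
    """Compute raw per-region scores: sum of weight x expression over the
    signature genes present in the cohort.

    Missing genes are simply omitted from the sum (no weight re-normalization);
    a warning is logged when coverage drops below 1.
    """
    present = [g for g in sig.genes if g in cohort.matrix.index]
    missing = tuple(g for g in sig.genes if g not in cohort.matrix.index)
    coverage = len(present) / sig.size
    if coverage < sig.min_coverage:
        raise CoverageError(
            f"signature '{sig.name}': only {len(present)}/{sig.size} genes present "
            f"(coverage {coverage:.2f} < {sig.min_coverage}); missing: {list(missing)}",
            missing_genes=missing,
        )
    if missing:
        logger.warning(
            "signature '%s': %d/%d genes missing (%s); scoring over available genes",
            sig.name, len(missing), sig.size, ", ".join(missing[:5]),
        )
    wmap = sig.weight_map
    weights = np.array([wmap[g] for g in present], dtype=float)
    expr = cohort.matrix.loc[present].to_numpy(dtype=float)
    raw = weights @ expr
    table = pd.DataFrame(
        {
            "patient_id": cohort.samples["patient_id"].to_numpy(),
            "region_id": cohort.samples["region_id"].to_numpy(),
            "raw_score": raw,
        },
        index=cohort.samples.index.copy(),
    )
    return RiskProfile(sig, table, coverage, missing)


def apply_batch_correction(scores, sig: SignatureModel):
    """Affine-correct raw scores: corrected = slope * raw + intercept.

    Accepts a :class:`RiskProfile` (returns a new profile with a
    ``corrected_score`` column) or any array-like of raw scores (returns the
    corrected array).
    """
    if isinstance(scores, RiskProfile):
        table = scores.region_scores.copy()
        table["corrected_score"] = sig.correct(table["raw_score"].to_numpy())
        return replace(scores, region_scores=table)
    return sig.correct(scores)


def classify_and_aggregate(profile: RiskProfile, sig: SignatureModel | None = None) -> RiskProfile:
    """Assign region risk classes and build the patient summary.

    A region is high risk iff its corrected score is strictly greater than
    the signature threshold (scores exactly equal to the threshold are low
    risk). A patient is concordant-X when all regions are class X, otherwise
    discordant; single-region patients are concordant by construction. The
    patient mean score is the arithmetic mean of its regions' corrected
    scores.
    """
    sig = sig or profile.signature
    table = profile.region_scores.copy()
    if "corrected_score" not in table:
        raise ValidationError(
            "corrected scores missing; run apply_batch_correction first "
            "(use identity slope/intercept if no correction is wanted)"
        )
    table["risk_class"] = np.where(
        table["corrected_score"] > sig.risk_threshold, HIGH, LOW
    )
    grouped = table.groupby("patient_id", sort=False)
    sizes = grouped.size()
    if (sizes == 0).any():
        raise ValidationError("patient with zero regions")
    mean_score = grouped["corrected_score"].mean()
    n_high = grouped["risk_class"].apply(lambda c: int((c == HIGH).sum()))
    patient_class = pd.Series(DISCORDANT, index=sizes.index, dtype=object)
    patient_class[n_high == 0] = CONCORDANT_LOW
    patient_class[n_high == sizes] = CONCORDANT_HIGH
    summary = pd.DataFrame(
        {"mean_score": mean_score, "n_regions": sizes, "risk_class": patient_class}
    )
    summary.index.name = "patient_id"
    return replace(profile, region_scores=table, patient_summary=summary)


def score_cohort(
    cohort: ExpressionCohort, sig: SignatureModel, batch_correct: bool = True
) -> RiskProfile:
    """Full scoring pipeline: raw scores, optional batch correction,
    classification and per-patient aggregation."""
    profile = score_regions(cohort, sig)
    if batch_correct:
        profile = apply_batch_correction(profile, sig)
    else:
        table = profile.region_scores.copy()
        table["corrected_score"] = table["raw_score"]
        profile = replace(profile, region_scores=table)
    return classify_and_aggregate(profile, sig)
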