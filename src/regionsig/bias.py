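"""Tumor sampling-bias metrics for multiregion cohorts.

Four metrics quantify how much a signature's readout depends on which region
of a tumor is sampled: (1) the discordance rate of region risk classes,
(2) the area under a clustering-concordance curve, (3) the median per-gene
within-patient expression variability, and (4) the number of biopsies needed
for a stable risk-score estimate, derived from a within/between-tumor
variance decomposition. Signatures are ranked per metric and by mean rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .cohort import ExpressionCohort
from .exceptions import ValidationError
from .scoring import DISCORDANT, RiskProfile, score_regions
from .signature import SignatureModel

__all__ = [
    "BiasReport",
    "VarianceDecomposition",
    "DiscordanceResult",
    "ClusteringConcordance",
    "StabilityResult",
    "discordance_rate",
    "clustering_concordance",
    "gene_variability",
    "variance_decomposition",
    "biopsies_to_stability",
    "compute_bias_report",
    "rank_signatures",
]

logger = logging.getLogger(__name__)

K_GRID = tuple(range(1, 11))


@dataclass
class DiscordanceResult:
    n_discordant: int
    n_multiregion: int

    @property
    def rate(self) -> float:
        return self.n_discordant / self.n_multiregion


@dataclass
class ClusteringConcordance:
    """Concordance per cluster count plus the trapezoidal AUC."""

    cluster_counts: np.ndarray  # c = 1..P
    concordance: np.ndarray     # fraction of multiregion patients co-clustered
    auc: float


@dataclass
class VarianceDecomposition:
    """Within/between-tumor variance of the risk score.

    ``A`` is the mean (over multiregion tumors) within-tumor sample variance
    of the score; ``B`` is the sample variance of per-tumor mean scores.
    """

    A: float
    B: float
    n_tumors: int

    def __post_init__(self):
        if self.A < 0 or self.B < 0:
            raise ValidationError("variance components must be non-negative")

    def within(self, k: float) -> float:
        """W(k): mean within-tumor variance at k pooled biopsies."""
        return self.A / k

    def ratio(self, k: float) -> float:
        """W(k) / (W(k) + B), the within-to-total variance ratio."""
        w = self.within(k)
        total = w + self.B
        if total == 0:
            return 0.0
        return w / total


@dataclass
class StabilityResult:
    k_star: float
    theta: float
    ratio_profile: dict  # k -> ratio(k) for k = 1..10


@dataclass
class BiasReport:
    """The four sampling-bias metrics for one signature."""

    signature: str
    discordance_rate: float
    clustering_auc: float
    median_gene_variability: float
    biopsies_to_stability: float
    per_metric_rank: tuple | None = None
    mean_rank: float | None = None


def _require_multiregion(profile: RiskProfile) -> pd.DataFrame:
    if profile.patient_summary is None:
        raise ValidationError("profile lacks patient summary; run classify_and_aggregate")
    summary = profile.patient_summary
    multi = summary[summary["n_regions"] >= 2]
    return multi


def discordance_rate(profile: RiskProfile) -> DiscordanceResult:
    """Fraction of multiregion patients whose regions carry both risk labels."""
    multi = _require_multiregion(profile)
    if multi.empty:
        raise ValidationError("no patients with >=2 regions")
    n_disc = int((multi["risk_class"] == DISCORDANT).sum())
    return DiscordanceResult(n_disc, len(multi))


def clustering_concordance(
    cohort: ExpressionCohort,
    sig: SignatureModel,
    metric: str = "cityblock",
    method: str = "ward",
) -> ClusteringConcordance:
    """Agglomerative clustering of all regions on signature-gene expression
    (Manhattan distance, Ward.D2 linkage by default); for each cut into
    c = 1..P clusters (P patients), the fraction of multiregion patients
    whose regions co-cluster. AUC integrates concordance over
    x = (c - 1) / (P - 1).
    """
    present = [g for g in sig.genes if g in cohort.matrix.index]
    if not present:
        raise ValidationError(f"no signature genes of '{sig.name}' in cohort")
    patients = cohort.patients
    n_patients = len(patients)
    if n_patients < 2:
        raise ValidationError("need at least two patients")
    multi = cohort.multiregion_patients()
    if not multi:
        logger.warning("no multiregion patients; concordance is vacuous (AUC 1)")
        counts = np.arange(1, n_patients + 1)
        return ClusteringConcordance(counts, np.ones(n_patients), 1.0)

    X = cohort.matrix.loc[present].to_numpy(dtype=float).T  # samples x genes
    dist = pdist(X, metric=metric)
    Z = linkage(dist, method=method)
    patient_ids = cohort.samples["patient_id"].to_numpy()
    multi_set = set(multi)

    counts = np.arange(1, n_patients + 1)
    concordance = np.empty(n_patients, dtype=float)
    for i, c in enumerate(counts):
        labels = fcluster(Z, t=c, criterion="maxclust")
        lab = pd.Series(labels).groupby(patient_ids, sort=False).nunique()
        ok = sum(1 for p in multi if lab[p] == 1)
        concordance[i] = ok / len(multi_set)
    if n_patients == 1:
        auc = 1.0
    else:
        x = (counts - 1) / (n_patients - 1)
        auc = float(np.trapezoid(concordance, x))
    return ClusteringConcordance(counts, concordance, auc)


def gene_variability(cohort: ExpressionCohort, sig: SignatureModel):
    """Per-gene within-patient expression variability.

    For each signature gene present, the sample SD (n-1 denominator) of its
    expression over each multiregion patient's regions, averaged over those
    patients. Returns (per-gene Series, median over genes).
    """
    present = [g for g in sig.genes if g in cohort.matrix.index]
    if not present:
        raise ValidationError(f"no signature genes of '{sig.name}' in cohort")
    multi = set(cohort.multiregion_patients())
    if not multi:
        raise ValidationError("no patients with >=2 regions")
    mask = cohort.samples["patient_id"].isin(multi).to_numpy()
    expr = cohort.matrix.loc[present].iloc[:, mask]
    pat = cohort.samples["patient_id"].to_numpy()[mask]
    sds = expr.T.groupby(pat, sort=False).std(ddof=1)  # patients x genes
    per_gene = sds.mean(axis=0)
    per_gene.name = "mean_within_patient_sd"
    return per_gene, float(per_gene.median())


def variance_decomposition(profile: RiskProfile) -> VarianceDecomposition:
    """Score-level variance decomposition over multiregion tumors.

    A = mean over tumors of the within-tumor sample variance of corrected
    scores; B = sample variance over tumors of the per-tumor mean score.
    """
    multi = _require_multiregion(profile)
    if len(multi) < 2:
        raise ValidationError("need at least two multiregion tumors")
    table = profile.region_scores
    sel = table[table["patient_id"].isin(multi.index)]
    grouped = sel.groupby("patient_id", sort=False)["corrected_score"]
    within = grouped.var(ddof=1)
    means = grouped.mean()
    A = float(within.mean())
    B = float(means.var(ddof=1))
    return VarianceDecomposition(A, B, len(multi))


def biopsies_to_stability(vd: VarianceDecomposition, theta: float) -> StabilityResult:
    """Continuous number of biopsies k* at which the within-to-total variance
    ratio first drops to theta: k* = A (1 - theta) / (B theta), clipped to
    [1, 10]. Also reports the discrete ratio profile for k = 1..10.
    """
    if not 0 < theta < 1:
        raise ValidationError("theta must lie in (0, 1)")
    profile = {k: vd.ratio(k) for k in K_GRID}
    if vd.A == 0:
        return StabilityResult(1.0, theta, profile)
    if vd.B == 0:
        raise ValidationError(
            "between-tumor variance is zero; ratio never falls below 1"
        )
    k_star = vd.A * (1 - theta) / (vd.B * theta)
    k_star = float(min(max(k_star, 1.0), 10.0))
    return StabilityResult(k_star, theta, profile)


def compute_bias_report(
    cohort: ExpressionCohort,
    sig: SignatureModel,
    profile: RiskProfile,
    theta: float,
) -> BiasReport:
    """All four sampling-bias metrics for one signature on one cohort."""
    disc = discordance_rate(profile)
    clust = clustering_concordance(cohort, sig)
    _, med_var = gene_variability(cohort, sig)
    vd = variance_decomposition(profile)
    stab = biopsies_to_stability(vd, theta)
    return BiasReport(
        signature=sig.name,
        discordance_rate=disc.rate,
        clustering_auc=clust.auc,
        median_gene_variability=med_var,
        biopsies_to_stability=stab.k_star,
    )


_METRIC_ASCENDING = {
    # rank 1 = least sampling bias
    "discordance_rate": True,
    "clustering_auc": False,
    "median_gene_variability": True,
    "biopsies_to_stability": True,
}


def rank_signatures(reports: list) -> pd.DataFrame:
    """Rank signatures per metric (average ranks on ties) and by mean rank.

    Returns a table sorted ascending by mean rank with columns: signature,
    the four metrics, rank_1..rank_4 and mean_rank.
    """
    if len(reports) < 1:
        raise ValidationError("need at least one BiasReport")
    rows = {}
    for rep in reports:
        for m in _METRIC_ASCENDING:
            v = getattr(rep, m)
            if v is None or not np.isfinite(v):
                raise ValidationError(f"signature '{rep.signature}' missing metric {m}")
        rows[rep.signature] = [getattr(rep, m) for m in _METRIC_ASCENDING]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(_METRIC_ASCENDING)
    )
    table.index.name = "signature"
    for i, (m, ascending) in enumerate(_METRIC_ASCENDING.items(), start=1):
        vals = table[m].to_numpy(dtype=float)
        table[f"rank_{i}"] = rankdata(vals if ascending else -vals, method="average")
    rank_cols = [f"rank_{i}" for i in range(1, 5)]
    table["mean_rank"] = table[rank_cols].mean(axis=1)
    table = table.sort_values("mean_rank", kind="stable")
    for rep in reports:
        row = table.loc[rep.signature]
        rep.per_metric_rank = tuple(float(row[c]) for c in rank_cols)
        rep.mean_rank = float(row["mean_rank"])
    return table.reset_index()
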