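"""Synthetic multiregion cohorts with known ground truth.

Expression follows a hierarchical Gaussian model on the normalized scale:

    x[g, i, r] = mu + lambda_g * z_i + b[i, g] + e[i, g, r]

with a standard-normal latent patient risk z_i loading only onto signature
genes, a between-patient component b ~ N(0, tau2) and a within-patient
(region) component e ~ N(0, sigma2). Survival is exponential proportional
hazards in the supplied risk variable with exponential censoring. Generators
are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .exceptions import ValidationError
from .scoring import HIGH, LOW
from .signature import SignatureModel

__all__ = [
    "SyntheticCohortSpec",
    "simulate_multiregion_expression",
    "simulate_survival",
    "simulate_screen_and_mutations",
    "ScreenSim",
]

_DEFAULT_REGION_DIST = {1: 0.25, 2: 0.30, 3: 0.25, 4: 0.12, 5: 0.08}


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for a synthetic multiregion cohort.

    ``regions_per_patient`` is either a fixed integer in 1..5 or a mapping
    {count: probability} over 1..5. ``mix_discordant`` of None disables
    class planting; a fraction d plants mixed region classes in exactly
    round(d * n_multiregion) multiregion patients and forces the remaining
    multiregion patients to be concordant.
    """

    n_patients: int = 100
    regions_per_patient: object = None
    n_genes: int = 200
    signature_size: int = 23
    tau2: float = 2.0
    sigma2: float = 1.0
    latent_loading: float = 0.0   # per-gene loading of z on signature genes
    latent_beta: float = 0.8      # per-unit log HR of the risk variable
    baseline_hazard: float = 0.1  # events / year
    censor_rate: float = 0.05     # censoring events / year
    relapse_hazard: float = 0.15
    lung_cause_fraction: float = 0.8
    mix_discordant: float | None = None
    mu: float = 8.0               # baseline expression
    seed: int = 0

    def __post_init__(self):
        if self.regions_per_patient is None:
            self.regions_per_patient = dict(_DEFAULT_REGION_DIST)
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValidationError("n_patients and n_genes must be positive")
        if not 1 <= self.signature_size <= self.n_genes:
            raise ValidationError("signature_size must lie in [1, n_genes]")
        if self.tau2 < 0 or self.sigma2 < 0:
            raise ValidationError("variance components must be non-negative")
        if self.mix_discordant is not None and not 0 <= self.mix_discordant <= 1:
            raise ValidationError("mix_discordant must lie in [0, 1]")
        if isinstance(self.regions_per_patient, dict):
            probs = np.array(list(self.regions_per_patient.values()), dtype=float)
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
                raise ValidationError("region-count probabilities must sum to 1")
            if not all(1 <= int(k) <= 5 for k in self.regions_per_patient):
                raise ValidationError("region counts must lie in 1..5")
        else:
            if not 1 <= int(self.regions_per_patient) <= 5:
                raise ValidationError("regions_per_patient must lie in 1..5")

    # -- derived objects ------------------------------------------------------

    @property
    def signature_genes(self) -> tuple:
        return tuple(f"G{i:04d}" for i in range(self.signature_size))

    @property
    def gene_names(self) -> tuple:
        return tuple(f"G{i:04d}" for i in range(self.n_genes))

    def signature(self) -> SignatureModel:
        """The planted signature: equal weights 1/sqrt(m) and a threshold at
        the score's expected value, so region classes split about 50/50 and
        the score inherits the spec's variance components exactly
        (within-region score variance sigma2 + between tau2 + m*loading^2)."""
        m = self.signature_size
        w = 1.0 / np.sqrt(m)
        return SignatureModel(
            name="synthetic",
            genes=self.signature_genes,
            weights=(w,) * m,
            risk_threshold=float(w * m * self.mu),
        )

    def score_between_variance(self) -> float:
        """Between-patient variance of the planted score (law of total
        variance at the patient level)."""
        m = self.signature_size
        return m * self.latent_loading**2 + self.tau2

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["regions_per_patient"], dict):
            d["regions_per_patient"] = {int(k): float(v) for k, v in d["regions_per_patient"].items()}
        return d


def _draw_region_counts(spec: SyntheticCohortSpec, rng) -> np.ndarray:
    if isinstance(spec.regions_per_patient, dict):
        ks = np.array(sorted(spec.regions_per_patient), dtype=int)
        probs = np.array([spec.regions_per_patient[int(k)] for k in ks], dtype=float)
        return rng.choice(ks, size=spec.n_patients, p=probs)
    return np.full(spec.n_patients, int(spec.regions_per_patient))


def simulate_multiregion_expression(spec: SyntheticCohortSpec):
    """Generate an :class:`ExpressionCohort` plus a ground-truth record.

    Returns (cohort, truth) where truth holds the latent risk z per patient,
    the variance components, the planted signature, and, when class planting
    is enabled, the planted per-region classes.
    """
    rng = np.random.default_rng([spec.seed, 0])
    counts = _draw_region_counts(spec, rng)
    patients = [f"P{i:04d}" for i in range(spec.n_patients)]
    sample_ids, pat_col, reg_col = [], [], []
    for pid, c in zip(patients, counts):
        for r in range(c):
            sample_ids.append(f"{pid}_R{r + 1}")
            pat_col.append(pid)
            reg_col.append(f"R{r + 1}")
    n_samples = len(sample_ids)
    genes = list(spec.gene_names)
    m = spec.signature_size

    z = rng.standard_normal(spec.n_patients)
    lam = np.zeros(spec.n_genes)
    lam[:m] = spec.latent_loading
    b = rng.normal(0.0, np.sqrt(spec.tau2), size=(spec.n_patients, spec.n_genes))
    sample_patient_idx = np.repeat(np.arange(spec.n_patients), counts)
    e = rng.normal(0.0, np.sqrt(spec.sigma2), size=(n_samples, spec.n_genes))
    x = spec.mu + z[sample_patient_idx, None] * lam[None, :] \
        + b[sample_patient_idx, :] + e  # samples x genes

    sig = spec.signature()
    planted = None
    if spec.mix_discordant is not None:
        x, planted_rows = _plant_classes(spec, x, sig, counts, sample_patient_idx, rng)
        planted = pd.Series(
            {sample_ids[row]: side for row, side in planted_rows.items()},
            name="planted_class",
        ).reindex(sample_ids)

    matrix = pd.DataFrame(x.T, index=genes, columns=sample_ids)
    tpm = pd.DataFrame(np.exp2(x.T - x.T.mean()), index=genes, columns=sample_ids)
    samples = pd.DataFrame(
        {"patient_id": pat_col, "region_id": reg_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = ExpressionCohort(matrix, samples, tpm)
    truth = {
        "z": pd.Series(z, index=patients, name="z"),
        "tau2": spec.tau2,
        "sigma2": spec.sigma2,
        "latent_loading": spec.latent_loading,
        "signature": sig,
        "region_counts": pd.Series(counts, index=patients, name="n_regions"),
        "planted_classes": planted,
        "spec": spec,
    }
    return cohort, truth


def _plant_classes(spec, x, sig, counts, sample_patient_idx, rng):
    """Shift signature-gene expression so each multiregion patient's region
    scores sit at a fixed margin on planted sides of the threshold."""
    m = spec.signature_size
    w_sum = m / np.sqrt(m)  # adding delta to each signature gene moves score by delta*w_sum
    margin = 1.0
    scores = x[:, :m].sum(axis=1) / np.sqrt(m)
    multi = np.flatnonzero(counts >= 2)
    n_mixed = int(round(spec.mix_discordant * len(multi)))
    mixed = set(rng.choice(multi, size=n_mixed, replace=False)) if n_mixed else set()
    planted = {}
    for i in np.flatnonzero(counts >= 1):
        rows = np.flatnonzero(sample_patient_idx == i)
        if counts[i] < 2:
            planted_side = [HIGH if scores[rows[0]] > sig.risk_threshold else LOW]
        elif i in mixed:
            sides = [HIGH, LOW] + [
                HIGH if rng.random() < 0.5 else LOW for _ in range(counts[i] - 2)
            ]
            order = rng.permutation(counts[i])
            planted_side = [sides[j] for j in order]
        else:
            side = HIGH if rng.random() < 0.5 else LOW
            planted_side = [side] * counts[i]
        for row, side in zip(rows, planted_side):
            if counts[i] < 2:
                continue  # single-region patients left untouched
            target = sig.risk_threshold + (margin if side == HIGH else -margin)
            delta = (target - scores[row]) / w_sum
            x[row, :m] += delta
            scores[row] = target
        planted[i] = planted_side
    planted_series = {}
    for i, sides in planted.items():
        rows = np.flatnonzero(sample_patient_idx == i)
        for row, side in zip(rows, sides):
            planted_series[row] = side
    return x, planted_series


def simulate_survival(risk: pd.Series, spec: SyntheticCohortSpec, center: bool = True) -> pd.DataFrame:
    """Exponential proportional-hazards outcomes driven by a per-patient risk.

    ``risk`` may be the latent z or a computed patient-level score; with
    ``center`` the risk is mean-centered so the baseline hazard applies to
    the average patient (the hazard ratio is unaffected). Produces OS, lung
    cancer-specific and disease-free endpoints plus clinical covariates.
    """
    if spec.baseline_hazard <= 0:
        raise ValidationError("baseline_hazard must be positive")
    rng = np.random.default_rng([spec.seed, 1])
    r = risk.astype(float).to_numpy()
    if center:
        r = r - r.mean()
    n = len(r)
    rate = spec.baseline_hazard * np.exp(spec.latent_beta * r)
    death = rng.exponential(1.0 / rate)
    if spec.censor_rate > 0:
        censor = rng.exponential(1.0 / spec.censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    os_time = np.minimum(death, censor)
    os_event = (death <= censor).astype(int)

    lung = rng.random(n) < spec.lung_cause_fraction
    lcss_event = (os_event.astype(bool) & lung).astype(int)

    relapse_rate = spec.relapse_hazard * np.exp(spec.latent_beta * r)
    relapse = rng.exponential(1.0 / relapse_rate)
    dfs_raw = np.minimum(relapse, death)
    dfs_time = np.minimum(dfs_raw, censor)
    dfs_event = (dfs_raw <= censor).astype(int)

    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "lcss_time": os_time,
            "lcss_event": lcss_event,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "age": np.round(rng.normal(68, 8, size=n), 1),
            "sex": rng.choice(["male", "female"], size=n),
            "pack_years": np.round(rng.gamma(2.0, 15.0, size=n), 1),
            "adjuvant": rng.choice([0, 1], size=n, p=[0.7, 0.3]),
            "stage": rng.choice(["I", "II", "III"], size=n, p=[0.5, 0.3, 0.2]),
            "grade": rng.choice(["G1", "G2", "G3"], size=n, p=[0.25, 0.5, 0.25]),
        },
        index=pd.Index(risk.index, name="patient_id"),
    )
    return clinical


@dataclass
class ScreenSim:
    """Synthetic drug screen and mutation tables with planted effects."""

    line_scores: pd.Series
    ic50: pd.DataFrame
    pathways: pd.Series
    mutations: pd.DataFrame       # long format: sample_id, gene, clonality
    region_classes: pd.Series
    truth: dict


def simulate_screen_and_mutations(
    spec: SyntheticCohortSpec,
    n_cell_lines: int = 45,
    n_compounds: int = 80,
    n_responsive: int = 8,
    rho_noise: float = 0.5,
    missing_fraction: float = 0.05,
    n_sparse_lines: int = 3,
    n_over_missing_compounds: int = 2,
    n_regions: int = 400,
    n_mut_genes: int = 10,
    planted_or: float = 4.0,
    base_mut_rate: float = 0.2,
) -> ScreenSim:
    """Generate an IC50 matrix with planted responsive compounds and planted
    missingness, plus a region-level mutation table with a planted odds
    ratio between mutation presence and high-risk class.

    ``n_sparse_lines`` lines are given too few compounds to survive the
    line filter; ``n_over_missing_compounds`` compounds are planted with
    more missing lines than the compound filter allows.
    """
    rng = np.random.default_rng([spec.seed, 2])
    lines = [f"CL{i:03d}" for i in range(n_cell_lines)]
    compounds = [f"D{i:03d}" for i in range(n_compounds)]
    scores = pd.Series(rng.normal(10.0, 1.5, size=n_cell_lines), index=lines)

    ic50 = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_compounds, n_cell_lines)),
        index=compounds, columns=lines,
    )
    responsive = compounds[:n_responsive]
    slope = -1.0  # responsive: higher risk -> lower IC50 (more sensitive)
    centered = (scores - scores.mean()).to_numpy()
    for compound in responsive:
        ic50.loc[compound] = slope * centered + rng.normal(0, rho_noise, n_cell_lines)
    # random missingness
    mask = rng.random(ic50.shape) < missing_fraction
    ic50 = ic50.mask(mask)
    # planted sparse lines: keep data for fewer than min_compounds compounds
    sparse = lines[-n_sparse_lines:] if n_sparse_lines else []
    for line in sparse:
        keep = rng.choice(n_compounds, size=min(49, n_compounds - 1), replace=False)
        col = pd.Series(np.nan, index=compounds)
        col.iloc[keep] = ic50[line].iloc[keep]
        ic50[line] = col
    # planted over-missing compounds (missing in > 5 surviving lines)
    dense_lines = [l for l in lines if l not in sparse]
    over = compounds[n_responsive:n_responsive + n_over_missing_compounds]
    for compound in over:
        gone = rng.choice(dense_lines, size=6, replace=False)
        ic50.loc[compound, gone] = np.nan
    pathways = pd.Series(
        rng.choice(["DNA replication", "EGFR signaling", "Cell cycle", "Other"],
                   size=n_compounds),
        index=compounds, name="pathway",
    )

    # mutation table with planted enrichment
    region_ids = [f"S{i:04d}" for i in range(n_regions)]
    region_classes = pd.Series(
        np.where(rng.random(n_regions) < 0.4, HIGH, LOW), index=region_ids
    )
    genes = [f"DRV{i:02d}" for i in range(n_mut_genes)]
    enriched = genes[: max(1, n_mut_genes // 3)]
    p_low = base_mut_rate
    odds_low = p_low / (1 - p_low)
    p_high_enriched = planted_or * odds_low / (1 + planted_or * odds_low)
    records = []
    is_high = (region_classes == HIGH).to_numpy()
    for gene in genes:
        p_high = p_high_enriched if gene in enriched else p_low
        prob = np.where(is_high, p_high, p_low)
        mutated = rng.random(n_regions) < prob
        clonality = rng.choice(["clonal", "subclonal"], size=n_regions, p=[0.7, 0.3])
        for sid, mut, clo in zip(region_ids, mutated, clonality):
            if mut:
                records.append(dict(sample_id=sid, gene=gene, clonality=clo))
    mutations = pd.DataFrame.from_records(records)
    truth = {
        "responsive_compounds": responsive,
        "planted_slope": slope,
        "sparse_lines": sparse,
        "over_missing_compounds": list(over),
        "enriched_genes": enriched,
        "planted_or": planted_or,
    }
    return ScreenSim(scores, ic50, pathways, mutations, region_classes, truth)
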