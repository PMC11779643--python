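"""Exploratory association procedures.

Driver-mutation enrichment by region risk class (Fisher exact, natural-log
odds ratio), drug-sensitivity screening with missing-data filters and
Spearman correlation, and determinants regression of patient mean scores.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ValidationError
from .scoring import HIGH, LOW
from .survival import _design_matrix

__all__ = [
    "ContingencyResult",
    "driver_enrichment",
    "drug_screen",
    "determinants_regression",
    "spearman_test",
    "mutation_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    gene: str
    counts: tuple  # ((mut_high, mut_low), (wt_high, wt_low))
    odds_ratio: float
    log_or: float
    p: float


def mutation_matrix(mutations: pd.DataFrame, clonality: str | None = None) -> pd.DataFrame:
    """Normalize a mutation table to a binary gene x sample matrix.

    Accepts either a wide binary matrix (genes as rows) or a long table with
    columns sample_id, gene and optionally clonality; ``clonality`` filters
    the long format to 'clonal' or 'subclonal' calls.
    """
    cols = set(mutations.columns)
    if {"sample_id", "gene"}.issubset(cols):
        long = mutations
        if clonality is not None:
            if "clonality" not in cols:
                raise ValidationError("long mutation table lacks 'clonality' column")
            long = long[long["clonality"] == clonality]
        wide = (
            long.assign(present=1)
            .pivot_table(index="gene", columns="sample_id", values="present",
                         aggfunc="max", fill_value=0)
        )
        return wide.astype(int)
    return (mutations > 0).astype(int)


def driver_enrichment(
    region_classes: pd.Series,
    mutations: pd.DataFrame,
    genes=None,
) -> pd.DataFrame:
    """Per-gene 2x2 enrichment of mutation presence in high- vs low-risk
    regions.

    Two-sided Fisher exact p on raw counts; the odds ratio uses a
    Haldane-Anscombe +0.5 on all cells only when a zero cell exists, so the
    natural-log OR is always finite. No multiplicity correction.
    """
    classes = region_classes.dropna().astype(str)
    if not {(classes == HIGH).any(), (classes == LOW).any()} == {True}:
        raise ValidationError("both risk classes must be present")
    mat = mutation_matrix(mutations)
    shared = [s for s in classes.index if s in mat.columns]
    if not shared:
        raise ValidationError("no samples shared between classes and mutation table")
    classes = classes.loc[shared]
    mat = mat[shared]
    wanted = list(genes) if genes is not None else list(mat.index)
    high = (classes == HIGH).to_numpy()
    rows = []
    for gene in wanted:
        if gene not in mat.index:
            logger.warning("gene '%s' absent from mutation table; skipped", gene)
            continue
        mut = mat.loc[gene].to_numpy(dtype=bool)
        a = int((mut & high).sum())      # mutated, high risk
        b = int((mut & ~high).sum())     # mutated, low risk
        c = int((~mut & high).sum())
        d = int((~mut & ~high).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append(
            dict(gene=gene, mut_high=a, mut_low=b, wt_high=c, wt_low=d,
                 odds_ratio=float(orr), log_or=float(math.log(orr)), p=float(p))
        )
    return pd.DataFrame(rows).set_index("gene")


def spearman_test(x, y):
    """Spearman rho with a two-sided p value.

    Average ranks on ties; the p value uses the large-sample approximation
    for n >= 10 and exact permutation enumeration for n < 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("need at least three observations")
    rho, p_approx = stats.spearmanr(x, y)
    if n >= 10:
        return float(rho), float(p_approx)
    # exact permutation null for small n
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum())

    def _rho(perm):
        ry_c = perm - perm.mean()
        d = denom * np.sqrt((ry_c**2).sum())
        if d == 0:
            return 0.0
        return float((rx_c * ry_c).sum() / d)

    obs = abs(rho) if np.isfinite(rho) else 0.0
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_rho(np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return float(rho), count / total


def drug_screen(
    cell_scores: pd.Series,
    ic50: pd.DataFrame,
    pathways: pd.Series | None = None,
    min_compounds: int = 50,
    max_missing_lines: int = 5,
    alpha: float = 0.05,
):
    """Risk-score vs IC50 correlation screen with the missing-data filters.

    Filter order: first drop cell lines with non-missing IC50 for fewer than
    ``min_compounds`` compounds, then drop compounds missing in more than
    ``max_missing_lines`` of the remaining lines. Per surviving compound,
    Spearman rho/p between risk score and IC50 over lines with data
    (at least 3 required). Returns (per-compound table, per-pathway summary).
    """
    if ic50.empty:
        raise ValidationError("empty IC50 matrix")
    lines = [l for l in ic50.columns if l in cell_scores.index]
    dropped = set(ic50.columns) - set(lines)
    if dropped:
        logger.warning("%d cell lines lack risk scores; dropped", len(dropped))
    ic50 = ic50[lines]
    # 1. line filter
    per_line = ic50.notna().sum(axis=0)
    kept_lines = per_line.index[per_line >= min_compounds]
    if len(kept_lines) == 0:
        raise ValidationError("all cell lines removed by the compound-count filter")
    ic50 = ic50[kept_lines]
    # 2. compound filter, evaluated on the post-line-filter matrix
    missing = ic50.isna().sum(axis=1)
    kept_compounds = missing.index[missing <= max_missing_lines]
    ic50 = ic50.loc[kept_compounds]
    scores = cell_scores.loc[ic50.columns].astype(float)
    rows = []
    for compound in ic50.index:
        vals = ic50.loc[compound]
        mask = vals.notna()
        n = int(mask.sum())
        if n < 3:
            logger.warning("compound '%s': only %d lines with data; skipped", compound, n)
            continue
        rho, p = spearman_test(scores[mask].to_numpy(), vals[mask].to_numpy())
        rows.append(
            dict(compound=compound,
                 pathway=pathways.get(compound) if pathways is not None else None,
                 rho=rho, p=p, n_cell_lines=n, significant=bool(p < alpha))
        )
    results = pd.DataFrame(rows).set_index("compound")
    results.attrs["n_lines"] = len(kept_lines)
    results.attrs["n_compounds"] = len(results)
    if pathways is not None and not results.empty:
        summary = (
            results.groupby("pathway", dropna=True)
            .agg(n_compounds=("rho", "size"),
                 median_rho=("rho", "median"),
                 n_significant=("significant", "sum"))
            .sort_values("median_rho")
        )
    else:
        summary = pd.DataFrame(columns=["n_compounds", "median_rho", "n_significant"])
    return results, summary


def determinants_regression(
    mean_scores: pd.Series,
    features: pd.DataFrame,
    baselines: dict | None = None,
) -> pd.DataFrame:
    """Ordinary least squares of patient mean score on a feature block.

    Categorical features are treatment-coded against the configured
    baselines (male / non-smoker / stage I by default). Complete cases only;
    no multiplicity correction. Raises on rank deficiency, naming the
    collinear columns.
    """
    df = pd.concat([mean_scores.rename("_score"), features], axis=1).dropna()
    if len(df) < features.shape[1] + 2:
        raise ValidationError("too few complete cases for the requested features")
    design, terms = _design_matrix(df, list(features.columns), baselines)
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X.to_numpy(), pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag[0]]
        bad += [X.columns[j] for j in piv[len(diag):]]
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(df["_score"].astype(float), X).fit()
    rows = [dict(term="intercept", variable=None, level=None,
                 coef=float(fit.params["const"]), se=float(fit.bse["const"]),
                 p=float(fit.pvalues["const"]), reference=False)]
    for term, variable, level, is_ref in terms:
        if is_ref:
            rows.append(dict(term=term, variable=variable, level=level,
                             coef=0.0, se=np.nan, p=np.nan, reference=True))
        else:
            rows.append(dict(term=term, variable=variable, level=level,
                             coef=float(fit.params[term]), se=float(fit.bse[term]),
                             p=float(fit.pvalues[term]), reference=False))
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["n"] = len(df)
    out.attrs["r2"] = float(fit.rsquared)
    return out
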