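"""Survival-analysis layer.

Cox and Kaplan-Meier contracts, the pseudo-single-biopsy bootstrap,
Harrell's concordance index, variance explained over follow-up time,
fixed-effect meta-analysis and linear mixed-effects trend contracts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .exceptions import ConvergenceError, ValidationError
from .scoring import RiskProfile

__all__ = [
    "BootstrapResult",
    "KMResult",
    "MetaResult",
    "fit_cox",
    "km_logrank",
    "pseudo_single_biopsy_bootstrap",
    "concordance_index",
    "pve_over_time",
    "meta_fixed_effect",
    "mixed_effects_trend",
    "cox_univariable",
]

logger = logging.getLogger(__name__)

# default reference levels for categorical covariates
BASELINES = {
    "sex": "male",
    "smoking_status": "non-smoker",
    "stage": "I",
}

Z975 = stats.norm.ppf(0.975)


def _endpoint_columns(clinical: pd.DataFrame, endpoint: str):
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for col in (tcol, ecol):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table lacks column '{col}'")
    return tcol, ecol


def _design_matrix(df: pd.DataFrame, predictors, baselines=None):
    """Expand categoricals to treatment-coded dummies.

    Returns (design DataFrame, list of (term, variable, level, is_reference)).
    """
    baselines = {**BASELINES, **(baselines or {})}
    design = pd.DataFrame(index=df.index)
    terms = []
    for pred in predictors:
        col = df[pred]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            design[pred] = col.astype(float)
            terms.append((pred, pred, None, False))
        elif pd.api.types.is_numeric_dtype(col):
            design[pred] = col.astype(float)
            terms.append((pred, pred, None, False))
        else:
            levels = sorted(col.astype(str).unique())
            ref = baselines.get(pred, levels[0])
            if ref not in levels:
                ref = levels[0]
            terms.append((f"{pred}[{ref}]", pred, ref, True))
            for level in levels:
                if level == ref:
                    continue
                name = f"{pred}[{level}]"
                design[name] = (col.astype(str) == level).astype(float)
                terms.append((name, pred, level, False))
    return design, terms


def fit_cox(
    clinical: pd.DataFrame,
    endpoint: str,
    predictors: list,
    baselines: dict | None = None,
) -> pd.DataFrame:
    """Multivariable Cox proportional-hazards fit (Efron tie handling).

    Continuous predictors enter per unit; categorical predictors are
    treatment-coded against the configured baseline (male / non-smoker /
    stage I by default). Complete cases only. Returns one row per term
    including reference levels (HR exactly 1).
    """
    tcol, ecol = _endpoint_columns(clinical, endpoint)
    df = clinical[[tcol, ecol] + list(predictors)].dropna()
    if df.empty:
        raise ValidationError("no complete cases for requested predictors")
    if df[ecol].sum() < 1:
        raise ValidationError("no events in complete-case data")
    design, terms = _design_matrix(df, predictors, baselines)
    frame = pd.concat([df[[tcol, ecol]], design], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col=tcol, event_col=ecol)
    except Exception as exc:  # noqa: BLE001 - surface as explicit error
        raise ConvergenceError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    rows = []
    for term, variable, level, is_ref in terms:
        if is_ref:
            rows.append(
                dict(term=term, variable=variable, level=level, hr=1.0,
                     ci_low=np.nan, ci_high=np.nan, p=np.nan, reference=True)
            )
        else:
            s = summ.loc[term]
            rows.append(
                dict(term=term, variable=variable, level=level,
                     hr=float(np.exp(s["coef"])),
                     ci_low=float(np.exp(s["coef lower 95%"])),
                     ci_high=float(np.exp(s["coef upper 95%"])),
                     p=float(s["p"]), reference=False)
            )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["n"] = len(df)
    out.attrs["n_events"] = int(df[ecol].sum())
    return out


@dataclass
class KMResult:
    curves: dict           # group -> survival function DataFrame
    medians: dict          # group -> float or None ("not reached")
    p: float
    test_statistic: float

    def median_display(self, group) -> str:
        med = self.medians[group]
        return "not reached" if med is None else f"{med:g}"


def km_logrank(clinical: pd.DataFrame, endpoint: str, groups: pd.Series) -> KMResult:
    """Kaplan-Meier curves per group and a two-sided log-rank test.

    ``groups`` maps patient (clinical index) to a class label. Median
    survival is None ("not reached") when the curve never drops to 0.5.
    """
    tcol, ecol = _endpoint_columns(clinical, endpoint)
    groups = groups.reindex(clinical.index).dropna()
    df = clinical.loc[groups.index, [tcol, ecol]].dropna()
    groups = groups.loc[df.index]
    labels = [g for g in pd.unique(groups) if (groups == g).any()]
    if len(labels) < 2:
        raise ValidationError("need at least two nonempty groups")
    curves, medians = {}, {}
    for g in labels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, tcol], df.loc[mask, ecol], label=str(g))
        curves[g] = kmf.survival_function_
        med = kmf.median_survival_time_
        medians[g] = None if np.isinf(med) else float(med)
    res = multivariate_logrank_test(df[tcol], groups, df[ecol])
    return KMResult(curves, medians, float(res.p_value), float(res.test_statistic))


# ---------------------------------------------------------------------------
# Fast univariable Cox (Efron ties) for the bootstrap


def cox_univariable(x, time, event, max_iter=100, tol=1e-10):
    """Newton-Raphson fit of a single-covariate Cox model with Efron tie
    handling. Returns (log hazard ratio, standard error)."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if x.shape != time.shape or x.shape != event.shape:
        raise ValidationError("x, time and event must have equal length")
    if event.sum() < 1:
        raise ValidationError("no events")
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    event_times = np.unique(time[event])
    starts = np.searchsorted(time, event_times, side="left")
    # per event time: indices of tied events
    tied = [np.flatnonzero(event & (time == t)) for t in event_times]

    beta = 0.0
    for _ in range(max_iter):
        r = np.exp(beta * x)
        rx = r * x
        rxx = rx * x
        S0 = np.cumsum(r[::-1])[::-1]
        S1 = np.cumsum(rx[::-1])[::-1]
        S2 = np.cumsum(rxx[::-1])[::-1]
        U = 0.0
        info = 0.0
        for t_idx, start in enumerate(starts):
            D = tied[t_idx]
            d = len(D)
            s0d, s1d, s2d = r[D].sum(), rx[D].sum(), rxx[D].sum()
            U += x[D].sum()
            for ell in range(d):
                f = ell / d
                den = S0[start] - f * s0d
                num1 = S1[start] - f * s1d
                num2 = S2[start] - f * s2d
                mean = num1 / den
                U -= mean
                info += num2 / den - mean * mean
        if not np.isfinite(U) or not np.isfinite(info) or info <= 0:
            raise ConvergenceError("singular information in univariable Cox fit")
        step = U / info
        beta += step
        if abs(step) < tol:
            return float(beta), float(1.0 / np.sqrt(info))
    raise ConvergenceError("univariable Cox fit did not converge")


@dataclass
class BootstrapResult:
    """Summary of the pseudo-single-biopsy bootstrap."""

    log_hr_draws: np.ndarray
    hr_point: float
    hr_ci: tuple
    n_iter: int
    seed: int | None
    n_failed: int = 0

    @property
    def mean_log_hr(self) -> float:
        return float(np.nanmean(self.log_hr_draws))


def pseudo_single_biopsy_bootstrap(
    profile: RiskProfile,
    clinical: pd.DataFrame,
    endpoint: str = "os",
    n_iter: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Repeatedly sample one region per patient and fit a univariable Cox of
    the continuous corrected score against the endpoint.

    Regions are indexed in sorted region_id order so the draw sequence is
    invariant to input row order given the same seed. Point estimate is
    exp(mean log HR); the CI is the 2.5/97.5 percentile of HR draws.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    tcol, ecol = _endpoint_columns(clinical, endpoint)
    table = profile.region_scores
    if "corrected_score" not in table:
        raise ValidationError("profile lacks corrected scores")
    # regions sorted by region_id within each patient
    ordered = table.sort_values(["patient_id", "region_id"], kind="stable")
    patients = [p for p in ordered["patient_id"].unique() if p in clinical.index]
    clin = clinical.loc[patients, [tcol, ecol]].dropna()
    patients = list(clin.index)
    if not patients:
        raise ValidationError("no patients shared between scores and clinical table")
    per_patient = [
        ordered.loc[ordered["patient_id"] == p, "corrected_score"].to_numpy()
        for p in patients
    ]
    counts = np.array([len(s) for s in per_patient])
    max_r = counts.max()
    padded = np.zeros((len(patients), max_r))
    for i, s in enumerate(per_patient):
        padded[i, : len(s)] = s
    time = clin[tcol].to_numpy(dtype=float)
    event = clin[ecol].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    draws = np.full(n_iter, np.nan)
    n_failed = 0
    for it in range(n_iter):
        pick = rng.integers(0, counts)
        xs = padded[np.arange(len(patients)), pick]
        try:
            beta, _ = cox_univariable(xs, time, event)
            draws[it] = beta
        except ConvergenceError:
            n_failed += 1
            logger.warning("bootstrap iteration %d failed to converge", it)
    if n_failed > 0.05 * n_iter:
        raise ConvergenceError(
            f"{n_failed}/{n_iter} bootstrap iterations failed to converge"
        )
    valid = draws[~np.isnan(draws)]
    hr_draws = np.exp(valid)
    hr_point = float(np.exp(valid.mean()))
    hr_ci = (float(np.percentile(hr_draws, 2.5)), float(np.percentile(hr_draws, 97.5)))
    return BootstrapResult(draws, hr_point, hr_ci, n_iter, seed, n_failed)


def concordance_index(scores, time, event) -> float:
    """Harrell's C.

    A pair is comparable when the strictly shorter time ends in an event;
    it is concordant when the higher score has the shorter time; score ties
    count 0.5.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    # comparable[i, j]: t_i < t_j and event_i
    comparable = (t[:, None] < t[None, :]) & e[:, None]
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValidationError("no comparable pairs")
    higher = (s[:, None] > s[None, :]) & comparable
    tied = (s[:, None] == s[None, :]) & comparable
    return float((higher.sum() + 0.5 * tied.sum()) / n_comp)


def _mcfadden(result) -> float:
    return float(1.0 - result.llf / result.llnull)


def _nagelkerke(result, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (result.llnull - result.llf) / n)
    max_r2 = 1.0 - np.exp(2.0 * result.llnull / n)
    return float(cox_snell / max_r2)


def pve_over_time(
    biomarkers: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: str = "os",
    years: list = (1, 2, 3, 4, 5),
    method: str = "mcfadden",
) -> pd.DataFrame:
    """Variance in the binary outcome death-by-year-t explained per biomarker.

    At each horizon t, patients censored before t are removed; the outcome is
    1 for an event at or before t, else 0. A logistic GLM is fit per
    biomarker and the pseudo-R^2 (McFadden by default, Nagelkerke behind the
    flag) is reported, capped at 1 under separation.
    """
    if method not in {"mcfadden", "nagelkerke"}:
        raise ValidationError("method must be 'mcfadden' or 'nagelkerke'")
    tcol, ecol = _endpoint_columns(clinical, endpoint)
    out = pd.DataFrame(index=list(years), columns=biomarkers.columns, dtype=float)
    out.index.name = "year"
    for year in years:
        keep = ~((clinical[ecol] == 0) & (clinical[tcol] < year))
        sub = clinical[keep]
        y = ((sub[ecol] == 1) & (sub[tcol] <= year)).astype(int)
        for bm in biomarkers.columns:
            x = biomarkers[bm].reindex(sub.index)
            mask = x.notna() & y.notna()
            yy, xx = y[mask], x[mask]
            if yy.sum() < 1 or (1 - yy).sum() < 1:
                raise ValidationError(
                    f"year {year}: need at least one death and one survivor"
                )
            X = sm.add_constant(xx.astype(float).to_numpy())
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(yy.to_numpy(), X).fit(disp=0, maxiter=200)
                pve = _mcfadden(res) if method == "mcfadden" else _nagelkerke(res, len(yy))
                if not np.isfinite(pve):
                    raise ValueError("non-finite pseudo-R2")
                pve = min(max(pve, 0.0), 1.0)
            except Exception:  # noqa: BLE001 - (quasi-)separation
                logger.warning(
                    "biomarker '%s' year %s: separation; PVE capped at 1", bm, year
                )
                pve = 1.0
            out.loc[year, bm] = pve
    return out


@dataclass
class MetaResult:
    pooled_log_hr: float
    se: float
    weights: np.ndarray

    @property
    def hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def ci(self) -> tuple:
        lo = self.pooled_log_hr - Z975 * self.se
        hi = self.pooled_log_hr + Z975 * self.se
        return (float(np.exp(lo)), float(np.exp(hi)))

    @property
    def p(self) -> float:
        z = self.pooled_log_hr / self.se
        return float(2.0 * stats.norm.sf(abs(z)))


def meta_fixed_effect(log_hrs, ses) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-cohort log hazard ratios."""
    b = np.asarray(log_hrs, dtype=float)
    se = np.asarray(ses, dtype=float)
    if b.size < 1:
        raise ValidationError("need at least one cohort")
    if np.any(se <= 0):
        raise ValidationError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    return MetaResult(pooled, float(np.sqrt(1.0 / np.sum(w))), w)


def mixed_effects_trend(
    values: pd.Series,
    fixed_label: pd.Series,
    group: pd.Series,
    reference=None,
) -> pd.DataFrame:
    """Linear mixed model with a random intercept per group.

    Returns per-category fixed-effect contrasts against the reference level
    with two-sided p values (no multiple-comparison correction).
    """
    df = pd.DataFrame({"y": values, "label": fixed_label, "group": group}).dropna()
    labels = sorted(df["label"].astype(str).unique())
    if len(labels) < 2:
        raise ValidationError("need at least two fixed-effect categories")
    if df["group"].nunique() < 2:
        raise ValidationError("need at least two groups")
    ref = str(reference) if reference is not None else labels[0]
    if ref not in labels:
        raise ValidationError(f"reference level '{ref}' absent")
    exog = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    contrast_terms = []
    for level in labels:
        if level == ref:
            continue
        name = f"label[{level}]"
        exog[name] = (df["label"].astype(str) == level).astype(float)
        contrast_terms.append((name, level))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df["y"].astype(float), exog, groups=df["group"])
        try:
            fit = model.fit(reml=True)
        except Exception as exc:  # noqa: BLE001
            raise ConvergenceError(f"mixed model failed: {exc}") from exc
    group_var = float(fit.cov_re.iloc[0, 0])
    params_ok = np.isfinite(fit.params.to_numpy()).all() and np.isfinite(
        fit.bse[[name for name, _ in contrast_terms]].to_numpy()
    ).all()
    # boundary fits (random-effect variance ~ 0) report converged=False with
    # perfectly usable estimates; reject only unusable fits
    if not params_ok:
        raise ConvergenceError(
            "mixed model produced non-finite estimates; "
            f"groups={df['group'].nunique()}, n={len(df)}, group_var={group_var:.3g}"
        )
    if not fit.converged:
        logger.warning(
            "mixed model optimizer stopped at the variance boundary "
            "(group_var=%.3g); estimates retained", group_var
        )
    fit_group_var = group_var
    rows = []
    for name, level in contrast_terms:
        rows.append(
            dict(level=level, reference=ref,
                 estimate=float(fit.params[name]),
                 se=float(fit.bse[name]),
                 p=float(fit.pvalues[name]))
        )
    out = pd.DataFrame(rows).set_index("level")
    out.attrs["group_var"] = fit_group_var
    out.attrs["intercept"] = float(fit.params["Intercept"])
    return out
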