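"""Paired condition contrasts and heteroscedasticity-robust OLS.

Two model families link individual differences to gaze behaviour, fitted
separately per condition and outcome on raw (unstandardised) units:

* trait model:      outcome ~ 1 + aq + age + sex
* discomfort model: outcome ~ 1 + discomfort + age + sex

Coefficient covariance uses the HC3 sandwich estimator by default
(recommended for small samples), with t statistics referred to a
t-distribution on n - p residual degrees of freedom. The report also
echoes n - 1 (``df_echo``) because small-sample studies often print t(n-1)
regardless of model size; the n - p convention is the one used for
inference here. Effect sizes are partial eta squared, t^2 / (t^2 + df).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateTestError

__all__ = [
    "PairedTestResult",
    "RegressionTerm",
    "RegressionResult",
    "paired_t",
    "ols_robust",
    "partial_eta_squared",
    "added_variable_data",
    "run_models",
    "coefficient_table",
]

_HC_TYPES = ("HC0", "HC1", "HC2", "HC3")


@dataclass
class PairedTestResult:
    """Classical paired t-test on within-participant differences x - y."""

    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"mean_diff": self.mean_diff, "sd_diff": self.sd_diff,
                "t": self.t, "df": self.df, "p": self.p, "n": self.n}


@dataclass
class RegressionTerm:
    name: str
    beta: float
    robust_se: float
    t: float
    p: float
    partial_eta_sq: float


@dataclass
class RegressionResult:
    """OLS fit with sandwich (HC) standard errors."""

    terms: Dict[str, RegressionTerm]
    df_resid: int
    df_echo: int          # n - 1, for comparability with t(n-1) reporting
    n: int
    hc_type: str
    r_squared: float

    def __getitem__(self, name: str) -> RegressionTerm:
        return self.terms[name]

    def to_dict(self) -> dict:
        return {
            "terms": {k: vars(v) for k, v in self.terms.items()},
            "df_resid": self.df_resid, "df_echo": self.df_echo, "n": self.n,
            "hc_type": self.hc_type, "r_squared": self.r_squared,
        }


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired t-test on pairwise-complete data.

    Raises :class:`DegenerateTestError` when the differences have zero
    variance (the statistic would be infinite or undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    complete = np.isfinite(x) & np.isfinite(y)
    d = x[complete] - y[complete]
    n = d.size
    if n < 3:
        raise DegenerateTestError(f"need at least 3 complete pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateTestError(
            f"zero variance of paired differences (all equal to {mean})")
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTestResult(mean, sd, t, df, p, n)


def partial_eta_squared(t: float, df: int) -> float:
    """Partial eta squared for a single regression term: t^2 / (t^2 + df)."""
    if df <= 0:
        raise DegenerateTestError(f"degrees of freedom must be positive, got {df}")
    return float(t * t / (t * t + df))


def _design_matrix(design: pd.DataFrame, add_intercept: bool) -> pd.DataFrame:
    X = design.copy()
    X = X.astype(float)
    if add_intercept:
        if "intercept" in X.columns:
            raise ConfigurationError("design already contains an 'intercept' column")
        X.insert(0, "intercept", 1.0)
    return X


def ols_robust(response, design: pd.DataFrame, hc_type: str = "HC3",
               add_intercept: bool = True) -> RegressionResult:
    """OLS point estimates with a heteroscedasticity-consistent covariance.

    The sandwich is (X'X)^-1 X' Omega X (X'X)^-1 with Omega = diag of
    squared residuals rescaled by leverage per the chosen HC variant
    (HC3: e_i^2 / (1 - h_i)^2). Inference uses a t-distribution on n - p df.
    """
    if hc_type not in _HC_TYPES:
        raise ConfigurationError(f"hc_type must be one of {_HC_TYPES}, got {hc_type!r}")
    y = np.asarray(response, dtype=float)
    X = _design_matrix(design, add_intercept)
    n, p = X.shape
    if n <= p:
        raise ConfigurationError(f"n = {n} observations cannot fit {p} terms")
    Xv = X.to_numpy()
    if not np.isfinite(Xv).all() or not np.isfinite(y).all():
        raise ConfigurationError("design or response contains non-finite values")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        raise ConfigurationError(
            f"design matrix is rank deficient (rank {rank} < {p} terms): "
            f"columns {list(X.columns)}")
    h = np.einsum("ij,ji->i", Xv, np.linalg.pinv(Xv))
    at_one = np.nonzero(h >= 1.0 - 1e-10)[0]
    if hc_type in ("HC2", "HC3") and at_one.size:
        raise ConfigurationError(
            f"observation(s) {at_one.tolist()} have leverage 1; "
            f"{hc_type} weights are undefined")
    fit = sm.OLS(y, Xv).fit(cov_type=hc_type, use_t=True)
    df_resid = n - p
    terms = {}
    for j, name in enumerate(X.columns):
        beta = float(fit.params[j])
        se = float(fit.bse[j])
        t = beta / se if se > 0 else math.inf * np.sign(beta)
        pval = 2.0 * float(sps.t.sf(abs(t), df_resid)) if np.isfinite(t) else 0.0
        terms[name] = RegressionTerm(name, beta, se, t, pval,
                                     partial_eta_squared(t, df_resid)
                                     if np.isfinite(t) else 1.0)
    return RegressionResult(terms, df_resid, n - 1, n, hc_type,
                            float(fit.rsquared))


def added_variable_data(response, design: pd.DataFrame, focus_term: str,
                        add_intercept: bool = True):
    """Partial-regression (added-variable) data for one focus term.

    Returns ``(focus_residuals, response_residuals, slope)`` where both
    residual vectors come from regressing out the remaining terms. By the
    Frisch-Waugh-Lovell theorem the OLS slope through the residual pairs
    equals the multiple-regression coefficient of the focus term; this is
    verified to 1e-8 before returning.
    """
    if focus_term not in design.columns:
        raise ConfigurationError(f"focus term {focus_term!r} not in design")
    y = np.asarray(response, dtype=float)
    X = _design_matrix(design, add_intercept)
    others = X.drop(columns=[focus_term]).to_numpy()
    f = X[focus_term].to_numpy()
    beta_others, *_ = np.linalg.lstsq(others, f, rcond=None)
    f_resid = f - others @ beta_others
    gamma, *_ = np.linalg.lstsq(others, y, rcond=None)
    y_resid = y - others @ gamma
    slope = float(f_resid @ y_resid / (f_resid @ f_resid))
    full = ols_robust(y, design, add_intercept=add_intercept)
    if abs(slope - full[focus_term].beta) > 1e-8:
        raise AssertionError(
            "Frisch-Waugh-Lovell equality violated: added-variable slope "
            f"{slope} vs multiple-regression beta {full[focus_term].beta}")
    return f_resid, y_resid, slope


# ---------------------------------------------------------------------------
# model battery
# ---------------------------------------------------------------------------

_OUTCOMES = ("eye_gaze_pct", "mutual_pct")


def run_models(cohort: pd.DataFrame, condition_metrics: pd.DataFrame,
               hc_type: str = "HC3", combined: bool = False) -> dict:
    """Fit the full model battery and condition contrasts.

    ``cohort`` needs columns id, aq, age, sex, discomfort;
    ``condition_metrics`` needs participant_id, condition, eye_gaze_pct,
    mutual_pct, missing_pct (one row per participant x condition).

    Per condition x outcome: the AQ (trait) model and the discomfort model
    (optionally one combined model with both predictors). Across
    conditions: paired t-tests for each outcome and for missingness (the
    control analysis that condition differences are not driven by missing
    data). Returns a JSON-serialisable report.
    """
    needed = {"id", "aq", "age", "sex", "discomfort"}
    if not needed <= set(cohort.columns):
        raise ConfigurationError(f"cohort table lacks columns {needed - set(cohort.columns)}")
    wide = condition_metrics.pivot(index="participant_id", columns="condition",
                                   values=["eye_gaze_pct", "mutual_pct", "missing_pct"])
    merged = cohort.set_index("id").loc[wide.index.intersection(cohort["id"])]
    wide = wide.loc[merged.index]
    incomplete = merged[merged[["aq", "age", "sex", "discomfort"]].isna().any(axis=1)]
    if len(incomplete):
        raise ConfigurationError(
            f"missing covariates for participants: {list(incomplete.index)}")

    report = {
        "meta": {
            "n": int(len(merged)),
            "hc_type": hc_type,
            "sex_coding": "0=female, 1=male",
            "df_note": ("inference uses df_resid = n - p; df_echo = n - 1 is "
                        "included for comparability with t(n-1) reporting"),
        },
        "models": {},
        "paired_tests": {},
    }
    for condition in ("DESCRIBE", "GUESS"):
        report["models"][condition] = {}
        for outcome in _OUTCOMES:
            y = wide[(outcome, condition)].to_numpy(dtype=float)
            block = {}
            specs = {
                "aq": ["aq", "age", "sex"],
                "discomfort": ["discomfort", "age", "sex"],
            }
            if combined:
                specs["combined"] = ["aq", "discomfort", "age", "sex"]
            for label, cols in specs.items():
                design = merged[cols].astype(float)
                design.columns = cols
                block[label] = ols_robust(y, design, hc_type=hc_type).to_dict()
            report["models"][condition][outcome] = block
    for outcome in ("eye_gaze_pct", "mutual_pct", "missing_pct"):
        g = wide[(outcome, "GUESS")].to_numpy(dtype=float)
        d = wide[(outcome, "DESCRIBE")].to_numpy(dtype=float)
        try:
            # describing minus guessing: negative t means less eye gaze while
            # describing, matching the directional convention of the contrast
            report["paired_tests"][outcome] = paired_t(d, g).to_dict()
        except DegenerateTestError as exc:
            report["paired_tests"][outcome] = {"error": str(exc)}
    return report


def coefficient_table(report: dict) -> pd.DataFrame:
    """Flatten a run_models report into a tidy coefficient table."""
    rows = []
    for condition, outcomes in report["models"].items():
        for outcome, models in outcomes.items():
            for model_label, res in models.items():
                for term, stats_ in res["terms"].items():
                    rows.append({
                        "condition": condition, "outcome": outcome,
                        "model": model_label, "term": term,
                        "beta": stats_["beta"], "robust_se": stats_["robust_se"],
                        "t": stats_["t"], "p": stats_["p"],
                        "partial_eta_sq": stats_["partial_eta_sq"],
                        "df_resid": res["df_resid"], "n": res["n"],
                        "hc_type": res["hc_type"],
                    })
    return pd.DataFrame(rows)
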