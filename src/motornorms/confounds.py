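"""Confound modelling: predictive OLS with a repeated cross-validation
generalizability gate, and full-data coefficient estimation.

The model is ``parameter ~ age + sex + height + weight + study`` with sex
dummy-coded (female 0, male 1) and study as an effect-coded (sum-to-zero)
control variable. Generalizability is judged by the coefficient of
determination on held-out folds, Rtest^2 = 1 - SSres/SStot — which, unlike a
squared correlation, is negative when predictions are worse than the
test-fold mean. Predictions for held-out data omit the study term, emulating
application of the model to external data. Only parameters whose mean
Rtest^2 over 100 repetitions of 5-fold CV exceeds 0.1 are considered to
carry a generalizable confound association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import Subject

COVARIATE_COLUMNS = ("const", "age", "sex", "height", "weight")


def encode_design(subjects: list[Subject]) -> pd.DataFrame:
    """Design matrix: intercept, age, sex (female 0 / male 1), height,
    weight, and k-1 effect-coded study columns (reference level =
    lexicographically last study label, coded -1).

    Raises on a constant covariate (an unestimable column).
    """
    df = pd.DataFrame({
        "const": 1.0,
        "age": [s.age for s in subjects],
        "sex": [float(s.sex_code) for s in subjects],
        "height": [s.height for s in subjects],
        "weight": [s.weight for s in subjects],
    }, index=[s.subject_id for s in subjects])
    for col in ("age", "sex", "height", "weight"):
        if df[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant; design is rank-deficient")
    studies = sorted({s.study for s in subjects})
    if len(studies) >= 2:
        ref = studies[-1]
        for lvl in studies[:-1]:
            col = np.zeros(len(subjects))
            for i, s in enumerate(subjects):
                if s.study == lvl:
                    col[i] = 1.0
                elif s.study == ref:
                    col[i] = -1.0
            df[f"study_{lvl}"] = col
    return df


@dataclass
class Coefficient:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ConfoundModel:
    """Fitted linear confound model for one parameter.

    Only the intercept and the four covariate terms are used for
    prediction; the study effects are estimation controls.
    """

    parameter: str
    coefficients: dict[str, Coefficient]
    residual_sd: float
    n: int
    study_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be positive")
        for name, c in self.coefficients.items():
            if not (c.ci_low <= c.estimate <= c.ci_high):
                raise ValueError(f"CI does not bracket the estimate for {name}")

    def predict(self, subject: Subject) -> float:
        """Linear predictor from the covariates (study term never used)."""
        c = self.coefficients
        return (
            c["const"].estimate
            + c["age"].estimate * subject.age
            + c["sex"].estimate * subject.sex_code
            + c["height"].estimate * subject.height
            + c["weight"].estimate * subject.weight
        )


def fit_ols(design: pd.DataFrame, y, parameter: str = "") -> ConfoundModel:
    """Full-data OLS fit with classical 95% CIs and p-values.

    The residual SD uses denominator n - p (p = number of model columns,
    including the effect-coded study terms).
    """
    y = np.asarray(y, dtype=float)
    if len(design) <= design.shape[1]:
        raise ValueError("need more observations than design columns")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    coeffs = {}
    study_effects = {}
    for name in design.columns:
        if name.startswith("study_"):
            study_effects[name] = float(res.params[name])
        else:
            coeffs[name] = Coefficient(
                estimate=float(res.params[name]),
                ci_low=float(ci.loc[name, 0]),
                ci_high=float(ci.loc[name, 1]),
                p_value=float(res.pvalues[name]),
            )
    return ConfoundModel(
        parameter=parameter,
        coefficients=coeffs,
        residual_sd=float(np.sqrt(res.scale)),
        n=int(res.nobs),
        study_effects=study_effects,
    )


@dataclass
class CVReport:
    """Result of the repeated k-fold cross-validation of one parameter."""

    parameter: str
    mean_rtest2: float
    per_repetition: np.ndarray
    repeats: int
    folds: int
    n_excluded_folds: int = 0
    threshold: float = 0.1

    @property
    def gate(self) -> bool:
        return bool(self.mean_rtest2 > self.threshold)


def _rep_rng(master_seed: int, repetition: int) -> np.random.Generator:
    """Per-repetition generator derived from the master seed by a counter."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, repetition]))


def repeated_cv_r2(
    design: pd.DataFrame,
    y,
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
    parameter: str = "",
    threshold: float = 0.1,
    sstot_baseline: str = "test",
) -> CVReport:
    """Mean test-fold R^2 over repeated shuffled k-fold cross-validation.

    Per fold the model (with study terms) is fitted on the training rows and
    held-out rows are predicted from the intercept + covariate terms only.
    ``sstot_baseline`` chooses the R^2 baseline mean: the test fold's own
    mean (default) or the training mean (``"train"``). Folds with constant
    outcome are excluded and counted.
    """
    X = design.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError("need at least as many observations as folds")
    cov_mask = np.array([not c.startswith("study_") for c in design.columns])

    per_rep = np.empty(repeats)
    excluded = 0
    for rep in range(repeats):
        rng = _rep_rng(seed, rep)
        perm = rng.permutation(n)
        r2s = []
        for fold_idx in np.array_split(perm, folds):
            train = np.setdiff1d(perm, fold_idx, assume_unique=True)
            beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
            yhat = X[np.ix_(fold_idx, np.flatnonzero(cov_mask))] @ beta[cov_mask]
            ytest = y[fold_idx]
            baseline = ytest.mean() if sstot_baseline == "test" else y[train].mean()
            sstot = float(np.sum((ytest - baseline) ** 2))
            if sstot == 0.0:
                excluded += 1
                continue
            ssres = float(np.sum((ytest - yhat) ** 2))
            r2s.append(1.0 - ssres / sstot)
        per_rep[rep] = np.mean(r2s) if r2s else np.nan
    mean = float(np.nanmean(per_rep))
    return CVReport(parameter=parameter, mean_rtest2=mean,
                    per_repetition=per_rep, repeats=repeats, folds=folds,
                    n_excluded_folds=excluded, threshold=threshold)


def generalizability_gate(report: CVReport, threshold: float = 0.1) -> bool:
    """Strict gate: mean test-fold R^2 must exceed the threshold."""
    return bool(report.mean_rtest2 > threshold)


def screen_parameters(
    subjects: list[Subject],
    features: pd.DataFrame,
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, ConfoundModel]]:
    """Run the full confound-screening procedure over all parameters.

    Returns a report frame (parameter, mean Rtest^2, gate) and, for gated
    parameters, the full-data :class:`ConfoundModel`.
    """
    design = encode_design(subjects)
    rows = []
    models: dict[str, ConfoundModel] = {}
    for key in features.columns:
        col = features[key].to_numpy(dtype=float)
        ok = np.isfinite(col)
        if ok.sum() < max(folds, design.shape[1] + 2):
            rows.append({"parameter": key, "mean_rtest2": np.nan, "gate": False})
            continue
        d = design.loc[features.index[ok]]
        rep = repeated_cv_r2(d, col[ok], repeats=repeats, folds=folds,
                             seed=seed, parameter=key, threshold=threshold)
        gated = generalizability_gate(rep, threshold)
        rows.append({"parameter": key, "mean_rtest2": rep.mean_rtest2,
                     "gate": gated})
        if gated:
            models[key] = fit_ols(d, col[ok], parameter=key)
    return pd.DataFrame(rows).set_index("parameter"), models
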