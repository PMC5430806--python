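"""Standardized regression suite for centrality, fertility and sickness.

All models are ordinary least squares with camp fixed effects and
predictors standardized over two sample standard deviations: a continuous
predictor enters as (x - mean)/(2*SD) while binary predictors are left
untouched, which puts their coefficients on a comparable footing (a
two-SD move of a roughly symmetric continuous variable resembles a 0->1
flip of a balanced binary one). Age is mean-centred before scaling, and
interaction columns are products of the standardized mains, so main
effects stay interpretable at the sample mean.

The suite covers:

- single-centrality fertility models (age-residualized offspring on one
  standardized centrality measure), optionally with a centrality-by-age
  interaction that is pruned when insignificant at p > 0.05;
- joint degree + betweenness + closeness models, guarded by variance
  inflation factors (collinearity flagged above VIF 2.5);
- sickness models (0-2 diagnosed instances on centrality plus maternal
  age, camp settledness, mobility and household belongings), with an
  optional number-of-dependents term whose inclusion operationalizes a
  mediation check by coefficient attenuation.

Inference is textbook OLS: t-based p-values and 95% CIs on residual
degrees of freedom, no small-sample corrections, no multiple-testing
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (CollinearityError, DegenerateDataError)

VIF_LIMIT = 2.5
SICKNESS_CONTROLS = ("age", "settled", "mobile", "belongings")


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def two_sd_standardize(df: pd.DataFrame, columns: list[str],
                       age_center: float | None = None) -> pd.DataFrame:
    """Return a copy with the named columns standardized over 2 SD.

    Continuous columns become (x - mean)/(2*SD) (sample SD, n-1); binary
    columns pass through unchanged. A column named ``age`` is centred at
    ``age_center`` (default: its sample mean) before scaling. Raises on a
    zero-variance continuous column.
    """
    out = df.copy()
    for col in columns:
        x = df[col].astype(float)
        if _is_binary(x):
            out[col] = x
            continue
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateDataError(f"zero-variance predictor {col!r}")
        center = x.mean()
        if col == "age" and age_center is not None:
            center = float(age_center)
        out[col] = (x - center) / (2.0 * sd)
    return out


@dataclass
class ModelResult:
    """One fitted model: standardized terms, fit quality, diagnostics."""

    outcome: str
    terms: pd.DataFrame            # term, beta, se, ci_lo, ci_hi, p
    adj_r2: float
    n: int
    vif: dict | None = None
    interaction_retained: bool | None = None
    _refit_without_interaction: Callable[[], "ModelResult"] | None = \
        field(default=None, repr=False, compare=False)

    def _row(self, term: str) -> pd.Series:
        hit = self.terms.loc[self.terms["term"] == term]
        if hit.empty:
            raise KeyError(f"no term {term!r} in model; have "
                           f"{self.terms['term'].tolist()}")
        return hit.iloc[0]

    def beta(self, term: str) -> float:
        return float(self._row(term)["beta"])

    def p(self, term: str) -> float:
        return float(self._row(term)["p"])

    def ci(self, term: str) -> tuple[float, float]:
        r = self._row(term)
        return float(r["ci_lo"]), float(r["ci_hi"])


def _ols(y: np.ndarray, X: pd.DataFrame, outcome: str,
         vif: dict | None = None,
         interaction_retained: bool | None = None) -> ModelResult:
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise CollinearityError(
            f"rank-deficient design with columns {list(Xc.columns)}")
    res = sm.OLS(np.asarray(y, dtype=float), Xc).fit()
    ci = res.conf_int(alpha=0.05)
    terms = pd.DataFrame({
        "term": list(Xc.columns),
        "beta": np.asarray(res.params, dtype=float),
        "se": np.asarray(res.bse, dtype=float),
        "ci_lo": np.asarray(ci)[:, 0],
        "ci_hi": np.asarray(ci)[:, 1],
        "p": np.asarray(res.pvalues, dtype=float),
    })
    return ModelResult(outcome=outcome, terms=terms,
                       adj_r2=float(res.rsquared_adj), n=int(res.nobs),
                       vif=vif, interaction_retained=interaction_retained)


def _camp_dummies(camp: pd.Series) -> pd.DataFrame:
    d = pd.get_dummies(camp.astype(str), prefix="camp", drop_first=True)
    return d.astype(float)


def compute_vif(design: pd.DataFrame,
                assess: list[str] | None = None) -> dict:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j).

    Each assessed predictor is regressed (with intercept) on every other
    design column — camp indicators included as regressors but not
    themselves assessed unless requested. Perfect collinearity yields
    ``inf``.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise DegenerateDataError("VIF needs at least two predictors")
    if assess is None:
        assess = [c for c in cols if not c.startswith("camp_")]
    X = design.astype(float)
    out = {}
    for col in assess:
        others = sm.add_constant(X.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def fit_fertility_model(data: pd.DataFrame, measure: str,
                        interaction_with_age: bool = False,
                        age_center: float | None = None) -> ModelResult:
    """OLS of fertility residuals on one standardized centrality measure.

    ``data`` needs columns ``residual``, ``z_<measure>``, ``age`` and
    ``camp``. Camp membership enters as fixed-effect indicator columns.
    With ``interaction_with_age`` a product of the standardized centrality
    and standardized centred age is added; :func:`prune_interaction`
    implements the keep-it-only-if-significant rule.
    """
    zcol = f"z_{measure}"
    if len(data) < 4:
        raise DegenerateDataError(f"too few rows ({len(data)}) to fit")
    std = two_sd_standardize(data[[zcol, "age"]].copy(), [zcol, "age"],
                             age_center=age_center)
    X = pd.DataFrame({measure: std[zcol]})
    if interaction_with_age:
        X[f"{measure}:age"] = std[zcol] * std["age"]
        X["age"] = std["age"]
    X = pd.concat([X, _camp_dummies(data["camp"])], axis=1)
    X.index = data.index
    return _ols(data["residual"].to_numpy(), X, outcome="fertility_residual",
                interaction_retained=interaction_with_age or None)


def prune_interaction(result: ModelResult, threshold: float = 0.05
                      ) -> ModelResult:
    """Drop the age interaction when it is insignificant (p > threshold).

    Returns the original model flagged ``interaction_retained=True`` when
    the interaction survives, otherwise the refit without it flagged
    ``False``. The model must have been fitted with an interaction and a
    refit closure.
    """
    inter = [t for t in result.terms["term"] if t.endswith(":age")]
    if not inter or result._refit_without_interaction is None:
        raise ValueError("model was not fitted with a prunable interaction")
    if result.p(inter[0]) > threshold:
        refit = result._refit_without_interaction()
        refit.interaction_retained = False
        return refit
    result.interaction_retained = True
    return result


def fit_fertility_with_pruning(data: pd.DataFrame, measure: str,
                               threshold: float = 0.05,
                               age_center: float | None = None
                               ) -> ModelResult:
    """Fit with the age interaction, then apply the pruning rule."""
    full = fit_fertility_model(data, measure, interaction_with_age=True,
                               age_center=age_center)
    full._refit_without_interaction = lambda: fit_fertility_model(
        data, measure, interaction_with_age=False, age_center=age_center)
    return prune_interaction(full, threshold)


def fit_joint_model(data: pd.DataFrame,
                    measures: tuple[str, ...] = ("degree", "betweenness",
                                                 "closeness"),
                    vif_mode: str = "warn",
                    age_center: float | None = None) -> ModelResult:
    """Joint OLS of fertility residuals on several centrality measures.

    A VIF report over the centrality columns (camp indicators as
    regressors) is attached. When any VIF exceeds 2.5 the fit proceeds
    with a warning in ``warn`` mode and raises :class:`CollinearityError`
    in ``abort`` mode.
    """
    zcols = [f"z_{m}" for m in measures]
    std = two_sd_standardize(data[zcols].copy(), zcols)
    X = std.rename(columns=dict(zip(zcols, measures)))
    X = pd.concat([X, _camp_dummies(data["camp"])], axis=1)
    X.index = data.index
    vif = compute_vif(X, assess=list(measures))
    breaches = {k: v for k, v in vif.items() if v > VIF_LIMIT}
    if breaches:
        if vif_mode == "abort":
            raise CollinearityError(
                f"VIF above {VIF_LIMIT}: {breaches}")
        import logging
        logging.getLogger(__name__).warning(
            "VIF above %.1f: %s (fitting anyway)", VIF_LIMIT, breaches)
    return _ols(data["residual"].to_numpy(), X,
                outcome="fertility_residual", vif=vif)


def fit_sickness_model(data: pd.DataFrame, measure: str,
                       include_dependents: bool = False,
                       family: str = "ols") -> ModelResult:
    """Regress sickness instances (0-2) on centrality plus controls.

    Medical-survey outcomes exist for one population only, so ``data``
    should already be restricted to it. Controls are maternal age, camp settledness, individual mobility and
    household belongings; ``include_dependents`` adds the number of living
    dependents (the mediation candidate). Camp enters through the settled
    flag rather than fixed effects (camp indicators would absorb the
    camp-level settledness control outright). Default family is OLS on
    the count with standardized predictors; ``family="poisson"`` fits the
    same mean structure with a log link instead.
    """
    y = data["sickness_count"].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise DegenerateDataError("sickness outcome is constant")
    zcol = f"z_{measure}"
    cols = [zcol, *SICKNESS_CONTROLS]
    if include_dependents:
        cols.append("n_dependents")
    # a binary control with no in-sample variation (e.g. every camp
    # settled) carries no information and would break the design
    constant = [c for c in cols if _is_binary(data[c])
                and data[c].nunique() < 2]
    if constant:
        import logging
        logging.getLogger(__name__).warning(
            "dropping constant control(s) %s from sickness model", constant)
        cols = [c for c in cols if c not in constant]
    std = two_sd_standardize(data[cols].copy(), cols)
    X = std.rename(columns={zcol: measure})
    X.index = data.index
    if family == "ols":
        return _ols(y, X, outcome="sickness_count")
    if family == "poisson":
        Xc = sm.add_constant(X.astype(float), has_constant="add")
        res = sm.GLM(y, Xc, family=sm.families.Poisson()).fit()
        ci = np.asarray(res.conf_int(alpha=0.05))
        terms = pd.DataFrame({
            "term": list(Xc.columns),
            "beta": np.asarray(res.params, dtype=float),
            "se": np.asarray(res.bse, dtype=float),
            "ci_lo": ci[:, 0], "ci_hi": ci[:, 1],
            "p": np.asarray(res.pvalues, dtype=float)})
        return ModelResult(outcome="sickness_count", terms=terms,
                           adj_r2=float("nan"), n=int(res.nobs))
    raise ValueError(f"unknown family {family!r}")


@dataclass
class MediationSummary:
    """Coefficient attenuation when the mediator enters the model."""

    term: str
    beta_without: float
    beta_with: float
    attenuation: float             # 1 - beta_with/beta_without
    significant_without: bool
    significant_with: bool


def mediation_check(model_without: ModelResult, model_with: ModelResult,
                    term: str, alpha: float = 0.05) -> MediationSummary:
    """Compare a term's coefficient before and after adding the mediator.

    Attenuation is the proportional shrinkage 1 - beta_with/beta_without
    (0 for identical coefficients, 1 for complete attenuation, negative
    if the coefficient grew). The two models must be fitted on the same
    sample.
    """
    if model_without.n != model_with.n:
        raise ValueError(
            f"sample mismatch: n={model_without.n} vs n={model_with.n}")
    b0, b1 = model_without.beta(term), model_with.beta(term)
    att = float("nan") if b0 == 0 else 1.0 - b1 / b0
    return MediationSummary(
        term=term, beta_without=b0, beta_with=b1, attenuation=att,
        significant_without=model_without.p(term) < alpha,
        significant_with=model_with.p(term) < alpha)


def write_coefficients_csv(results: dict[str, ModelResult], path,
                           population: str = "A") -> None:
    """Tidy coefficient export across a dictionary of fitted models."""
    rows = []
    for name, res in results.items():
        for r in res.terms.itertuples(index=False):
            rows.append({
                "population": population, "model": name, "term": r.term,
                "beta": r.beta, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
                "p": r.p, "adj_r2": res.adj_r2,
                "vif": (res.vif or {}).get(r.term, float("nan")),
                "interaction_retained": res.interaction_retained})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
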