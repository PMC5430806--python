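"""Age-controlled reproductive success from living-offspring counts.

The number of currently living offspring confounds fertility with
maternal age, so each population's counts are regressed on age and age
squared with a Poisson log-link (counts are small and discrete; the
quadratic captures the rise and plateau of cumulative fertility). The
quantity carried downstream is the *response residual*

    r_i = observed_i - fitted_i ,

read in offspring units: 0 means an age-typical number of living
offspring, negative below average for one's age, positive above. By the
Poisson score equations the residuals are exactly orthogonal to the
intercept, age and age^2 columns, so no age signal survives in them.

The maximum-likelihood fit is delegated to statsmodels' IRLS and then
polished with a few Newton steps on a rescaled design until the score
vector is at numerical zero; this makes the orthogonality identities hold
to ~1e-8 even against the raw age^2 column, whose entries reach several
thousand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConvergenceError, DegenerateDataError, MissingDataError

_AGE_SCALE = 50.0  # years; conditions the quadratic design


@dataclass
class AgeFertilityFit:
    """Quadratic Poisson age model for one population."""

    coef: np.ndarray               # (intercept, age, age^2) on log scale
    converged: bool
    fitted: pd.Series = field(repr=False)   # mean offspring per mother id
    deviance: float = float("nan")
    null_deviance: float = float("nan")

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        eta = self.coef[0] + self.coef[1] * age + self.coef[2] * age ** 2
        return np.exp(eta)


def _design(age: np.ndarray) -> np.ndarray:
    a = age / _AGE_SCALE
    return np.column_stack([np.ones_like(a), a, a ** 2])


def fit_age_fertility(mothers: pd.DataFrame, tol: float = 1e-10,
                      max_iter: int = 200) -> AgeFertilityFit:
    """Fit living offspring ~ Poisson(exp(a + b*age + c*age^2)).

    Expects columns ``id``, ``age``, ``n_living_offspring``; one call per
    population. Requires at least 10 mothers spanning at least 3 distinct
    ages. Convergence is declared when the max-norm of the score vector on
    the rescaled design falls below ``tol``; otherwise
    :class:`ConvergenceError` reports the trailing residuals.
    """
    if len(mothers) < 10:
        raise DegenerateDataError(
            f"need >= 10 mothers to fit the age curve, got {len(mothers)}")
    age = mothers["age"].to_numpy(dtype=float)
    y = mothers["n_living_offspring"].to_numpy(dtype=float)
    if len(np.unique(age)) < 3:
        raise DegenerateDataError("need >= 3 distinct ages for a quadratic")

    X = _design(age)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
    beta = np.asarray(res.params, dtype=float)

    # Newton polish: drive the score to numerical zero so the residual
    # orthogonality identities hold against raw age moments too.
    trace = []
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        score = X.T @ (y - mu)
        trace.append(float(np.abs(score).max()))
        if trace[-1] < tol:
            break
        H = X.T @ (mu[:, None] * X)
        beta = beta + np.linalg.solve(H, score)
    else:
        raise ConvergenceError(
            f"Poisson age fit: score norm trace {trace[-5:]} (tol {tol})")

    mu = np.exp(X @ beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
        ybar = y.mean()
        null_dev = 2.0 * np.sum(
            np.where(y > 0, y * np.log(y / ybar), 0.0) - (y - ybar))
    raw = np.array([beta[0], beta[1] / _AGE_SCALE, beta[2] / _AGE_SCALE ** 2])
    return AgeFertilityFit(coef=raw, converged=True,
                           fitted=pd.Series(mu, index=mothers["id"].to_numpy()),
                           deviance=float(dev), null_deviance=float(null_dev))


def fit_by_population(mothers: pd.DataFrame) -> dict[str, AgeFertilityFit]:
    """One age-fertility fit per population (no pooling across them)."""
    return {pop: fit_age_fertility(grp)
            for pop, grp in mothers.groupby("population")}


def read_mothers_csv(path) -> pd.DataFrame:
    """Read the mothers dialect ``id,camp,population,age,offspring,
    dependents,sickness,settled,mobile,belongings`` into analysis names."""
    df = pd.read_csv(path, dtype={"id": str, "camp": str, "population": str})
    rename = {"offspring": "n_living_offspring",
              "dependents": "n_dependents", "sickness": "sickness_count"}
    missing = [c for c in ("id", "camp", "age", "offspring") if c not in df]
    if missing:
        from .errors import FormatError
        raise FormatError(f"mothers file {path!r} missing columns {missing}")
    return df.rename(columns=rename)


def write_residuals_csv(residuals: pd.DataFrame, path) -> None:
    residuals.to_csv(path, index=False, float_format="%.10g")


def fertility_residuals(mothers: pd.DataFrame,
                        fit: AgeFertilityFit) -> pd.DataFrame:
    """Observed minus fitted living offspring per mother (response scale).

    Returns ``id,residual``; residuals sum to zero and are orthogonal to
    age and age squared up to solver tolerance.
    """
    missing = [i for i in mothers["id"] if i not in fit.fitted.index]
    if missing:
        raise MissingDataError(f"mothers absent from fit: {missing[:10]}")
    resid = (mothers["n_living_offspring"].to_numpy(dtype=float)
             - fit.fitted.loc[mothers["id"]].to_numpy())
    return pd.DataFrame({"id": mothers["id"].to_numpy(), "residual": resid})
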