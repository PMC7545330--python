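"""Two-level random-slope linear models with empirical-Bayes person estimates.

Thin, contract-enforcing wrapper around :class:`statsmodels` MixedLM.
A model has a random intercept plus one random slope per lagged
predictor (at most two predictors). Person-specific coefficients are
empirical-Bayes (EB) estimates: fixed effect plus the conditional
(posterior) mean of the person's random effect, i.e. shrunk toward the
population value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = [
    "MixedModelSpec",
    "MixedModelFit",
    "ConvergenceError",
    "fit_random_slope_model",
    "empirical_bayes_coefficients",
    "within_share",
    "variance_components",
    "icc",
]


class ConvergenceError(RuntimeError):
    """Raised when neither the full nor the diagonal model converges."""


@dataclass(frozen=True)
class MixedModelSpec:
    """Outcome, up to two predictors, and centering/estimation options."""

    outcome: str
    predictors: tuple[str, ...] = ()
    center_within: bool = True
    reml: bool = True

    def __post_init__(self):
        if len(self.predictors) > 2:
            raise ValueError("at most 2 predictors are supported")


@dataclass
class MixedModelFit:
    """Fitted fixed effects, variance components, and EB person coefficients."""

    spec: MixedModelSpec
    fixed_effects: pd.Series
    cov_re: pd.DataFrame
    resid_var: float
    eb: pd.DataFrame  # one row per person: fixed + predicted random effect
    converged: bool
    diagonal_fallback: bool
    n_groups: int
    n_rows: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "predictors": list(self.spec.predictors),
            "fixed_effects": self.fixed_effects.to_dict(),
            "cov_re": self.cov_re.to_numpy().tolist(),
            "resid_var": self.resid_var,
            "converged": self.converged,
            "diagonal_fallback": self.diagonal_fallback,
            "n_groups": self.n_groups,
            "n_rows": self.n_rows,
        }


def _center_within(df: pd.DataFrame, cols, group_col: str) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        df[c] = df[c] - df.groupby(group_col)[c].transform("mean")
    return df


def fit_random_slope_model(
    rows: pd.DataFrame,
    spec: MixedModelSpec,
    group_col: str = "person_id",
) -> MixedModelFit:
    """REML (default) fit of a random-intercept/random-slope model.

    ``rows`` holds one row per usable observation with the outcome,
    predictor, and grouping columns. The random-effects covariance is
    unstructured; on non-convergence the model is automatically refit
    with a diagonal covariance and flagged.
    """
    needed = [group_col, spec.outcome, *spec.predictors]
    df = rows[needed].dropna().copy()
    if not np.isfinite(df[[spec.outcome, *spec.predictors]].to_numpy()).all():
        raise ValueError("non-finite outcome or predictor values")
    sizes = df.groupby(group_col).size()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 persons with at least 2 rows each")
    if spec.center_within and spec.predictors:
        df = _center_within(df, spec.predictors, group_col)

    exog_names = ["const", *spec.predictors]
    exog = np.column_stack(
        [np.ones(len(df))] + [df[p].to_numpy() for p in spec.predictors]
    )
    endog = df[spec.outcome].to_numpy()
    groups = df[group_col].to_numpy()
    model = MixedLM(endog, exog, groups=groups, exog_re=exog)

    k_fe = exog.shape[1]
    free = MixedLMParams.from_components(fe_params=np.ones(k_fe), cov_re=np.eye(k_fe))
    # full covariance first; automatic diagonal fallback on non-convergence
    attempts = [
        (False, {"method": "lbfgs", "maxiter": 200}),
        (False, {"method": "powell", "maxiter": 500}),
        (False, {"method": "nm", "maxiter": 2000}),
        (True, {"method": "lbfgs", "maxiter": 200, "free": free}),
        (True, {"method": "powell", "maxiter": 500, "free": free}),
        (True, {"method": "nm", "maxiter": 2000, "free": free}),
    ]
    result, diagonal = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for diag, kwargs in attempts:
            try:
                cand = model.fit(reml=spec.reml, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if _acceptable(cand):
                result, diagonal = cand, diag
                break
    if result is None:
        raise ConvergenceError(
            f"mixed model for {spec.outcome!r} did not converge "
            f"(n_groups={sizes.size}, n_rows={len(df)})"
        )

    fe = pd.Series(result.fe_params, index=exog_names)
    cov_re = pd.DataFrame(
        np.asarray(result.cov_re), index=exog_names, columns=exog_names
    )
    # EB person coefficients: fixed effect + conditional mean of the random
    # effect, b_i = G Z_i' (Z_i G Z_i' + s2 I)^-1 (y_i - X_i beta). Computed
    # directly so boundary (singular) covariance estimates still work.
    G = cov_re.to_numpy()
    s2 = float(result.scale)
    beta = fe.to_numpy()
    eb_rows = {}
    for g in np.unique(groups):
        mask = groups == g
        Zg = exog[mask]
        resid = endog[mask] - Zg @ beta
        V = Zg @ G @ Zg.T + s2 * np.eye(mask.sum())
        b = G @ Zg.T @ np.linalg.solve(V, resid)
        eb_rows[g] = beta + b
    eb = pd.DataFrame.from_dict(eb_rows, orient="index", columns=exog_names)
    eb.index.name = group_col
    return MixedModelFit(
        spec=spec,
        fixed_effects=fe,
        cov_re=cov_re,
        resid_var=float(result.scale),
        eb=eb.sort_index(),
        converged=bool(result.converged),
        diagonal_fallback=diagonal,
        n_groups=int(sizes.size),
        n_rows=int(len(df)),
    )


def _acceptable(result) -> bool:
    if not np.all(np.isfinite(result.params)):
        return False
    eigvals = np.linalg.eigvalsh(np.asarray(result.cov_re))
    if eigvals.min() < -1e-8:
        return False
    return bool(result.converged)


def empirical_bayes_coefficients(fit: MixedModelFit) -> pd.DataFrame:
    """Per-person EB coefficient vectors (fixed + predicted random effect)."""
    if not fit.converged and not fit.diagonal_fallback:
        raise ConvergenceError("fit did not converge")
    return fit.eb.copy()


def within_share(between_var: float, within_var: float) -> float:
    """Within-person share of total variance, ``within / (between + within)``."""
    total = between_var + within_var
    if total <= 0:
        raise ValueError("total variance must be positive")
    return within_var / total


def variance_components(
    ratings: pd.DataFrame, value_col: str, group_col: str = "person_id"
) -> tuple[float, float]:
    """(between, within) variance from a random-intercept-only model."""
    df = ratings[[group_col, value_col]].dropna()
    if df[group_col].nunique() < 2:
        raise ValueError("need at least 2 persons")
    if np.ptp(df[value_col].to_numpy()) == 0:
        raise ValueError("zero total variance")
    exog = np.ones((len(df), 1))
    model = MixedLM(df[value_col].to_numpy(), exog, groups=df[group_col].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    between = float(np.asarray(result.cov_re)[0, 0])
    within = float(result.scale)
    return between, within


def icc(
    ratings: pd.DataFrame, value_col: str, group_col: str = "person_id"
) -> float:
    """Between-person variance as a share of total variance, in [0, 1]."""
    between, within = variance_components(ratings, value_col, group_col)
    return 1.0 - within_share(between, within)
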