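"""Two-part modelling of elderly medical expenditure.

Medical expenditure data are zero-inflated: many respondents record no
spending at all because seeking care is itself a choice.  Ignoring the
zeros biases any single-equation fit, so expenditure is modelled in two
parts: a probit for whether any expenditure occurs, and a linear
level-scale (yuan) equation for its amount conditional on occurrence.
The likelihood factorizes over the two parts, so probit MLE plus OLS on
the positive observations is the joint MLE; the joint log-likelihood is
still reported.

The unconditional mean at a covariate profile x is

    E[ME | x] = Phi(x . delta1) * max(x . delta2, 0),

with negative linear predictions floored at zero (expenditure is
non-negative and the level equation is unbounded below).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._errors import EstimationError, ValidationError
from .states import DEATH_STATE, TRANSIENT_STATES, age_group_label

#: Outcome flag -> panel column holding it.
OUTCOME_COLUMNS = {
    "individual_monthly": "individual_monthly_expenditure",
    "family_annual": "family_annual_expenditure",
}


@dataclass
class TwoPartFit:
    """A fitted two-part expenditure model.

    ``delta1``/``delta2`` map design-column names (``const`` first) to
    the probit participation and linear level coefficients; ``sigma``
    is the residual standard deviation of the level equation (yuan,
    maximum-likelihood scaling).
    """

    outcome: str
    design_columns: list[str]
    delta1: dict[str, float]
    delta1_bse: dict[str, float]
    delta2: dict[str, float]
    delta2_bse: dict[str, float]
    sigma: float
    n_used: int
    n_positive: int
    log_likelihood: float

    def wald_interval(self, part: int, column: str, level: float = 0.99):
        """Two-sided Wald CI for one coefficient of part 1 or part 2."""
        coefs, bses = (self.delta1, self.delta1_bse) if part == 1 else (self.delta2, self.delta2_bse)
        z = norm.ppf(0.5 + level / 2)
        return coefs[column] - z * bses[column], coefs[column] + z * bses[column]


def _design(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = np.ones((len(df), len(columns)))
    for c, name in enumerate(columns):
        if name == "const":
            continue
        if name not in df.columns:
            raise ValidationError(f"design column {name!r} not in data")
        X[:, c] = df[name].to_numpy(dtype=float)
    return X


def fit_two_part(
    panel: pd.DataFrame,
    outcome: str = "individual_monthly",
    covariates: list[str] | None = None,
) -> TwoPartFit:
    """Fit the two-part model of ``outcome`` on ``covariates``.

    Only living records (state 1..4) with a non-missing outcome enter;
    the outcome must contain both zero and positive values, otherwise
    the participation part is unidentified.  ``covariates`` may include
    ``state`` and ``age`` alongside the generated covariates.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValidationError(f"unknown outcome {outcome!r}")
    col = OUTCOME_COLUMNS[outcome]
    if col not in panel.columns:
        raise ValidationError(f"panel has no column {col!r}")
    data = panel[(panel["state"] != DEATH_STATE) & panel[col].notna()]
    y = data[col].to_numpy(dtype=float)
    if len(y) == 0:
        raise EstimationError("no usable observations")
    positive = y > 0
    if positive.all() or not positive.any():
        raise EstimationError(
            "outcome is all-positive or all-zero; two-part model unidentified"
        )

    columns = ["const"] + list(covariates or [])
    X = _design(data, columns)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            probit = sm.Probit(positive.astype(float), X).fit(
                method="newton", maxiter=200, disp=0
            )
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise EstimationError(f"participation part: {exc}") from exc
        ols = sm.OLS(y[positive], X[positive]).fit()

    n_pos = int(positive.sum())
    resid = y[positive] - X[positive] @ np.asarray(ols.params)
    sigma = float(np.sqrt((resid**2).sum() / n_pos))

    idx1 = X @ np.asarray(probit.params)
    loglik = float(
        np.sum(norm.logcdf(-idx1[~positive]))
        + np.sum(norm.logcdf(idx1[positive]))
        + np.sum(norm.logpdf(resid, scale=sigma))
    )

    as_map = lambda values: dict(zip(columns, np.asarray(values, dtype=float)))
    return TwoPartFit(
        outcome=outcome,
        design_columns=columns,
        delta1=as_map(probit.params),
        delta1_bse=as_map(probit.bse),
        delta2=as_map(ols.params),
        delta2_bse=as_map(ols.bse),
        sigma=sigma,
        n_used=len(y),
        n_positive=n_pos,
        log_likelihood=loglik,
    )


def expected_expenditure(fit: TwoPartFit, profile: dict[str, float] | pd.DataFrame) -> float | np.ndarray:
    """Unconditional mean expenditure Phi(x.delta1) * max(x.delta2, 0).

    ``profile`` is a covariate mapping (returns a scalar) or a frame of
    covariate rows (returns one value per row).
    """
    if isinstance(profile, dict):
        missing = {c for c in fit.design_columns if c != "const"} - set(profile)
        if missing:
            raise ValidationError(f"profile missing covariates: {sorted(missing)}")
        df = pd.DataFrame({k: [float(v)] for k, v in profile.items()}, index=[0])
        scalar = True
    else:
        df, scalar = profile, False
    X = _design(df, fit.design_columns)
    p = norm.cdf(X @ np.asarray([fit.delta1[c] for c in fit.design_columns]))
    level = np.maximum(X @ np.asarray([fit.delta2[c] for c in fit.design_columns]), 0.0)
    out = p * level
    return float(out[0]) if scalar else out


def per_state_expenditure(
    panel: pd.DataFrame,
    fit_family: TwoPartFit | None = None,
    fit_individual: TwoPartFit | None = None,
    by_age: bool = False,
) -> pd.DataFrame:
    """Per-capita expenditure table: sample-averaged fitted values by state.

    For each living state (optionally crossed with age group) the table
    entry is the mean of :func:`expected_expenditure` over the covariate
    rows of the panel members in that cell.  Empty cells are NaN (never
    silently zero).  Returns a frame with ``family_annual`` and/or
    ``individual_monthly`` columns, indexed by state or (age_group,
    state).
    """
    if fit_family is None and fit_individual is None:
        raise ValidationError("at least one fitted model is required")
    living = panel[panel["state"].isin(TRANSIENT_STATES)].copy()
    if by_age:
        living["age_group"] = living["age"].map(age_group_label)
        groups = living.groupby(["age_group", "state"])
    else:
        groups = living.groupby("state")

    records = {}
    for key, sub in groups:
        row = {}
        if fit_family is not None:
            row["family_annual"] = float(np.mean(expected_expenditure(fit_family, sub)))
        if fit_individual is not None:
            row["individual_monthly"] = float(np.mean(expected_expenditure(fit_individual, sub)))
        records[key] = row
    table = pd.DataFrame.from_dict(records, orient="index").sort_index()
    if by_age:
        table.index = pd.MultiIndex.from_tuples(table.index, names=["age_group", "state"])
    else:
        table.index.name = "state"
    return table


def annualize_monthly(value: float) -> float:
    """Convert a stable monthly per-capita expenditure to a yearly one (x12)."""
    if value < 0:
        raise ValidationError("expenditure cannot be negative")
    return value * 12.0


def expenditure_ratios(table: pd.DataFrame) -> dict[str, float]:
    """'Times higher' statistics: value(state 4) / value(state 1) - 1.

    Computed for each expenditure column of a per-state table and
    rounded to two decimals, the convention used when reporting how much
    more the very unhealthy spend than the healthy.
    """
    if by_age := isinstance(table.index, pd.MultiIndex):
        raise ValidationError("ratios are defined on the overall (per-state) table")
    out = {}
    for column in table.columns:
        v1, v4 = table.loc[1, column], table.loc[4, column]
        if v1 == 0 or np.isnan(v1) or np.isnan(v4):
            raise ValidationError(f"{column}: undefined ratio (state-1 value missing or zero)")
        out[column] = round(v4 / v1 - 1.0, 2)
    return out


def read_expenditure_table(path) -> pd.DataFrame:
    """Read a per-capita expenditure CSV (state[, age_group] indexed)."""
    df = pd.read_csv(path)
    index = ["age_group", "state"] if "age_group" in df.columns else ["state"]
    df = df.set_index(index)
    if (df < 0).any().any():
        raise ValidationError(f"{path}: negative per-capita expenditure")
    return df if len(index) == 2 else df.rename_axis("state")


def write_expenditure_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path)
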