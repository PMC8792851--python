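"""Estimation of health-state transition matrices from two-wave panels.

The destination state two years ahead is modelled as a function of the
origin state and covariates.  Two parameterizations are offered:

``multinomial``
    A multinomial logit over destinations 1..5 (destination 1 is the
    reference), with the origin entering as indicator variables.  Rows
    of the predicted matrix are stochastic by construction, which the
    Chapman-Kolmogorov projection downstream requires.  This is the
    canonical mode.

``binary_renormalized``
    One binary logit of "destination = j" per destination — the literal
    odds-of-each-state formulation — whose predicted probabilities need
    not sum to one across destinations and are therefore renormalized
    row-wise.  Provided for comparability; at realistic sample sizes the
    two modes agree closely.

With an intercept-and-origin-only design the multinomial MLE is the
saturated model, so its predicted matrix equals the empirical frequency
matrix exactly — that identity is the oracle used throughout the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._errors import EstimationError, ValidationError
from .matrix import ABSORBING_ROW, TransitionMatrix
from .states import (
    DEATH_STATE,
    DEFAULT_AGE_BOUNDARIES,
    N_STATES,
    PERIOD_YEARS,
    TRANSIENT_STATES,
    age_group_label,
)

_ORIGIN_COLUMNS = ["origin_2", "origin_3", "origin_4"]


def transition_pairs(panel: pd.DataFrame) -> pd.DataFrame:
    """Match wave-1 and wave-2 rows into one row per person.

    Returns a frame with ``person_id, age`` (wave-1 age), the wave-1
    covariates, ``origin`` (wave-1 state) and ``destination`` (wave-2
    state).  Persons missing either wave are dropped.
    """
    w1 = panel[panel["wave"] == 1]
    w2 = panel[panel["wave"] == 2][["person_id", "state"]]
    pairs = w1.merge(w2, on="person_id", suffixes=("", "_w2"), how="inner")
    pairs = pairs.rename(columns={"state": "origin", "state_w2": "destination"})
    if not pairs["origin"].isin(TRANSIENT_STATES).all():
        raise ValidationError("wave-1 states must all be transient (1..4)")
    return pairs


def _as_pairs(panel: pd.DataFrame) -> pd.DataFrame:
    if {"origin", "destination"}.issubset(panel.columns):
        return panel
    return transition_pairs(panel)


def empirical_transition_matrix(panel: pd.DataFrame, label: str = "overall") -> TransitionMatrix:
    """Raw transition frequencies: entry (i, j) = count(i -> j) / count(i).

    Every transient origin state must be observed at least once;
    otherwise the offending state is named in the error.
    """
    pairs = _as_pairs(panel)
    probs = np.zeros((N_STATES, N_STATES))
    for i in TRANSIENT_STATES:
        sub = pairs[pairs["origin"] == i]
        if len(sub) == 0:
            raise EstimationError(f"no observations with origin state {i}")
        counts = sub["destination"].value_counts()
        for j in range(1, N_STATES + 1):
            probs[i - 1, j - 1] = counts.get(j, 0) / len(sub)
    probs[DEATH_STATE - 1] = ABSORBING_ROW
    return TransitionMatrix(probs, label=label)


def _build_design(pairs: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(pairs))}, index=pairs.index)
    for i in (2, 3, 4):
        X[f"origin_{i}"] = (pairs["origin"] == i).astype(float)
    for name in covariates:
        if name not in pairs.columns:
            raise ValidationError(f"covariate {name!r} not in panel")
        col = pairs[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise EstimationError(f"covariate {name!r} is constant")
        X[name] = col
    return X


@dataclass
class TransitionModelFit:
    """A fitted destination-state model.

    ``params`` is a (n_columns x 4) array of coefficients for
    destinations 2..5 (destination 1 is the reference); under the
    binary_renormalized parameterization it stores one logit per
    destination 1..5 instead (n_columns x 5).  ``bse`` has the same
    layout.  The wave-1 covariate rows used in fitting are retained for
    sample-average prediction.
    """

    parameterization: str
    covariate_names: list[str]
    design_columns: list[str]
    params: np.ndarray
    bse: np.ndarray
    log_likelihood: float
    n_used: int
    _train_pairs: pd.DataFrame

    def wald_interval(self, column: str, destination: int, level: float = 0.99):
        """Two-sided Wald CI for one coefficient (multinomial mode)."""
        from scipy.stats import norm

        row = self.design_columns.index(column)
        col = destination - 2
        z = norm.ppf(0.5 + level / 2)
        est, se = self.params[row, col], self.bse[row, col]
        return est - z * se, est + z * se


def fit_transition_model(
    panel: pd.DataFrame,
    covariates: list[str] | None = None,
    parameterization: str = "multinomial",
) -> TransitionModelFit:
    """Maximum-likelihood fit of the destination-state model.

    ``covariates`` is a list of panel column names entering the linear
    predictor in addition to the origin-state indicators; pass an empty
    list (the default) for the intercept-and-origin-only model, whose
    multinomial predictions reproduce the empirical frequency matrix.
    """
    covariates = list(covariates or [])
    pairs = _as_pairs(panel)
    for i in TRANSIENT_STATES:
        if (pairs["origin"] == i).sum() == 0:
            raise EstimationError(f"no observations with origin state {i}")
    X = _build_design(pairs, covariates)
    dest = pairs["destination"].to_numpy(dtype=int)

    if parameterization == "multinomial":
        observed = np.unique(dest)
        if len(observed) < 2:
            raise EstimationError("only one destination state observed")
        # statsmodels codes categories 0..J-1 in sorted order of the labels
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MNLogit(dest, X)
            try:
                res = model.fit(method="newton", maxiter=200, disp=0)
            except PerfectSeparationError as exc:
                raise EstimationError(f"perfect separation: {exc}") from exc
            except np.linalg.LinAlgError as exc:
                raise EstimationError(f"singular design: {exc}") from exc
        if not np.all(np.isfinite(res.params.to_numpy() if hasattr(res.params, "to_numpy") else res.params)):
            raise EstimationError("non-finite coefficients; possible perfect separation")
        params = np.asarray(res.params)
        with warnings.catch_warnings():
            # sparse destination cells can give a near-singular Hessian;
            # the affected standard errors come back NaN, which is fine
            warnings.simplefilter("ignore")
            bse = np.asarray(res.bse)
        # pad columns if some destination states were unobserved
        if len(observed) < N_STATES:
            full_p = np.full((params.shape[0], N_STATES - 1), np.nan)
            full_se = np.full_like(full_p, np.nan)
            nonref = [s for s in observed if s != observed[0]]
            for k, s in enumerate(nonref):
                full_p[:, s - 2] = params[:, k]
                full_se[:, s - 2] = bse[:, k]
            params, bse = full_p, full_se
        fit = TransitionModelFit(
            parameterization, covariates, list(X.columns),
            params, bse, float(res.llf), len(pairs), pairs,
        )
        fit._observed_destinations = observed  # type: ignore[attr-defined]
        return fit

    if parameterization == "binary_renormalized":
        params = np.zeros((X.shape[1], N_STATES))
        bse = np.zeros_like(params)
        llf = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for j in range(1, N_STATES + 1):
                y = (dest == j).astype(float)
                if y.min() == y.max():
                    raise EstimationError(
                        f"destination {j} is never (or always) observed; "
                        "binary logit unidentified"
                    )
                try:
                    res = sm.Logit(y, X).fit(method="newton", maxiter=200, disp=0)
                except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                    raise EstimationError(f"destination {j}: {exc}") from exc
                params[:, j - 1] = np.asarray(res.params)
                bse[:, j - 1] = np.asarray(res.bse)
                llf += float(res.llf)
        return TransitionModelFit(
            parameterization, covariates, list(X.columns),
            params, bse, llf, len(pairs), pairs,
        )

    raise ValidationError(f"unknown parameterization {parameterization!r}")


def _predict_rows(fit: TransitionModelFit, X: np.ndarray) -> np.ndarray:
    """Destination probabilities (n x 5) for design rows ``X``."""
    if fit.parameterization == "multinomial":
        observed = getattr(fit, "_observed_destinations", np.arange(1, N_STATES + 1))
        cols = [s - 2 for s in observed if s != observed[0]]
        util = np.zeros((len(X), len(observed)))
        util[:, 1:] = X @ fit.params[:, cols]
        util -= util.max(axis=1, keepdims=True)
        expu = np.exp(util)
        probs_obs = expu / expu.sum(axis=1, keepdims=True)
        probs = np.zeros((len(X), N_STATES))
        for k, s in enumerate(observed):
            probs[:, s - 1] = probs_obs[:, k]
        return probs
    index = X @ fit.params
    raw = 1.0 / (1.0 + np.exp(-index))
    return raw / raw.sum(axis=1, keepdims=True)


def predict_transition_matrix(
    fit: TransitionModelFit,
    profile: dict[str, float] | str = "sample-average",
    label: str = "overall",
) -> TransitionMatrix:
    """Predicted transition matrix at a covariate profile.

    ``profile`` is either a mapping covering every fitted covariate, or
    the string ``"sample-average"``, in which case each row is the mean
    of the predicted destination distributions over the covariate rows
    of the fitting panel (a population-averaged matrix, matching the
    interpretation of a cohort-level table).
    """
    if isinstance(profile, str):
        if profile != "sample-average":
            raise ValidationError(f"unknown profile {profile!r}")
        base = fit._train_pairs
        cov = {name: base[name].to_numpy(dtype=float) for name in fit.covariate_names}
        n = len(base)
    else:
        unknown = set(profile) - set(fit.covariate_names)
        if unknown:
            raise ValidationError(f"unknown covariates in profile: {sorted(unknown)}")
        missing = set(fit.covariate_names) - set(profile)
        if missing:
            raise ValidationError(f"profile missing covariates: {sorted(missing)}")
        cov = {name: np.asarray([float(profile[name])]) for name in fit.covariate_names}
        n = 1

    probs = np.zeros((N_STATES, N_STATES))
    for i in TRANSIENT_STATES:
        X = np.ones((n, len(fit.design_columns)))
        for c, colname in enumerate(fit.design_columns):
            if colname == "const":
                continue
            if colname in _ORIGIN_COLUMNS:
                X[:, c] = 1.0 if colname == f"origin_{i}" else 0.0
            else:
                X[:, c] = cov[colname]
        probs[i - 1] = _predict_rows(fit, X).mean(axis=0)
    probs[DEATH_STATE - 1] = ABSORBING_ROW
    probs = probs / probs.sum(axis=1, keepdims=True)
    return TransitionMatrix(probs, label=label)


def stratified_matrices(
    panel: pd.DataFrame,
    age_boundaries: tuple[int, ...] = DEFAULT_AGE_BOUNDARIES,
    min_n: int = 30,
) -> tuple[dict[str, TransitionMatrix], list[str]]:
    """Empirical transition matrices by wave-1 age group.

    Returns ``(matrices, flagged)`` where ``flagged`` lists the labels
    of bins that were empty or held fewer than ``min_n`` matched pairs
    (flagged bins with at least one pair per origin are still
    estimated; empty ones are excluded).
    """
    bounds = tuple(age_boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValidationError("age boundaries must be strictly increasing")
    pairs = _as_pairs(panel)
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(bounds[:-1], bounds[1:])]
    labels.append(f"{bounds[-1]}+")
    groups = pairs["age"].map(lambda a: age_group_label(a, bounds))

    matrices: dict[str, TransitionMatrix] = {}
    flagged: list[str] = []
    for label in labels:
        sub = pairs[groups == label]
        if len(sub) < min_n:
            flagged.append(label)
        if len(sub) == 0:
            continue
        try:
            matrices[label] = empirical_transition_matrix(sub, label=label)
        except EstimationError:
            if label not in flagged:
                flagged.append(label)
    return matrices, flagged
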