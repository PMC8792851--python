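"""Synthetic two-wave panel generator with known ground truth.

The generator emulates the structure of a biennial ageing survey: a
baseline wave of respondents aged 60+ with demographic, socioeconomic,
health-behaviour and social covariates; a follow-up wave two years later
in which each person's five-level self-rated health state (1 = healthy
.. 4 = very unhealthy, 5 = death, absorbing) is drawn from a
multinomial-logit transition kernel; and zero-inflated medical
expenditures drawn from a two-part process (probit participation, then
a linear level-scale conditional expenditure, censored below at zero).

Because the truth — the transition coefficients, the participation and
expenditure coefficients, the residual scale — is known, every
downstream estimator can be tested by parameter recovery without access
to any survey microdata.

The panel is represented as a :class:`pandas.DataFrame` with one row
per person-wave (columns ``person_id, wave, age, state, <covariates>,
sought_care, family_annual_expenditure, individual_monthly_expenditure``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import SchemaError, ValidationError
from .matrix import ABSORBING_ROW, TransitionMatrix
from .states import DEATH_STATE, N_STATES, PERIOD_YEARS, TRANSIENT_STATES

PANEL_ID_COLUMNS = ["person_id", "wave", "age", "state"]
PANEL_OUTCOME_COLUMNS = [
    "sought_care",
    "family_annual_expenditure",
    "individual_monthly_expenditure",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Distributional description of one baseline covariate.

    kind is one of ``binary`` (Bernoulli, param ``p``), ``categorical``
    (params ``levels`` and ``probs``) or ``continuous`` (Normal, params
    ``mean`` and ``sd``).
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    reference_level: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "binary":
            p = self.params.get("p")
            if p is None or not 0 <= p <= 1:
                raise ValidationError(f"covariate {self.name}: binary p must be in [0, 1]")
        elif self.kind == "categorical":
            probs = np.asarray(self.params.get("probs", ()), dtype=float)
            if probs.size == 0 or abs(probs.sum() - 1.0) > 1e-8 or (probs < 0).any():
                raise ValidationError(
                    f"covariate {self.name}: categorical probs must be a distribution"
                )
            if len(self.params.get("levels", ())) != probs.size:
                raise ValidationError(f"covariate {self.name}: levels/probs length mismatch")
        elif self.kind == "continuous":
            if self.params.get("sd", 0.0) <= 0:
                raise ValidationError(f"covariate {self.name}: continuous sd must be > 0")
        else:
            raise ValidationError(f"covariate {self.name}: unknown kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "binary":
            return rng.binomial(1, self.params["p"], size=n).astype(float)
        if self.kind == "categorical":
            return rng.choice(
                np.asarray(self.params["levels"], dtype=float),
                size=n, p=self.params["probs"],
            )
        return rng.normal(self.params["mean"], self.params["sd"], size=n)


def default_covariate_specs() -> list[CovariateSpec]:
    """A covariate battery covering the usual determinants of elderly health.

    Demographic (gender, agricultural household registration), socio-
    economic (education, family income, pension, medical insurance),
    health-behaviour (chronic disease, drinking, smoking, BMI) and
    social-relation (marriage, social activities) variables.  The
    distributions are plausible config defaults for an elderly Chinese
    cohort, not survey estimates.
    """
    b = lambda name, p: CovariateSpec(name, "binary", {"p": p})
    return [
        b("female", 0.5),
        b("agricultural_hukou", 0.7),
        b("middle_school_or_above", 0.3),
        CovariateSpec("log_family_income", "continuous", {"mean": 9.5, "sd": 1.0}),
        b("pension", 0.4),
        b("medical_insurance", 0.9),
        b("married", 0.75),
        b("social_activities", 0.5),
        b("chronic_disease", 0.6),
        b("drinking", 0.3),
        b("smoking", 0.3),
        CovariateSpec("bmi", "continuous", {"mean": 23.0, "sd": 3.0}),
    ]


@dataclass(frozen=True)
class TransitionTruth:
    """Multinomial-logit transition kernel parameters.

    For origin state ``i`` in 1..4 and covariate vector ``x``, the
    destination utilities are ``u_1 = 0`` (reference) and, for j in
    2..5, ``u_j = alpha[j] + beta[i, j] + gamma[j] . x``; destination
    probabilities are the softmax of the utilities.  ``beta`` is
    reference-coded in the origin: its row for origin 1 is zero.
    """

    covariate_names: tuple[str, ...]
    alpha: np.ndarray        # (4,) intercepts for destinations 2..5
    beta: np.ndarray         # (4, 4) origin 1..4 x destination 2..5
    gamma: np.ndarray        # (4, k) destination 2..5 x covariate

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float).reshape(4, -1)
        k = len(self.covariate_names)
        if alpha.shape != (4,) or beta.shape != (4, 4) or gamma.shape != (4, k):
            raise ValidationError("transition truth coefficient shapes do not conform")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)

    @classmethod
    def from_kernel(cls, kernel, covariate_names: Sequence[str] = ()) -> "TransitionTruth":
        """Build a covariate-free truth whose kernel equals ``kernel`` exactly.

        Requires every transient row of the kernel to have a strictly
        positive destination-1 probability (the logit reference).
        """
        probs = kernel.probs if isinstance(kernel, TransitionMatrix) else np.asarray(kernel, float)
        trans = probs[:4]
        if np.any(trans[:, 0] <= 0):
            raise ValidationError("kernel rows need P(i -> 1) > 0 for reference coding")
        logits = np.log(trans[:, 1:] / trans[:, :1])  # (4 origins, dest 2..5)
        alpha = logits[0]
        beta = logits - alpha
        gamma = np.zeros((4, len(covariate_names)))
        return cls(tuple(covariate_names), alpha, beta, gamma)

    def kernel(self, origin: int, x: np.ndarray | None = None) -> np.ndarray:
        """Destination distribution (5-vector) from ``origin`` at covariates ``x``."""
        rows = self.kernel_rows(
            np.asarray([origin]),
            np.zeros((1, len(self.covariate_names))) if x is None else np.atleast_2d(x),
        )
        return rows[0]

    def kernel_rows(self, origins: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Vectorized destination distributions, one row per observation."""
        n = len(origins)
        util = np.zeros((n, N_STATES))
        util[:, 1:] = self.alpha + self.beta[origins - 1] + X @ self.gamma.T
        util -= util.max(axis=1, keepdims=True)
        expu = np.exp(util)
        return expu / expu.sum(axis=1, keepdims=True)

    def implied_matrix(self, X: np.ndarray | None = None) -> TransitionMatrix:
        """The kernel averaged over covariate rows ``X`` (zeros if omitted)."""
        if X is None:
            X = np.zeros((1, len(self.covariate_names)))
        probs = np.empty((N_STATES, N_STATES))
        for i in TRANSIENT_STATES:
            rows = self.kernel_rows(np.full(len(X), i), X)
            probs[i - 1] = rows.mean(axis=0)
        probs[DEATH_STATE - 1] = ABSORBING_ROW
        return TransitionMatrix(probs / probs.sum(axis=1, keepdims=True))


@dataclass(frozen=True)
class TwoPartTruth:
    """Two-part expenditure process parameters.

    ``delta1`` and ``delta2`` map design-column names (``const``,
    covariates, optionally ``state`` and ``age``) to coefficients of
    the probit participation index and the linear expenditure level;
    ``sigma`` is the residual standard deviation of the level equation
    in yuan.
    """

    delta1: dict[str, float]
    delta2: dict[str, float]
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("residual sd must be >= 0")

    def _index(self, df: pd.DataFrame, coeffs: dict[str, float]) -> np.ndarray:
        out = np.zeros(len(df))
        for name, value in coeffs.items():
            if name == "const":
                out += value
            else:
                if name not in df.columns:
                    raise ValidationError(f"coefficient references missing column {name!r}")
                out += value * df[name].to_numpy(dtype=float)
        return out

    def participation_index(self, df: pd.DataFrame) -> np.ndarray:
        return self._index(df, self.delta1)

    def level_index(self, df: pd.DataFrame) -> np.ndarray:
        return self._index(df, self.delta2)


@dataclass(frozen=True)
class GeneratorTruth:
    """Complete ground truth of a synthetic two-wave panel."""

    transition: TransitionTruth
    individual_monthly: TwoPartTruth
    family_annual: TwoPartTruth | None = None
    seed: int = 0


def generate_baseline(
    specs: Sequence[CovariateSpec],
    n: int,
    age_range: tuple[int, int] = (60, 90),
    state_distribution: Sequence[float] = (0.1215, 0.2982, 0.3849, 0.1954),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a baseline (wave-1) panel of ``n`` living respondents.

    ``state_distribution`` is the marginal distribution over the four
    transient states; ages are uniform integers over ``age_range``.
    Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not specs:
        raise ValidationError("at least one covariate spec is required")
    dist = np.asarray(state_distribution, dtype=float)
    if dist.shape != (4,) or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-8:
        raise ValidationError("state_distribution must be a probability 4-vector")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate covariate names")

    rng = np.random.default_rng(seed)
    width = len(str(n))
    df = pd.DataFrame(
        {
            "person_id": [f"p{i:0{width}d}" for i in range(1, n + 1)],
            "wave": 1,
            "age": rng.integers(age_range[0], age_range[1] + 1, size=n),
            "state": rng.choice(np.arange(1, 5), size=n, p=dist),
        }
    )
    for spec in specs:
        df[spec.name] = spec.sample(rng, n)
    for col in PANEL_OUTCOME_COLUMNS:
        df[col] = np.nan
    return df


def simulate_wave2(records: pd.DataFrame, truth: GeneratorTruth) -> pd.DataFrame:
    """Draw each person's wave-2 state from the truth's transition kernel.

    Ages advance by the two-year period; death (state 5) is absorbing by
    construction of the kernel, and wave-1 records must all be living.
    """
    if (records["wave"] != 1).any():
        raise ValidationError("all input records must be wave 1")
    if records["person_id"].duplicated().any():
        dup = records.loc[records["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValidationError(f"duplicate person_id {dup!r} in wave-1 input")
    if not records["state"].isin(TRANSIENT_STATES).all():
        raise ValidationError("wave-1 states must be transient (1..4)")

    tr = truth.transition
    X = records[list(tr.covariate_names)].to_numpy(dtype=float)
    origins = records["state"].to_numpy(dtype=int)
    probs = tr.kernel_rows(origins, X)

    rng = np.random.default_rng(truth.seed)
    u = rng.random(len(records))
    cum = np.cumsum(probs, axis=1)
    new_state = 1 + (u[:, None] > cum).sum(axis=1)

    out = records.copy()
    out["wave"] = 2
    out["age"] = records["age"] + PERIOD_YEARS
    out["state"] = new_state.astype(int)
    for col in PANEL_OUTCOME_COLUMNS:
        out[col] = np.nan
    return out


def simulate_expenditure(records: pd.DataFrame, truth: GeneratorTruth) -> pd.DataFrame:
    """Draw care-seeking and medical expenditures for each record.

    Participation is ``1{x . delta1 + N(0,1) >= 0}``; conditional on
    participation the expenditure is ``x . delta2 + N(0, sigma)``
    censored below at zero, else exactly zero.  A participant whose
    individual conditional draw censors to exactly zero is coded as a
    non-participant, so ``sought_care = 0`` if and only if expenditure
    is zero; under sensible truths (level index several sigma above
    zero) this affects a negligible share of records.  Dead records
    (state 5) get zero participation and expenditure.  The coefficient
    maps may reference the ``state`` and ``age`` columns as well as the
    covariates.
    """
    out = records.copy()
    alive = (out["state"] != DEATH_STATE).to_numpy()
    rng = np.random.default_rng(truth.seed + 1)

    idx1 = truth.individual_monthly.participation_index(out)
    participates = (idx1 + rng.standard_normal(len(out)) >= 0) & alive

    def draw_level(part: TwoPartTruth) -> np.ndarray:
        level = part.level_index(out) + rng.standard_normal(len(out)) * part.sigma
        return np.maximum(level, 0.0)

    ind_level = draw_level(truth.individual_monthly)
    family = truth.family_annual or truth.individual_monthly
    fam_level = draw_level(family)

    sought = participates & (ind_level > 0)
    out["sought_care"] = sought.astype(float)
    out["individual_monthly_expenditure"] = np.where(sought, ind_level, 0.0)
    out["family_annual_expenditure"] = np.where(sought, fam_level, 0.0)
    return out


def simulate_panel(
    truth: GeneratorTruth,
    n: int,
    specs: Sequence[CovariateSpec] | None = None,
    age_range: tuple[int, int] = (60, 90),
    state_distribution: Sequence[float] = (0.1215, 0.2982, 0.3849, 0.1954),
) -> pd.DataFrame:
    """Generate a complete two-wave panel (baseline + follow-up) as one frame."""
    specs = default_covariate_specs() if specs is None else list(specs)
    wave1 = generate_baseline(
        specs, n, age_range=age_range,
        state_distribution=state_distribution, seed=truth.seed,
    )
    wave1 = simulate_expenditure(wave1, truth)
    wave2 = simulate_wave2(wave1, truth)
    wave2 = simulate_expenditure(wave2, truth)
    return pd.concat([wave1, wave2], ignore_index=True)


def write_panel(records: pd.DataFrame, path: str | Path) -> None:
    """Write a panel frame to CSV (UTF-8, header, empty field = missing)."""
    records.to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a panel CSV written by :func:`write_panel`.

    Schema violations (unknown state codes, negative expenditures,
    missing mandatory columns) raise :class:`SchemaError` naming the
    offending row and column.
    """
    df = pd.read_csv(path)
    for col in PANEL_ID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    bad_state = ~df["state"].isin(STATE_CODES)
    if bad_state.any():
        row = int(np.argmax(bad_state.to_numpy()))
        raise SchemaError(
            f"{path}: row {row}: invalid state code {df['state'].iloc[row]!r}"
        )
    for col in ("family_annual_expenditure", "individual_monthly_expenditure"):
        if col in df.columns:
            neg = df[col] < 0
            if neg.any():
                row = int(np.argmax(neg.to_numpy()))
                raise SchemaError(f"{path}: row {row}: negative value in {col!r}")
    return df


STATE_CODES = list(range(1, N_STATES + 1))
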