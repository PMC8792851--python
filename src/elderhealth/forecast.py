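"""Chapman-Kolmogorov projection of the elderly population by health state.

Starting from a base-year population split by age group and health
state, each two-year step advances every age group's living states
through its (or the overall) transition matrix, accumulates deaths in
the absorbing state, moves a fraction of each five-year age bin into
the next bin (2/5 per two-year step under the uniform-within-bin
assumption), and adds exogenous new entrants to the 60-64 group.
Annual values between the biennial grid points are obtained by linear
interpolation; a matrix-square-root annualization (principal square
root of the kernel, clipped to non-negative entries and renormalized)
is available behind a flag for users who prefer a genuine one-year
kernel.

Everything is bookkept in persons; the state-5 column of a projection
holds the cumulative deaths of the projected population, so that
living + cumulative deaths - cumulative entrants is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from ._errors import SchemaError, ValidationError
from .matrix import ABSORBING_ROW, TransitionMatrix, read_matrix
from .states import AGE_GROUP_LABELS, DEATH_STATE, N_STATES

#: Default initial state distribution of new entrants: the observed 2011
#: baseline shares over the transient states, renormalized.
DEFAULT_ENTRANT_DISTRIBUTION = np.array([0.1215, 0.2982, 0.3849, 0.1954])

#: Width of the five-year age bins, used for the aging fraction.
BIN_WIDTH_YEARS = 5


def n_step_matrix(P: TransitionMatrix, n: int) -> TransitionMatrix:
    """The n-step transition matrix P^n (n = 0 gives the identity)."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    probs = np.linalg.matrix_power(P.probs, n)
    probs[DEATH_STATE - 1] = ABSORBING_ROW
    return TransitionMatrix(
        probs / probs.sum(axis=1, keepdims=True),
        label=P.label,
        period_years=P.period_years * n,
    )


def propagate(dist: np.ndarray, P: TransitionMatrix) -> np.ndarray:
    """One-step marginal update dist . P (mass, living + dead, conserved)."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_STATES,):
        raise ValidationError(f"distribution must be a {N_STATES}-vector")
    if (dist < 0).any():
        raise ValidationError("distribution entries must be non-negative")
    return dist @ P.probs


def annualized_matrix(P: TransitionMatrix) -> TransitionMatrix:
    """Principal square root of a two-year kernel as a one-year kernel.

    Negative entries of the square root (possible for empirical
    matrices) are clipped to zero and rows renormalized, so the result
    is a valid stochastic matrix whose square approximates ``P``.
    """
    root = scipy.linalg.sqrtm(P.probs)
    root = np.real_if_close(root, tol=1e6).astype(float)
    root = np.clip(root, 0.0, None)
    root[DEATH_STATE - 1] = ABSORBING_ROW
    root = root / root.sum(axis=1, keepdims=True)
    return TransitionMatrix(root, label=P.label, period_years=max(P.period_years // 2, 1))


@dataclass(frozen=True)
class EntrantsSchedule:
    """Exogenous counts of people turning 60 per calendar year.

    ``counts`` maps year -> persons entering the 60-64 group; entrants
    arrive with ``initial_state_distribution`` over the transient
    states.
    """

    counts: dict[int, float]
    initial_state_distribution: np.ndarray = field(
        default_factory=lambda: DEFAULT_ENTRANT_DISTRIBUTION.copy()
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValidationError("entrant counts must be non-negative")
        dist = np.asarray(self.initial_state_distribution, dtype=float)
        if dist.shape != (4,) or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-8:
            raise ValidationError("entrant state distribution must be a 4-vector summing to 1")
        object.__setattr__(self, "initial_state_distribution", dist)

    def between(self, start_exclusive: int, end_inclusive: int) -> float:
        """Total entrants over the calendar years in (start, end]."""
        total = 0.0
        for year in range(start_exclusive + 1, end_inclusive + 1):
            if year not in self.counts:
                raise ValidationError(f"entrants schedule has a gap at year {year}")
            total += self.counts[year]
        return total


@dataclass
class ProjectionSeries:
    """Annual per-state population counts, per age group and pooled.

    ``data`` is long format: columns ``year, age_group, state, count``
    with state 5 holding cumulative deaths.  ``provenance`` records the
    matrices and entrants schedule used.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def pooled(self) -> pd.DataFrame:
        """Counts summed over age groups: index year, columns state 1..5."""
        return self.data.pivot_table(
            index="year", columns="state", values="count", aggfunc="sum"
        )

    def at(self, year: int, state: int, age_group: str | None = None) -> float:
        if age_group is None:
            return float(self.pooled().loc[year, state])
        sel = (
            (self.data["year"] == year)
            & (self.data["state"] == state)
            & (self.data["age_group"] == age_group)
        )
        if not sel.any():
            raise ValidationError(f"no entry for {year}/{age_group}/state {state}")
        return float(self.data.loc[sel, "count"].iloc[0])


def project_cohorts(
    base: pd.DataFrame,
    matrices: TransitionMatrix | dict[str, TransitionMatrix],
    entrants: EntrantsSchedule | None = None,
    base_year: int = 2015,
    horizon: int = 2035,
    aging: bool = True,
    annualization: str = "interpolate",
) -> ProjectionSeries:
    """Project the population forward from ``base_year`` to ``horizon``.

    Parameters
    ----------
    base : DataFrame with columns ``age_group, state, population``
        Base-year living population (states 1-4) per age group.
    matrices : a single overall matrix, or a dict keyed by age-group label
        Two-year transition kernels.
    entrants : EntrantsSchedule or None
        Yearly counts joining the 60-64 group; ``None`` means closed
        population.
    aging : bool
        Move 2/5 of each bin's post-transition living population to the
        next bin per two-year step (the uniform-within-bin demographic
        approximation).  The last bin (80+) retains its members.
    annualization : ``"interpolate"`` (default) or ``"matrix_root"``
        How annual values are produced: linear interpolation between
        biennial grid points, or genuine one-year steps through the
        principal square root of each kernel.
    """
    if horizon <= base_year:
        raise ValidationError("horizon must be after the base year")
    if annualization not in ("interpolate", "matrix_root"):
        raise ValidationError(f"unknown annualization {annualization!r}")

    labels = [g for g in AGE_GROUP_LABELS if g in set(base["age_group"])]
    if not labels:
        raise ValidationError("base population has no recognized age groups")

    if isinstance(matrices, TransitionMatrix):
        kernel = {g: matrices for g in labels}
    else:
        missing = [g for g in labels if g not in matrices]
        if missing:
            raise ValidationError(f"missing transition matrix for age groups {missing}")
        kernel = {g: matrices[g] for g in labels}

    step = 1 if annualization == "matrix_root" else 2
    if annualization == "matrix_root":
        kernel = {g: annualized_matrix(P) for g, P in kernel.items()}
    aging_fraction = step / BIN_WIDTH_YEARS if aging else 0.0

    counts = {g: np.zeros(N_STATES) for g in labels}
    for _, row in base.iterrows():
        state = int(row["state"])
        if state == DEATH_STATE:
            continue
        if row["population"] < 0:
            raise ValidationError("base population counts must be non-negative")
        counts[row["age_group"]][state - 1] = float(row["population"])

    snapshots: list[tuple[int, dict[str, np.ndarray]]] = [
        (base_year, {g: c.copy() for g, c in counts.items()})
    ]
    year = base_year
    while year < horizon:
        nxt = min(year + step, horizon) if step == 1 else year + step
        # transition every age group through its kernel
        for g in labels:
            vec = counts[g].copy()
            vec[DEATH_STATE - 1] = 0.0           # deaths tracked separately
            moved = propagate(vec, kernel[g])
            counts[g][:4] = moved[:4]
            counts[g][DEATH_STATE - 1] += moved[DEATH_STATE - 1]
        # age a fraction of each bin's living into the next bin
        if aging_fraction > 0:
            flows = {g: counts[g][:4] * aging_fraction for g in labels[:-1]}
            for g, nxt_g in zip(labels[:-1], labels[1:]):
                counts[g][:4] -= flows[g]
                counts[nxt_g][:4] += flows[g]
        # exogenous new entrants into the youngest bin
        if entrants is not None:
            total = entrants.between(year, nxt)
            counts[labels[0]][:4] += total * entrants.initial_state_distribution
        year = nxt
        snapshots.append((year, {g: c.copy() for g, c in counts.items()}))

    grid_years = np.array([y for y, _ in snapshots])
    rows = []
    for g in labels:
        series = np.stack([snap[g] for _, snap in snapshots])  # (T, 5)
        for target_year in range(base_year, horizon + 1):
            values = [
                np.interp(target_year, grid_years, series[:, s])
                for s in range(N_STATES)
            ]
            for s in range(N_STATES):
                rows.append(
                    {"year": target_year, "age_group": g, "state": s + 1, "count": values[s]}
                )
    data = pd.DataFrame(rows)
    provenance = {
        "matrices": {g: kernel[g].label for g in labels},
        "annualization": annualization,
        "aging": aging,
        "base_year": base_year,
        "horizon": horizon,
        "entrants": "none" if entrants is None else "schedule",
    }
    return ProjectionSeries(data, provenance)


def read_matrices(directory: str | Path) -> dict[str, TransitionMatrix]:
    """Load every matrix CSV in a directory, keyed by its label."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*.csv")):
        matrix = read_matrix(path)
        out[matrix.label] = matrix
    if not out:
        raise SchemaError(f"no matrix CSVs found in {directory}")
    return out


def read_entrants(path: str | Path) -> EntrantsSchedule:
    """Read an entrants CSV: ``year, entrant_count[, share_1..share_4]``."""
    df = pd.read_csv(path)
    for col in ("year", "entrant_count"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    share_cols = [f"share_{s}" for s in range(1, 5)]
    if all(c in df.columns for c in share_cols):
        shares = df[share_cols].iloc[0].to_numpy(dtype=float)
    else:
        shares = DEFAULT_ENTRANT_DISTRIBUTION.copy()
    counts = dict(zip(df["year"].astype(int), df["entrant_count"].astype(float)))
    return EntrantsSchedule(counts, shares)


def write_series(series: ProjectionSeries, path: str | Path) -> None:
    """Write a projection as long-format CSV (year, age_group, state, count)."""
    series.data.to_csv(path, index=False)


def read_series(path: str | Path) -> ProjectionSeries:
    df = pd.read_csv(path)
    expected = {"year", "age_group", "state", "count"}
    if not expected.issubset(df.columns):
        raise SchemaError(f"{path}: series CSV needs columns {sorted(expected)}")
    if (df["count"] < 0).any():
        raise SchemaError(f"{path}: negative population count")
    return ProjectionSeries(df)
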