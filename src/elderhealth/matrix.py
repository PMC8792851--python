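"""Row-stochastic health-state transition matrices.

A :class:`TransitionMatrix` holds the 5x5 kernel of one estimation period
(two years by default): entry ``(i, j)`` is the probability that a person
in state ``i`` at the start of the period is in state ``j`` at its end.
Row 5 (death) is absorbing and must be exactly ``(0, 0, 0, 0, 1)``.

Printed source tables carry four decimal places, so rows read from disk
may sum to 1 +/- a few 1e-4; the loader accepts a bounded row-sum error
and rescales transient rows to sum exactly to one, because repeated
Chapman-Kolmogorov powers amplify any residual drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import SchemaError, ValidationError
from .states import DEATH_STATE, N_STATES, PERIOD_YEARS

#: Tolerance for row sums of matrices built in memory.
ROW_SUM_ATOL = 1e-9

#: Tolerance for row sums of matrices read from 4-decimal printed tables.
LOAD_ROW_SUM_ATOL = 5e-4

ABSORBING_ROW = np.array([0.0, 0.0, 0.0, 0.0, 1.0])


@dataclass(frozen=True)
class TransitionMatrix:
    """A validated 5x5 row-stochastic transition kernel.

    Parameters
    ----------
    probs : ndarray, shape (5, 5)
        Transition probabilities; rows index the origin state, columns
        the destination state (states 1..5 in order).
    label : str
        ``"overall"`` or an age-group label such as ``"60-64"``.
    period_years : int
        Length of one transition step, in years.
    """

    probs: np.ndarray
    label: str = "overall"
    period_years: int = PERIOD_YEARS

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (N_STATES, N_STATES):
            raise ValidationError(
                f"transition matrix must be {N_STATES}x{N_STATES}, got {probs.shape}"
            )
        if not np.all(np.isfinite(probs)):
            raise ValidationError("transition matrix contains non-finite entries")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        row_sums = probs.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=ROW_SUM_ATOL, rtol=0):
            bad = int(np.argmax(np.abs(row_sums - 1.0))) + 1
            raise ValidationError(
                f"row {bad} sums to {row_sums[bad - 1]:.10f}, not 1"
            )
        if not np.array_equal(probs[DEATH_STATE - 1], ABSORBING_ROW):
            raise ValidationError("death row must be exactly (0, 0, 0, 0, 1)")
        object.__setattr__(self, "probs", probs)

    def __matmul__(self, other: "TransitionMatrix") -> "TransitionMatrix":
        out = self.probs @ other.probs
        out[DEATH_STATE - 1] = ABSORBING_ROW
        return TransitionMatrix(
            out, label=self.label,
            period_years=self.period_years + other.period_years,
        )

    def entry(self, origin: int, destination: int) -> float:
        """Probability of the ``origin -> destination`` transition (1-based)."""
        return float(self.probs[origin - 1, destination - 1])

    def round(self, decimals: int = 4) -> np.ndarray:
        """Entries rounded for report output; internal precision is full."""
        return np.round(self.probs, decimals)


def _renormalize(probs: np.ndarray) -> np.ndarray:
    """Rescale transient rows to sum exactly to 1; force the absorbing row."""
    out = np.asarray(probs, dtype=float).copy()
    sums = out.sum(axis=1, keepdims=True)
    out = out / sums
    out[DEATH_STATE - 1] = ABSORBING_ROW
    return out


def read_matrix(path: str | Path, row_sum_atol: float = LOAD_ROW_SUM_ATOL) -> TransitionMatrix:
    """Read a transition matrix from a metadata-commented CSV file.

    The file starts with ``# label:`` and ``# period_years:`` comment
    lines, then a header row and one row per origin state.  Rows whose
    sum deviates from 1 by more than ``row_sum_atol`` are rejected
    (printed tables are 4-decimal, so legitimate drift is at most a few
    1e-4; a larger tolerance can be passed explicitly for source tables
    with known typos); accepted rows are rescaled to sum exactly to 1.
    """
    path = Path(path)
    label = "overall"
    period_years = PERIOD_YEARS
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                key = key.strip()
                if key == "label":
                    label = value.strip()
                elif key == "period_years":
                    period_years = int(value)
                continue
            cells = line.split(",")
            if cells[0] == "state":  # header
                continue
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric entry") from exc
    if len(rows) != N_STATES:
        raise SchemaError(f"{path}: expected {N_STATES} state rows, got {len(rows)}")
    probs = np.asarray(rows, dtype=float)
    row_sums = probs.sum(axis=1)
    bad = np.abs(row_sums - 1.0) > row_sum_atol
    if bad.any():
        state = int(np.argmax(bad)) + 1
        raise SchemaError(
            f"{path}: row for state {state} sums to {row_sums[state - 1]:.4f}, "
            f"outside 1 +/- {row_sum_atol}"
        )
    return TransitionMatrix(_renormalize(probs), label=label, period_years=period_years)


def write_matrix(matrix: TransitionMatrix, path: str | Path, decimals: int | None = None) -> None:
    """Write a matrix as a metadata-commented CSV (full precision by default)."""
    path = Path(path)
    probs = matrix.probs if decimals is None else matrix.round(decimals)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# label: {matrix.label}\n")
        fh.write(f"# period_years: {matrix.period_years}\n")
        fh.write("state," + ",".join(str(s) for s in range(1, N_STATES + 1)) + "\n")
        for i in range(N_STATES):
            cells = ",".join(repr(float(v)) for v in probs[i])
            fh.write(f"{i + 1},{cells}\n")
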