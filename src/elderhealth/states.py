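"""Health-state coding and age-group conventions.

Self-rated health is coded into five states: 1 = healthy, 2 = basically
healthy, 3 = unhealthy, 4 = very unhealthy, 5 = death.  States 1-4 are
transient; state 5 is absorbing.  Transition matrices describe one
two-year survey interval, and the elderly population is grouped into
five-year age bins from age 60 upward.
"""

from __future__ import annotations

N_STATES = 5
STATES = (1, 2, 3, 4, 5)
TRANSIENT_STATES = (1, 2, 3, 4)
DEATH_STATE = 5

STATE_LABELS = {
    1: "healthy",
    2: "basically healthy",
    3: "unhealthy",
    4: "very unhealthy",
    5: "death",
}

#: Default period between panel waves (and hence one matrix step), in years.
PERIOD_YEARS = 2

#: Default age-bin lower boundaries; the last bin is open-ended (80+).
DEFAULT_AGE_BOUNDARIES = (60, 65, 70, 75, 80)

AGE_GROUP_LABELS = ("60-64", "65-69", "70-74", "75-79", "80+")


def age_group_label(age: float, boundaries=DEFAULT_AGE_BOUNDARIES) -> str:
    """Return the age-group label for ``age`` given bin lower boundaries.

    Ages below the first boundary raise ``ValueError``; the last bin is
    open-ended ("80+" under the default boundaries).
    """
    if age < boundaries[0]:
        raise ValueError(f"age {age} below the first boundary {boundaries[0]}")
    for low, high in zip(boundaries[:-1], boundaries[1:]):
        if low <= age < high:
            return f"{low}-{high - 1}"
    return f"{boundaries[-1]}+"
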