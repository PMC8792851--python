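"""Bundled reference tables.

The package ships the published estimates it builds on as small CSV
fixtures: the observed 2011/2013 self-rated-health shares, the overall
and age-specific two-year transition matrices, the per-state per-capita
medical expenditure tables (overall and by age group), the projected
2015/2025/2035 population by age group and state, and the projected
2035 national population by state.  Each fixture is checksummed so that
silent edits are caught at load time.

All monetary values are nominal yuan; population fixtures are stored in
persons (the by-age table is published in units of 10,000 persons and
converted on load).
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .matrix import TransitionMatrix, read_matrix
from .states import AGE_GROUP_LABELS

_DATA_PACKAGE = "elderhealth.data"

#: SHA-256 checksums of the bundled fixture files.
CHECKSUMS = {
    "observed_state_shares.csv": "c40315472fc8a50999cf7522761d9c711699bfe1cc86a2174b6c1b706d7b0044",
    "overall_matrix.csv": "49d26272cb78234cce4d75b342c32d5c57c16fb094aae6ad4824e8cb632e41dd",
    "age_matrix_60-64.csv": "58663b1891962dbb38feac63f14bf12be82f52f1ee16caac46212a723b271300",
    "age_matrix_65-69.csv": "9c4e9c6a3f29c1e0bc39d18760436fa146339245ce82399d55e2391b42febf03",
    "age_matrix_70-74.csv": "99ada6a6e4818eb792dec1d136ef12c3a80313afcc39637fbca8768b30b16a8a",
    "age_matrix_75-79.csv": "33e96b1cfb48c13749836463de3ca3e193d1cc952204fec56c77ea72997534c2",
    "age_matrix_80plus.csv": "3de4c969ae486365dce649edc8c4f1bd600562b1b9d5321fabeb6e88fe110480",
    "percapita_expenditure.csv": "7624236b1f18b8a702920fb9daf46f92911e98ca093d3c7df67f2138c44c0870",
    "percapita_expenditure_by_age.csv": "87654d9712254c73bb555b507132c983f3a7ec1772b5fdc63b2491bc54d6aa25",
    "projected_population_by_age.csv": "8e587bda8ababe95078b734bc6b4e054a347d69926e6bd3357a1aa6a2bf0a769",
    "projected_2035_population.csv": "3574909b777b7a0e067dc38b5a2aeea9fad5b41dd40b79f7dea7a1151141810a",
}

#: Published 2015 pooled annual medical-expenditure totals, billions of yuan.
TOTALS_2015_BILLIONS = {1: 5.542, 4: 26.112}

#: Published per-age-group state-4 (very unhealthy) totals, billions of yuan.
STATE4_BY_AGE_BILLIONS = {
    2015: {"60-64": 9.853, "65-69": 6.262, "70-74": 4.713, "75-79": 3.695, "80+": 2.738},
    2035: {"60-64": 14.07, "65-69": 12.373, "70-74": 11.20, "75-79": 7.387, "80+": 6.288},
}


def _fixture_path(name: str):
    if name not in CHECKSUMS:
        raise ValidationError(f"unknown fixture {name!r}")
    ref = resources.files(_DATA_PACKAGE) / name
    digest = hashlib.sha256(ref.read_bytes()).hexdigest()
    if digest != CHECKSUMS[name]:
        raise ValidationError(
            f"fixture {name} is corrupted: checksum {digest} != {CHECKSUMS[name]}"
        )
    return ref


def observed_state_shares() -> pd.DataFrame:
    """Observed 2011/2013 state shares (percent), indexed by state 1..5."""
    with resources.as_file(_fixture_path("observed_state_shares.csv")) as path:
        return pd.read_csv(path, index_col="state")


def baseline_share_vector() -> np.ndarray:
    """The observed 2011 distribution over states as a probability 5-vector.

    The death share is zero by construction: 2011 respondents are alive.
    """
    shares = observed_state_shares()["percent_2011"].to_numpy() / 100.0
    shares[4] = 0.0
    return shares


def overall_matrix() -> TransitionMatrix:
    """The overall two-year transition matrix."""
    with resources.as_file(_fixture_path("overall_matrix.csv")) as path:
        return read_matrix(path)


def age_specific_matrices() -> dict[str, TransitionMatrix]:
    """The five age-specific two-year transition matrices, keyed by label."""
    names = {
        "60-64": "age_matrix_60-64.csv",
        "65-69": "age_matrix_65-69.csv",
        "70-74": "age_matrix_70-74.csv",
        "75-79": "age_matrix_75-79.csv",
        "80+": "age_matrix_80plus.csv",
    }
    out = {}
    for label, name in names.items():
        # the published 65-69 table carries a typo: its first row sums to
        # 1.0100; keep the printed digits and let the loader renormalize
        atol = 0.011 if label == "65-69" else 5e-4
        with resources.as_file(_fixture_path(name)) as path:
            out[label] = read_matrix(path, row_sum_atol=atol)
    return out


def percapita_expenditure() -> pd.DataFrame:
    """Per-capita expenditure by state: family_annual and individual_monthly
    columns (yuan), indexed by state 1..4."""
    with resources.as_file(_fixture_path("percapita_expenditure.csv")) as path:
        return pd.read_csv(path, index_col="state")


def percapita_expenditure_by_age() -> pd.DataFrame:
    """Per-capita expenditure by age group and state (yuan)."""
    with resources.as_file(_fixture_path("percapita_expenditure_by_age.csv")) as path:
        return pd.read_csv(path, index_col=["age_group", "state"])


def projected_population_by_age() -> pd.DataFrame:
    """Projected population (persons) by age group, year and state."""
    with resources.as_file(_fixture_path("projected_population_by_age.csv")) as path:
        df = pd.read_csv(path)
    df["population"] = df.pop("population_10k") * 10_000.0
    return df


def projected_2035_population() -> pd.Series:
    """Projected 2035 national population (persons) by state 1..4."""
    with resources.as_file(_fixture_path("projected_2035_population.csv")) as path:
        return pd.read_csv(path, index_col="state")["population"].astype(float)


def base_population_2015() -> pd.DataFrame:
    """2015 population by age group and state — the projection start point."""
    df = projected_population_by_age()
    out = df[df["year"] == 2015][["age_group", "state", "population"]].copy()
    missing = set(AGE_GROUP_LABELS) - set(out["age_group"])
    if missing:
        raise ValidationError(f"2015 base population missing age groups {missing}")
    return out.reset_index(drop=True)
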