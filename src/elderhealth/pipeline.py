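"""End-to-end pipeline: simulate -> fit -> project -> aggregate.

Two entry points live here.  :func:`run_pipeline` chains the full
analysis on a synthetic panel — generation, transition-matrix and
two-part expenditure estimation, Chapman-Kolmogorov projection, and
actuarial aggregation — writing every intermediate artifact so each
stage can be inspected or re-run.  :func:`reproduce_published` re-derives
from the bundled fixtures every piece of downstream arithmetic that the
published estimates determine completely (one-step propagation of the
baseline shares, annualization, between-state ratios, the 2035
expenditure totals, gap and age-group changes) and reports a pass/fail
table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, actuarial, expenditure, fixtures, forecast, synthetic, transitions
from ._errors import ElderHealthError
from .matrix import write_matrix

logger = logging.getLogger("elderhealth")


class PipelineError(ElderHealthError):
    """A stage failed; the message names the stage and its input."""


def default_config() -> dict:
    """Demo configuration: a 5,000-person panel and a 2015-2035 projection."""
    return {
        "seed": 0,
        "n": 5000,
        "covariates": [],
        "expenditure_covariates": ["state", "age"],
        "basis": "annual",
        "base_year": 2015,
        "horizon": 2035,
        "entrants_per_year": 16_000_000.0,
        "aging": True,
        "annualization": "interpolate",
        "use_age_specific_matrices": False,
    }


def demo_truth(seed: int = 0) -> synthetic.GeneratorTruth:
    """A ground truth with the bundled overall kernel and a two-part
    expenditure process whose level rises with worse health."""
    kernel = fixtures.overall_matrix()
    specs = synthetic.default_covariate_specs()
    names = tuple(s.name for s in specs)
    transition = synthetic.TransitionTruth.from_kernel(kernel, names)
    individual = synthetic.TwoPartTruth(
        delta1={"const": 0.2, "state": 0.25},
        delta2={"const": 100.0, "state": 150.0},
        sigma=60.0,
    )
    family = synthetic.TwoPartTruth(
        delta1={"const": 0.2, "state": 0.25},
        delta2={"const": 2500.0, "state": 1000.0},
        sigma=600.0,
    )
    return synthetic.GeneratorTruth(
        transition=transition,
        individual_monthly=individual,
        family_annual=family,
        seed=seed,
    )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | None = None, out_dir: str | Path = "artifacts") -> dict[str, Path]:
    """Run every stage in order, writing each intermediate to ``out_dir``.

    Returns a map of artifact name -> path.  Deterministic under a fixed
    seed; any stage failure raises :class:`PipelineError` naming the
    stage.  A ``provenance.yaml`` sidecar records the package version,
    seed, config hash and per-stage row counts.
    """
    config = {**default_config(), **(config or {})}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    row_counts: dict[str, int] = {}
    stage = "simulate"
    try:
        truth = demo_truth(seed=int(config["seed"]))
        panel = synthetic.simulate_panel(truth, n=int(config["n"]))
        artifacts["panel"] = out_dir / "panel.csv"
        synthetic.write_panel(panel, artifacts["panel"])
        row_counts["panel"] = len(panel)
        logger.info("simulate: wrote %d panel rows", len(panel))

        stage = "fit-transitions"
        fit = transitions.fit_transition_model(panel, config["covariates"])
        matrix = transitions.predict_transition_matrix(fit)
        artifacts["matrix"] = out_dir / "matrix_overall.csv"
        write_matrix(matrix, artifacts["matrix"])
        matrices_dir = out_dir / "matrices"
        matrices_dir.mkdir(exist_ok=True)
        by_age, flagged = transitions.stratified_matrices(panel)
        for label, m in by_age.items():
            write_matrix(m, matrices_dir / f"matrix_{label.replace('+', 'plus')}.csv")
        row_counts["transition_pairs"] = fit.n_used
        logger.info(
            "fit-transitions: %d pairs, %d age-group matrices (%d flagged)",
            fit.n_used, len(by_age), len(flagged),
        )

        stage = "fit-expenditure"
        cov = config["expenditure_covariates"]
        fit_ind = expenditure.fit_two_part(panel, "individual_monthly", cov)
        fit_fam = expenditure.fit_two_part(panel, "family_annual", cov)
        table = expenditure.per_state_expenditure(panel, fit_fam, fit_ind)
        artifacts["expenditure_table"] = out_dir / "expenditure_table.csv"
        expenditure.write_expenditure_table(table, artifacts["expenditure_table"])
        row_counts["expenditure_fit"] = fit_ind.n_used
        logger.info("fit-expenditure: n=%d (positive %d)", fit_ind.n_used, fit_ind.n_positive)

        stage = "project"
        base = fixtures.base_population_2015()
        entrants = forecast.EntrantsSchedule(
            {
                year: float(config["entrants_per_year"])
                for year in range(int(config["base_year"]) + 1, int(config["horizon"]) + 1)
            }
        )
        kernels = (
            fixtures.age_specific_matrices()
            if config["use_age_specific_matrices"]
            else matrix
        )
        series = forecast.project_cohorts(
            base,
            kernels,
            entrants=entrants,
            base_year=int(config["base_year"]),
            horizon=int(config["horizon"]),
            aging=bool(config["aging"]),
            annualization=config["annualization"],
        )
        artifacts["series"] = out_dir / "series.csv"
        forecast.write_series(series, artifacts["series"])
        row_counts["series"] = len(series.data)
        logger.info("project: %d series rows", len(series.data))

        stage = "forecast-expenditure"
        result = actuarial.total_expenditure(series, table, basis=config["basis"])
        artifacts["forecast"] = out_dir / "forecast.csv"
        actuarial.render_report(result, artifacts["forecast"])
        row_counts["forecast"] = len(result.data)
        logger.info("forecast-expenditure: %d rows", len(result.data))
    except ElderHealthError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    except FileNotFoundError as exc:
        raise PipelineError(f"stage {stage!r} failed: missing input {exc}") from exc

    provenance = {
        "package_version": __version__,
        "seed": int(config["seed"]),
        "config_hash": _config_hash(config),
        "row_counts": row_counts,
    }
    with open(out_dir / "provenance.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    artifacts["provenance"] = out_dir / "provenance.yaml"
    return artifacts


def reproduce_published(out_dir: str | Path | None = None) -> pd.DataFrame:
    """Re-derive the published downstream arithmetic from bundled fixtures.

    Every check recomputes a quantity from the fixture tables through
    the package's own operations and compares it with the published
    number at its printed tolerance.  Returns the check table (and
    writes ``reproduction_report.csv`` when ``out_dir`` is given).
    """
    checks: list[dict] = []

    def check(name, computed, expected, tol, source):
        checks.append(
            {
                "check": name,
                "computed": computed,
                "expected": expected,
                "tolerance": tol,
                "passed": abs(computed - expected) <= tol,
                "source": source,
            }
        )

    # one-step propagation of the 2011 shares vs the observed 2013 share
    shares = fixtures.baseline_share_vector()
    P = fixtures.overall_matrix()
    after = forecast.propagate(shares, P)
    check(
        "state1_share_2013_pct", 100 * after[0], 12.96, 0.1,
        "observed-shares table x overall matrix",
    )

    # annualization of the monthly per-capita values
    t5 = fixtures.percapita_expenditure()
    check(
        "annual_individual_state4_yuan",
        expenditure.annualize_monthly(float(t5.loc[4, "individual_monthly"])),
        7774.32, 0.005, "per-capita table, state 4 x 12",
    )
    check(
        "annual_individual_state3_yuan",
        expenditure.annualize_monthly(float(t5.loc[3, "individual_monthly"])),
        3791.88, 0.005, "per-capita table, state 3 x 12",
    )

    # between-state "times higher" ratios
    ratios = expenditure.expenditure_ratios(t5)
    check("family_ratio_state4_vs_1", ratios["family_annual"], 1.27, 0.005,
          "per-capita table, family column")
    check("individual_ratio_state4_vs_1", ratios["individual_monthly"], 2.64, 0.005,
          "per-capita table, individual column")

    # 2035 totals under the monthly basis, their gap
    pops = fixtures.projected_2035_population()
    result = actuarial.forecast_from_populations(pops, t5, basis="monthly", year=2035)
    check("total_2035_state4_billion", result.total_billions(2035, 4), 48.645, 0.01,
          "2035 populations x per-capita table")
    check("total_2035_state1_billion", result.total_billions(2035, 1), 10.558, 0.01,
          "2035 populations x per-capita table")
    check(
        "gap_2035_state4_minus_1_billion",
        actuarial.expenditure_gap(result, 2035, 4, 1) / actuarial.YUAN_PER_BILLION,
        38.088, 0.01, "difference of the two 2035 totals",
    )

    # age-group change statistics from the published state-4 totals
    s4 = fixtures.STATE4_BY_AGE_BILLIONS
    res_2015 = _result_from_billions(s4[2015], year=2015)
    res_2035 = _result_from_billions(s4[2035], year=2035)
    change = actuarial.expenditure_change(res_2015, res_2035, state=4, age_group="65-69")
    check("change_65_69_state4_billion", change / actuarial.YUAN_PER_BILLION,
          6.111, 0.0005, "published 2015/2035 state-4 totals, 65-69")
    change = actuarial.expenditure_change(res_2015, res_2035, state=4, age_group="70-74")
    check("change_70_74_state4_billion", change / actuarial.YUAN_PER_BILLION,
          6.487, 0.0005, "published 2015/2035 state-4 totals, 70-74")

    report = pd.DataFrame(checks)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "reproduction_report.csv", index=False)
    return report


def _result_from_billions(by_group: dict[str, float], year: int) -> actuarial.ForecastResult:
    """Wrap published per-age-group state-4 totals as a ForecastResult."""
    rows = pd.DataFrame(
        {
            "year": year,
            "age_group": list(by_group),
            "state": 4,
            "population": np.nan,
            "per_capita": np.nan,
            "total_yuan": [v * actuarial.YUAN_PER_BILLION for v in by_group.values()],
        }
    )
    return actuarial.ForecastResult(rows, basis="monthly", provenance={"source": "published totals"})
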