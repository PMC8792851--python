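"""Two-part expenditure model: recovery, means, tables, ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from elderhealth import EstimationError, ValidationError, fixtures
from elderhealth import synthetic
from elderhealth.expenditure import (
    TwoPartFit,
    annualize_monthly,
    expected_expenditure,
    expenditure_ratios,
    fit_two_part,
    per_state_expenditure,
    read_expenditure_table,
    write_expenditure_table,
)
from elderhealth.synthetic import GeneratorTruth, TransitionTruth, TwoPartTruth


def manual_fit(delta1, delta2, sigma=0.0, outcome="individual_monthly"):
    cols = sorted(set(delta1) | set(delta2), key=lambda c: (c != "const", c))
    return TwoPartFit(
        outcome=outcome,
        design_columns=cols,
        delta1={c: delta1.get(c, 0.0) for c in cols},
        delta1_bse={c: 0.0 for c in cols},
        delta2={c: delta2.get(c, 0.0) for c in cols},
        delta2_bse={c: 0.0 for c in cols},
        sigma=sigma,
        n_used=0,
        n_positive=0,
        log_likelihood=0.0,
    )


class TestFitTwoPart:
    def test_constant_outcome_limit(self):
        rng = np.random.default_rng(0)
        n = 4000
        panel = pd.DataFrame(
            {
                "person_id": range(n),
                "wave": 1,
                "age": 70,
                "state": rng.integers(1, 5, n),
                "x": rng.normal(size=n),
            }
        )
        care = rng.random(n) < 0.5
        panel["individual_monthly_expenditure"] = np.where(care, 500.0, 0.0)
        fit = fit_two_part(panel, "individual_monthly", ["x"])
        assert fit.delta2["const"] == pytest.approx(500.0, abs=1e-8)
        assert fit.delta2["x"] == pytest.approx(0.0, abs=1e-8)
        assert fit.sigma == pytest.approx(0.0, abs=1e-6)
        lo, hi = fit.wald_interval(1, "const")
        assert lo < 0 < hi  # 50% participation => probit intercept ~ 0

    def test_all_zero_outcome_unidentified(self):
        panel = pd.DataFrame(
            {"person_id": [1, 2], "wave": 1, "age": 70, "state": [1, 2],
             "individual_monthly_expenditure": [0.0, 0.0]}
        )
        with pytest.raises(EstimationError, match="unidentified"):
            fit_two_part(panel, "individual_monthly", [])

    def test_health_gradient_sign_recovered(self, big_panel, demo_truth):
        """The generated truth spends more in worse states; fits agree."""
        fit = fit_two_part(big_panel, "individual_monthly", ["state"])
        assert fit.delta1["state"] > 0
        assert fit.delta2["state"] > 0

    def test_joint_likelihood_is_finite_and_negative(self, small_panel):
        fit = fit_two_part(small_panel, "family_annual", ["state"])
        assert np.isfinite(fit.log_likelihood)
        assert fit.n_positive < fit.n_used


class TestExpectedExpenditure:
    def test_probit_symmetry_halves_the_level(self):
        fit = manual_fit({"const": 0.0}, {"const": 400.0})
        assert expected_expenditure(fit, {}) == pytest.approx(200.0)

    def test_saturated_participation_passes_level_through(self):
        fit = manual_fit({"const": 40.0}, {"const": 355.69})
        assert expected_expenditure(fit, {}) == pytest.approx(355.69)

    def test_negative_level_floored_at_zero(self):
        fit = manual_fit({"const": 0.0}, {"const": -50.0})
        assert expected_expenditure(fit, {}) == 0.0

    def test_monte_carlo_oracle(self):
        """Simulated mean at a fixed profile matches Phi(x d1) max(x d2, 0)."""
        truth = TwoPartTruth({"const": 0.4, "state": 0.1}, {"const": 100.0, "state": 150.0}, 60.0)
        gen = GeneratorTruth(
            transition=TransitionTruth.from_kernel(fixtures.overall_matrix(), ()),
            individual_monthly=truth,
            seed=13,
        )
        n = 1_000_000
        records = pd.DataFrame(
            {"person_id": range(n), "wave": 1, "age": 70, "state": 3}
        )
        out = synthetic.simulate_expenditure(records, gen)
        mc_mean = out["individual_monthly_expenditure"].mean()
        fit = manual_fit(truth.delta1, truth.delta2)
        analytic = expected_expenditure(fit, {"state": 3.0})
        # censoring at 0 is ~Phi(-550/60) here, so the closed form is exact
        assert mc_mean == pytest.approx(analytic, rel=0.01)

    def test_incomplete_profile_rejected(self):
        fit = manual_fit({"const": 0.0, "state": 0.1}, {"const": 1.0, "state": 1.0})
        with pytest.raises(ValidationError, match="missing"):
            expected_expenditure(fit, {})


class TestPerStateTable:
    def test_state_blind_model_gives_equal_states(self, small_panel):
        fit = fit_two_part(small_panel, "individual_monthly", [])
        table = per_state_expenditure(small_panel, fit_individual=fit)
        values = table["individual_monthly"].to_numpy()
        np.testing.assert_allclose(values, values[0])

    def test_monotone_truth_yields_monotone_table(self, big_panel, demo_truth):
        fit_i = fit_two_part(big_panel, "individual_monthly", ["state"])
        fit_f = fit_two_part(big_panel, "family_annual", ["state"])
        table = per_state_expenditure(big_panel, fit_f, fit_i)
        for col in ("individual_monthly", "family_annual"):
            assert table[col].is_monotonic_increasing
        assert (table >= 0).all().all()

    def test_by_age_table_has_age_group_index(self, big_panel):
        fit = fit_two_part(big_panel, "individual_monthly", ["state", "age"])
        table = per_state_expenditure(big_panel, fit_individual=fit, by_age=True)
        assert table.index.names == ["age_group", "state"]
        assert set(table.index.get_level_values("state")) <= {1, 2, 3, 4}

    def test_round_trip(self, tmp_path):
        table = fixtures.percapita_expenditure()
        write_expenditure_table(table, tmp_path / "t.csv")
        back = read_expenditure_table(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back, table)


class TestDecomposition:
    def test_fitted_mean_matches_observed_mean(self, big_panel):
        fit = fit_two_part(big_panel, "individual_monthly", ["state"])
        living = big_panel[big_panel["state"] != 5]
        observed = living["individual_monthly_expenditure"].mean()
        fitted = np.mean(expected_expenditure(fit, living))
        assert fitted == pytest.approx(observed, rel=0.02)

    def test_reduces_to_ols_under_full_participation(self, big_panel):
        fit = fit_two_part(big_panel, "individual_monthly", ["state"])
        forced = manual_fit({"const": 100.0}, fit.delta2)
        living = big_panel[big_panel["state"] != 5]
        X = np.column_stack([np.ones(len(living)), living["state"]])
        beta = np.array([fit.delta2["const"], fit.delta2["state"]])
        np.testing.assert_allclose(
            expected_expenditure(forced, living),
            np.maximum(X @ beta, 0.0),
        )

    def test_rmse_shrinks_with_sample_size(self, demo_truth):
        """delta2 RMSE roughly halves per 4x sample, i.e. ~1/sqrt(n)."""
        truth_val = demo_truth.individual_monthly.delta2["state"]
        rmse = {}
        for n in (500, 5000, 50000):
            errs = []
            for rep in range(8):
                truth = GeneratorTruth(
                    transition=demo_truth.transition,
                    individual_monthly=demo_truth.individual_monthly,
                    family_annual=demo_truth.family_annual,
                    seed=1000 + 17 * rep + n,
                )
                panel = synthetic.simulate_panel(truth, n=n)
                fit = fit_two_part(panel, "individual_monthly", ["state"])
                errs.append(fit.delta2["state"] - truth_val)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[500] > rmse[5000] > rmse[50000]
        assert rmse[500] / rmse[50000] > 4  # ~10 expected under 1/sqrt(n)


class TestScalars:
    @pytest.mark.parametrize(
        "monthly,annual",
        [(647.86, 7774.32), (315.99, 3791.88), (175.73, 2108.76), (177.81, 2133.72), (0.0, 0.0)],
    )
    def test_annualization(self, monthly, annual):
        assert annualize_monthly(monthly) == pytest.approx(annual, abs=1e-9)

    def test_negative_monthly_rejected(self):
        with pytest.raises(ValidationError):
            annualize_monthly(-1.0)

    def test_times_higher_ratios_from_bundled_table(self):
        ratios = expenditure_ratios(fixtures.percapita_expenditure())
        assert ratios["family_annual"] == 1.27
        assert ratios["individual_monthly"] == 2.64

    def test_equal_values_give_zero_ratio(self):
        table = pd.DataFrame(
            {"individual_monthly": [100.0] * 4}, index=pd.Index([1, 2, 3, 4], name="state")
        )
        assert expenditure_ratios(table)["individual_monthly"] == 0.0
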