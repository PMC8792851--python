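"""Generator correctness: marginals, determinism, invariants, file I/O."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from elderhealth import SchemaError, ValidationError, fixtures, synthetic
from elderhealth.synthetic import (
    CovariateSpec,
    GeneratorTruth,
    TransitionTruth,
    TwoPartTruth,
    default_covariate_specs,
    generate_baseline,
    read_panel,
    simulate_expenditure,
    simulate_wave2,
    write_panel,
)

SPECS = default_covariate_specs()
NAMES = tuple(s.name for s in SPECS)


def truth_from_kernel(kernel, seed=0, sigma=60.0):
    return GeneratorTruth(
        transition=TransitionTruth.from_kernel(kernel, NAMES),
        individual_monthly=TwoPartTruth({"const": 0.3}, {"const": 400.0}, sigma),
        seed=seed,
    )


class TestCovariateSpec:
    def test_binary_probability_validated(self):
        with pytest.raises(ValidationError):
            CovariateSpec("x", "binary", {"p": 1.4})

    def test_continuous_sd_validated(self):
        with pytest.raises(ValidationError):
            CovariateSpec("x", "continuous", {"mean": 0, "sd": 0})

    def test_categorical_probs_must_normalize(self):
        with pytest.raises(ValidationError):
            CovariateSpec("x", "categorical", {"levels": [0, 1], "probs": [0.7, 0.7]})


class TestGenerateBaseline:
    def test_degenerate_distribution_puts_everyone_in_state_1(self):
        df = generate_baseline(SPECS, 10, state_distribution=(1, 0, 0, 0), seed=3)
        assert (df["state"] == 1).all()
        assert (df["wave"] == 1).all()

    def test_state_shares_match_target_within_binomial_error(self):
        target = np.array([0.1215, 0.2982, 0.3849, 0.1954])
        df = generate_baseline(SPECS, 5487, state_distribution=target, seed=1)
        shares = df["state"].value_counts(normalize=True).sort_index().to_numpy()
        se = np.sqrt(target * (1 - target) / len(df))
        assert np.all(np.abs(shares - target) < 3 * se)

    def test_same_seed_identical_different_seed_differs(self):
        kwargs = dict(n=5000, state_distribution=(0.25, 0.25, 0.25, 0.25))
        a = generate_baseline(SPECS, seed=1, **kwargs)
        b = generate_baseline(SPECS, seed=1, **kwargs)
        c = generate_baseline(SPECS, seed=2, **kwargs)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        a.to_csv(buf_a, index=False)
        b.to_csv(buf_b, index=False)
        assert buf_a.getvalue() == buf_b.getvalue()
        assert not a.equals(c)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValidationError):
            generate_baseline(SPECS, 10, state_distribution=(0.5, 0.5, 0.5, 0.5))

    def test_empty_covariate_spec_rejected(self):
        with pytest.raises(ValidationError):
            generate_baseline([], 10)


class TestSimulateWave2:
    def test_identity_kernel_keeps_every_state(self):
        # near-identity: reference coding needs strictly positive entries
        probs = np.full((5, 5), 0.0008)
        np.fill_diagonal(probs, 0.9968)
        probs[4] = [0, 0, 0, 0, 1]
        truth = truth_from_kernel(probs, seed=5)
        w1 = generate_baseline(SPECS, 4000, state_distribution=(0.25,) * 4, seed=5)
        w2 = simulate_wave2(w1, truth)
        assert (w2["age"] == w1["age"] + 2).all()
        assert (w2["state"] == w1["state"]).mean() > 0.99

    def test_marginal_matches_matrix_vector_product(self):
        """Monte-Carlo wave-2 marginal vs the exact shares . kernel oracle."""
        kernel = fixtures.overall_matrix()
        shares = np.array([0.1215, 0.2982, 0.3849, 0.1954])
        truth = truth_from_kernel(kernel, seed=11)
        w1 = generate_baseline(SPECS, 100_000, state_distribution=shares, seed=11)
        w2 = simulate_wave2(w1, truth)
        expected = np.concatenate([shares, [0.0]]) @ kernel.probs
        observed = w2["state"].value_counts(normalize=True).sort_index().to_numpy()
        se = np.sqrt(expected * (1 - expected) / len(w2))
        assert np.all(np.abs(observed - expected) < 3 * se + 1e-12)

    def test_duplicate_person_rejected(self):
        w1 = generate_baseline(SPECS, 10, seed=0)
        doubled = pd.concat([w1, w1])
        with pytest.raises(ValidationError, match="duplicate"):
            simulate_wave2(doubled, truth_from_kernel(fixtures.overall_matrix()))

    def test_wave2_input_rejected(self):
        truth = truth_from_kernel(fixtures.overall_matrix())
        w1 = generate_baseline(SPECS, 10, seed=0)
        w2 = simulate_wave2(w1, truth)
        with pytest.raises(ValidationError, match="wave 1"):
            simulate_wave2(w2, truth)


class TestSimulateExpenditure:
    def test_saturated_participation(self):
        truth = GeneratorTruth(
            transition=TransitionTruth.from_kernel(fixtures.overall_matrix(), NAMES),
            individual_monthly=TwoPartTruth({"const": 50.0}, {"const": 400.0}, 10.0),
            seed=2,
        )
        w1 = generate_baseline(SPECS, 2000, seed=2)
        out = simulate_expenditure(w1, truth)
        assert (out["sought_care"] == 1).all()

    def test_probit_symmetry_gives_half_participation(self):
        truth = GeneratorTruth(
            transition=TransitionTruth.from_kernel(fixtures.overall_matrix(), NAMES),
            individual_monthly=TwoPartTruth({"const": 0.0}, {"const": 400.0}, 10.0),
            seed=4,
        )
        w1 = generate_baseline(SPECS, 50_000, seed=4)
        out = simulate_expenditure(w1, truth)
        assert abs(out["sought_care"].mean() - 0.5) < 3 * np.sqrt(0.25 / len(out))

    def test_deterministic_level_annualizes_to_published_value(self):
        truth = GeneratorTruth(
            transition=TransitionTruth.from_kernel(fixtures.overall_matrix(), NAMES),
            individual_monthly=TwoPartTruth({"const": 5.0}, {"const": 647.86}, 0.0),
            seed=6,
        )
        w1 = generate_baseline(SPECS, 100, seed=6)
        out = simulate_expenditure(w1, truth)
        seekers = out[out["sought_care"] == 1]
        assert np.allclose(seekers["individual_monthly_expenditure"], 647.86)
        assert np.allclose(seekers["individual_monthly_expenditure"] * 12, 7774.32)

    def test_zero_inflation_matches_probit_mass(self, demo_truth):
        """P(expenditure = 0) converges to 1 - mean Phi(x . delta1)."""
        w1 = generate_baseline(SPECS, 50_000, seed=9)
        out = simulate_expenditure(w1, demo_truth)
        idx = demo_truth.individual_monthly.participation_index(w1)
        expected_zero = 1 - norm.cdf(idx).mean()
        observed_zero = (out["individual_monthly_expenditure"] == 0).mean()
        assert abs(observed_zero - expected_zero) < 3 * np.sqrt(0.25 / len(out))

    def test_care_seeking_iff_positive_expenditure(self, small_panel):
        zero = small_panel["individual_monthly_expenditure"] == 0
        no_care = small_panel["sought_care"] == 0
        assert (zero == no_care).all()

    def test_dead_records_have_zero_expenditure(self, big_panel):
        dead = big_panel[big_panel["state"] == 5]
        assert len(dead) > 0
        assert (dead["sought_care"] == 0).all()
        assert (dead["individual_monthly_expenditure"] == 0).all()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            TwoPartTruth({"const": 0.0}, {"const": 1.0}, -1.0)


class TestPanelIO:
    def test_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "panel.csv"
        write_panel(small_panel, path)
        back = read_panel(path)
        pd.testing.assert_frame_equal(back, small_panel.reset_index(drop=True))

    def test_unknown_state_code_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("person_id,wave,age,state\np1,1,65,7\n")
        with pytest.raises(SchemaError, match="row 0.*state"):
            read_panel(path)

    def test_negative_expenditure_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "person_id,wave,age,state,individual_monthly_expenditure\np1,1,65,2,-5\n"
        )
        with pytest.raises(SchemaError, match="negative"):
            read_panel(path)
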