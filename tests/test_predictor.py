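"""Feature-table construction, subject-level splitting, OLS fitting with
inference, prediction and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toegait import (
    KamReductionModel,
    SimulationConfig,
    build_feature_table,
    simulate_cohort,
    simulate_feature_response,
    split_by_subject,
    synthesize_cohort,
    learn_pattern_library,
)
from toegait.exceptions import CollinearityError
from toegait.predictor import (
    FEATURE_COLUMNS,
    fit_linear_model,
    predict_reduction,
)


@pytest.fixture(scope="module")
def noiseless_table():
    df, truth = simulate_feature_response(
        SimulationConfig(seed=11, n_subjects=138, sigma_y=0.0)
    )
    return df, truth


class TestFeatureTable:
    def test_rows_per_entry_and_feature_copying(self, clean_cohort):
        subjects, _ = clean_cohort
        lib = learn_pattern_library(subjects)
        targets, _ = simulate_cohort(
            SimulationConfig(seed=13, n_subjects=7), with_toe_in=False
        )
        entries = synthesize_cohort(targets, lib)
        table = build_feature_table(entries, targets)
        assert len(table) == 70
        one = table[table.subject_id == targets[0].subject_id]
        assert sorted(one.toe_in_deg) == list(range(1, 11))
        # clinical features identical across a subject's rows
        for col in ("height_m", "weight_kg", "speed_mps", "valgus_deg"):
            assert one[col].nunique() == 1

    def test_unknown_subject_rejected(self, clean_cohort):
        subjects, _ = clean_cohort
        lib = learn_pattern_library(subjects)
        entries = synthesize_cohort(subjects[:1], lib)
        with pytest.raises(KeyError):
            build_feature_table(entries, subjects[1:2])


class TestSplit:
    def test_counts_138(self, noiseless_table):
        df, _ = noiseless_table
        out = split_by_subject(df, seed=5)
        per = out.groupby("split")["subject_id"].nunique()
        assert per["train"] == 110 and per["val"] == 14 and per["test"] == 14

    def test_deterministic_and_partition(self, noiseless_table):
        df, _ = noiseless_table
        a = split_by_subject(df, seed=9)
        b = split_by_subject(df, seed=9)
        assert (a["split"] == b["split"]).all()
        labels = a.groupby("subject_id")["split"].nunique()
        assert (labels == 1).all()

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "reduction": [0.1, 0.2]})
        with pytest.raises(ValueError):
            split_by_subject(df)


class TestFit:
    def test_exact_ols_on_noiseless_design(self, rng):
        n = 200
        z1, z2 = rng.normal(size=(2, n))
        df = pd.DataFrame(
            {"subject_id": "x", "f1": z1, "f2": z2, "reduction": 2.0 * z1 - z2}
        )
        res = fit_linear_model(df, features=["f1", "f2"])
        raw = res.params_raw
        assert raw["f1"] == pytest.approx(2.0, abs=1e-8)
        assert raw["f2"] == pytest.approx(-1.0, abs=1e-8)
        assert res.evaluate(df)["r2_prediction"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_response(self, rng):
        df = pd.DataFrame(
            {"subject_id": "x", "f1": rng.normal(size=50), "reduction": 0.44}
        )
        res = fit_linear_model(df, features=["f1"])
        assert res.coefficients[0] == pytest.approx(0.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.44)

    def test_standardization_and_leakage_guard(self, noiseless_table):
        df, _ = noiseless_table
        df = split_by_subject(df, seed=1)
        res = KamReductionModel(df).fit(split="train")
        Z = res.transform(df[df.split == "train"])
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(Z.var(axis=0) - 1.0) < 1e-10)
        # held-out rows transformed with training parameters only
        Zt = res.transform(df[df.split == "test"])
        assert np.any(np.abs(Zt.mean(axis=0)) > 1e-6)

    def test_collinear_design_named(self, rng):
        f1 = rng.normal(size=60)
        df = pd.DataFrame(
            {"subject_id": "x", "f1": f1, "f2": 2.0 * f1, "reduction": f1}
        )
        with pytest.raises(CollinearityError, match="f1"):
            fit_linear_model(df, features=["f1", "f2"])

    def test_degenerate_feature_rejected(self, rng):
        df = pd.DataFrame(
            {"subject_id": "x", "f1": np.ones(60), "reduction": rng.normal(size=60)}
        )
        with pytest.raises(CollinearityError):
            fit_linear_model(df, features=["f1"])

    def test_single_feature_model_supported(self, noiseless_table):
        df, truth = noiseless_table
        res = fit_linear_model(df, features=["toe_in_deg"])
        assert res.feature_names == ["toe_in_deg"]
        assert np.isfinite(res.p_values).all()

    def test_coefficient_recovery_and_dominance(self, noiseless_table):
        df, truth = noiseless_table
        res = fit_linear_model(df)
        for f in FEATURE_COLUMNS:
            assert res.params_raw[f] == pytest.approx(truth["beta_raw"][f], abs=1e-8)
        assert res.params.abs().idxmax() == "toe_in_deg"

    def test_estimator_sd_shrinks_with_n(self):
        """OLS theory: multiplying n by ~100 shrinks the coefficient SE
        by ~10x."""
        small = simulate_feature_response(
            SimulationConfig(seed=2, n_subjects=10, sigma_y=0.05)
        )[0]
        large = simulate_feature_response(
            SimulationConfig(seed=2, n_subjects=1000, sigma_y=0.05)
        )[0]
        se_small = fit_linear_model(small).bse["toe_in_deg"]
        se_large = fit_linear_model(large).bse["toe_in_deg"]
        assert se_small / se_large == pytest.approx(10.0, rel=0.5)

    def test_ci_coverage_monte_carlo(self):
        """Empirical 95% CI coverage of each coefficient stays in a
        binomial-plausible band over 60 replicates."""
        R = 60
        cover = np.zeros(len(FEATURE_COLUMNS))
        for r in range(R):
            df, truth = simulate_feature_response(
                SimulationConfig(seed=20_000 + r, n_subjects=138, sigma_y=0.05)
            )
            res = fit_linear_model(df)
            tcrit = stats.t.ppf(0.975, res.n_train - len(FEATURE_COLUMNS) - 1)
            for j, f in enumerate(FEATURE_COLUMNS):
                half = tcrit * res.stderrs[j] / res.scales[j]
                cover[j] += (
                    abs(res.coefficients[j] / res.scales[j] - truth["beta_raw"][f])
                    <= half
                )
        assert np.all(cover / R >= 0.85) and np.all(cover / R <= 1.0)


class TestPredictEvaluate:
    def test_prediction_identities(self, noiseless_table):
        df, _ = noiseless_table
        res = fit_linear_model(df)
        at_means = {f: m for f, m in zip(res.feature_names, res.means)}
        assert predict_reduction(res, at_means) == pytest.approx(res.intercept)
        bumped = dict(at_means)
        bumped["toe_in_deg"] += res.scales[res.feature_names.index("toe_in_deg")]
        assert predict_reduction(res, bumped) - res.intercept == pytest.approx(
            res.params["toe_in_deg"]
        )

    def test_perfect_and_offset_predictions(self, noiseless_table):
        df, _ = noiseless_table
        res = fit_linear_model(df)
        ev = res.evaluate(df)
        assert ev["mae"] == pytest.approx(0.0, abs=1e-10)
        assert ev["r2_prediction"] == pytest.approx(1.0)
        assert ev["mean_signed_error"] == pytest.approx(0.0, abs=1e-10)
        # uniform +0.1 shift in actuals -> MAE 0.1, signed error +0.1
        shifted = df.copy()
        shifted["reduction"] = shifted["reduction"] + 0.1
        ev2 = res.evaluate(shifted)
        assert ev2["mae"] == pytest.approx(0.1, abs=1e-9)
        assert ev2["mean_signed_error"] == pytest.approx(0.1, abs=1e-9)

    def test_shuffled_predictions_r2_near_zero(self, rng):
        df, _ = simulate_feature_response(
            SimulationConfig(seed=31, n_subjects=138, sigma_y=0.05)
        )
        res = fit_linear_model(df)
        shuffled = df.copy()
        shuffled["reduction"] = rng.permutation(shuffled["reduction"].to_numpy())
        ev = res.evaluate(shuffled)
        assert ev["r2_fit_line"] < 0.05

    def test_empty_rows_rejected(self, noiseless_table):
        df, _ = noiseless_table
        res = fit_linear_model(df)
        with pytest.raises(ValueError):
            res.evaluate(df.iloc[0:0])
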