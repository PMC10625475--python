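"""Evaluation: scoring power, enrichment, statistical comparison, importance."""
import numpy as np
import pandas as pd
import pytest

from msecif.evaluation import (aggregate_templates, bootstrap_compare,
                               cliffs_delta, enrichment_factor,
                               per_shell_ablation, permutation_importance,
                               scoring_power, seed_ensemble_compare)
from msecif.featurization import shell_scheme
from msecif.model_training import GBTConfig, train

LIGHT = GBTConfig(n_stages=120, max_depth=3, learning_rate=0.1,
                  subsample_fraction=1.0, max_features_rule="all", seed=0)


class TestScoringPower:
    def test_identity_prediction(self):
        result = scoring_power([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert result.pearson_r == pytest.approx(1.0)
        assert result.rmse == pytest.approx(0.0)

    def test_anti_correlation(self):
        experimental = np.array([1.0, 2.0, 3.0, 4.0])
        result = scoring_power(-(experimental - experimental.mean()),
                               experimental)
        assert result.pearson_r == pytest.approx(-1.0)

    def test_four_point_toy_against_hand_calculation(self):
        # points (1,2), (2,2), (3,4), (4,4): r = 4/sqrt(20), rmse = sqrt(1/2)
        result = scoring_power([1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 4.0, 4.0])
        assert result.pearson_r == pytest.approx(4 / np.sqrt(20), abs=1e-12)
        assert result.rmse == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert result.n == 4

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            scoring_power([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            scoring_power([1.0, 2.0], [1.0, 2.0])


class TestEnrichmentFactor:
    def test_single_top_active_among_hundred(self):
        scores = np.linspace(1.0, 0.0, 100)
        labels = np.zeros(100, dtype=bool)
        labels[0] = True                      # top-ranked compound is active
        labels[50:59] = True                  # 9 more actives lower down
        result = enrichment_factor(scores, labels, fraction=0.01)
        assert result.ef_value == pytest.approx(10.0)
        assert result.n_actives == 10

    def test_whole_set_fraction_gives_unity(self):
        rng = np.random.default_rng(0)
        labels = rng.random(50) < 0.2
        labels[0] = True
        result = enrichment_factor(rng.random(50), labels, fraction=1.0)
        assert result.ef_value == pytest.approx(1.0)

    def test_random_scores_have_unit_expectation(self):
        rng = np.random.default_rng(42)
        labels = np.zeros(200, dtype=bool)
        labels[:20] = True
        efs = [enrichment_factor(rng.random(200), labels, 0.01).ef_value
               for _ in range(1000)]
        se = np.std(efs, ddof=1) / np.sqrt(len(efs))
        assert abs(np.mean(efs) - 1.0) < 3 * se + 1e-9

    def test_no_actives_is_an_error(self):
        with pytest.raises(ValueError):
            enrichment_factor([1.0, 2.0], [False, False])


class TestAggregateTemplates:
    def test_single_template_has_zero_sd(self):
        assert aggregate_templates([4.2]) == (pytest.approx(4.2), 0.0)

    def test_two_templates_mean(self):
        mean, _ = aggregate_templates([2.0, 4.0])
        assert mean == pytest.approx(3.0)

    def test_three_templates_hand_formula(self):
        mean, sd = aggregate_templates([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_templates([])


class TestBootstrapCompare:
    def test_identical_predictions_are_indistinguishable(self):
        rng = np.random.default_rng(1)
        y = rng.normal(6, 1, 60)
        preds = y + rng.normal(0, 0.5, 60)
        result = bootstrap_compare(preds, preds.copy(), y, n_boot=200, seed=3)
        assert result["delta_pearson_r"] == 0.0
        assert result["p_pearson_r"] == pytest.approx(1.0)

    def test_perfect_model_beats_noise_model(self):
        rng = np.random.default_rng(2)
        y = rng.normal(6, 1, 100)
        good = y + rng.normal(0, 0.1, 100)
        noise = rng.normal(6, 1, 100)
        result = bootstrap_compare(good, noise, y, n_boot=1000, seed=4)
        assert result["p_pearson_r"] < 1e-3
        assert result["delta_pearson_r"] > 0.9

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(5)
        y = rng.normal(6, 1, 40)
        a = y + rng.normal(0, 0.3, 40)
        b = y + rng.normal(0, 0.6, 40)
        r1 = bootstrap_compare(a, b, y, n_boot=300, seed=11)
        r2 = bootstrap_compare(a, b, y, n_boot=300, seed=11)
        assert r1["p_pearson_r"] == r2["p_pearson_r"]
        assert r1["p_rmse"] == r2["p_rmse"]


class TestSeedEnsembleCompare:
    def test_identical_samples_have_zero_effect(self):
        sample = np.array([0.85, 0.86, 0.87, 0.88])
        result = seed_ensemble_compare(sample, sample.copy())
        assert result["cohens_d"] == pytest.approx(0.0)

    def test_separated_samples_recover_effect_size(self):
        rng = np.random.default_rng(6)
        a = rng.normal(1.5, 1.0, 2000)
        b = rng.normal(0.0, 1.0, 2000)
        result = seed_ensemble_compare(a, b, n_comparisons=3)
        assert result["cohens_d"] == pytest.approx(1.5, abs=0.1)
        assert result["p_corrected"] < 1e-10

    def test_single_comparison_keeps_raw_p(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 30), rng.normal(0.2, 1, 30)
        result = seed_ensemble_compare(a, b, n_comparisons=1)
        assert result["p_corrected"] == pytest.approx(result["p_raw"])

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            seed_ensemble_compare([0.8], [0.9, 0.91])


@pytest.fixture(scope="module")
def driven_model():
    rng = np.random.default_rng(8)
    features = pd.DataFrame({
        "driver": rng.normal(size=250),
        "bystander": rng.normal(size=250),
        "constant": np.ones(250),
    })
    pk = 2.0 * features["driver"].to_numpy() + rng.normal(0, 0.1, 250)
    model = train(features, pk, LIGHT)
    return model, features, pk


class TestPermutationImportance:
    def test_constant_feature_has_exactly_zero_importance(self, driven_model):
        model, features, pk = driven_model
        imp = permutation_importance(model, features, pk, n_repeats=5, seed=0)
        assert imp.loc["constant", "importance_mean"] == 0.0

    def test_driving_feature_ranks_first(self, driven_model):
        model, features, pk = driven_model
        imp = permutation_importance(model, features, pk, n_repeats=10, seed=0)
        assert imp["importance_mean"].idxmax() == "driver"

    def test_fixed_seed_is_deterministic(self, driven_model):
        model, features, pk = driven_model
        imp1 = permutation_importance(model, features, pk, n_repeats=5, seed=2)
        imp2 = permutation_importance(model, features, pk, n_repeats=5, seed=2)
        pd.testing.assert_frame_equal(imp1, imp2)


@pytest.fixture(scope="module")
def shelled_table():
    """A multi-shelled-style table whose signal lives in the 4.5 shell."""
    rng = np.random.default_rng(9)
    scheme = shell_scheme(6.0, 2.0)
    columns = [f"N;3;2;1;0-O;2;1;1;0-{b}" for b in ("2.5", "4.5", "6.0")]
    columns += [f"C;4;3;1;0-C;4;1;3;0-{b}" for b in ("2.5", "4.5", "6.0")]
    features = pd.DataFrame(rng.poisson(1.5, size=(220, 6)), columns=columns)
    pk = (1.5 * features["N;3;2;1;0-O;2;1;1;0-4.5"]
          + 0.8 * features["C;4;3;1;0-C;4;1;3;0-4.5"]
          + rng.normal(0, 0.3, 220))
    return features, pk, scheme


class TestPerShellAblation:
    def test_band_partition_covers_all_columns_once(self, shelled_table):
        features, pk, scheme = shelled_table
        result = per_shell_ablation(features, pk, scheme, LIGHT,
                                    n_folds=3, n_trials=1)
        assert int(result["n_features"].sum()) == features.shape[1]

    def test_signal_bearing_shell_wins(self, shelled_table):
        features, pk, scheme = shelled_table
        result = per_shell_ablation(features, pk, scheme, LIGHT,
                                    n_folds=3, n_trials=1)
        assert result["mean_pearson_r"].idxmax() == "4.5"

    def test_band_of_all_shells_equals_full_run(self, shelled_table):
        from msecif.model_training import cross_validate
        features, pk, scheme = shelled_table
        result = per_shell_ablation(features, pk, scheme, LIGHT,
                                    bands=[tuple(scheme.bounds)],
                                    n_folds=3, n_trials=1)
        full = cross_validate(features, pk, LIGHT, n_folds=3, n_trials=1)
        assert result["mean_pearson_r"].iloc[0] == pytest.approx(
            full["pearson_r"].mean())

    def test_empty_band_rejected(self, shelled_table):
        features, pk, scheme = shelled_table
        with pytest.raises(ValueError):
            per_shell_ablation(features, pk, scheme, LIGHT, bands=[()])


class TestCliffsDelta:
    def test_identical_samples_give_zero(self):
        assert cliffs_delta([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == \
            pytest.approx(0.0)

    def test_fully_separated_samples_give_unity(self):
        assert cliffs_delta([4.0, 5.0, 6.0], [1.0, 2.0, 3.0]) == \
            pytest.approx(1.0)
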