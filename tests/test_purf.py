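"""Weighted PU random forest: training, OOB scheme, G mean, grid search."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetprops import purf
from targetprops import synthetic_data as synth
from targetprops.purf import (
    ConfusionCounts,
    RFConfig,
    TrainingError,
    classify,
    confusion_from_predictions,
    full_similarity,
    grid_search,
    model_from_json,
    model_to_json,
    oob_similarity,
    permutation_importance,
    PUPrediction,
    similarity_histogram,
    train_forest,
)


class TestGMean:
    @pytest.mark.parametrize(
        "tp, fn, tn, fp, expected",
        [
            # Printed prediction tables: whole-proteome and protease runs.
            (1018, 306, 15021, 3898, 0.78),
            (52, 7, 419, 53, 0.88),
            (10, 0, 10, 0, 1.0),
            (0, 10, 10, 0, 0.0),
        ],
    )
    def test_geometric_mean_of_sensitivity_specificity(
        self, tp, fn, tn, fp, expected
    ):
        cc = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
        assert round(purf.g_mean(cc), 2) == expected

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fn=0, tn=5, fp=5).g_mean

    @given(st.integers(0, 500), st.integers(1, 500), st.integers(0, 500),
           st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_class_swap(self, tp, fn, tn, fp):
        forward = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp).g_mean
        swapped = ConfusionCounts(tp=tn, fn=fp, tn=tp, fp=fn).g_mean
        assert forward == pytest.approx(swapped)


class TestTraining:
    def test_same_seed_gives_identical_forest(self, moderate_table):
        config = RFConfig(number_trees=10, mtry=3, seed=99)
        a = train_forest(moderate_table.table, moderate_table.labels, config)
        b = train_forest(moderate_table.table, moderate_table.labels, config)
        assert model_to_json(a) == model_to_json(b)

    def test_different_seed_gives_different_forest(self, moderate_table):
        a = train_forest(moderate_table.table, moderate_table.labels,
                         RFConfig(number_trees=10, mtry=3, seed=1))
        b = train_forest(moderate_table.table, moderate_table.labels,
                         RFConfig(number_trees=10, mtry=3, seed=2))
        assert model_to_json(a) != model_to_json(b)

    def test_single_class_rejected(self, moderate_table):
        with pytest.raises(TrainingError):
            train_forest(moderate_table.table,
                         np.ones(len(moderate_table.table), dtype=int),
                         RFConfig(number_trees=5, mtry=2, seed=0))

    def test_mtry_exceeding_feature_count_rejected(self, moderate_table):
        with pytest.raises(TrainingError):
            train_forest(moderate_table.table, moderate_table.labels,
                         RFConfig(number_trees=5, mtry=999, seed=0))

    def test_separable_clusters_reach_high_oob_g_mean(self, separable_table):
        config = RFConfig(number_trees=100, mtry=3, seed=0)
        model = train_forest(separable_table.table, separable_table.labels,
                             config)
        cc = confusion_from_predictions(
            oob_similarity(model, separable_table.table),
            separable_table.labels,
        )
        assert cc.g_mean >= 0.9

    def test_label_permutation_yields_chance_level_g_mean(self):
        table = synth.gen_feature_table(synth.SyntheticTableConfig(
            n_pos=40, n_unl=40,
            features=[synth.FeatureSpec("sig", 0.9)],
            n_noise_features=4, seed=23,
        ))
        rng = np.random.default_rng(24)
        g_means = []
        for seed in range(10):
            permuted = rng.permutation(table.labels)
            model = train_forest(table.table, permuted,
                                 RFConfig(number_trees=60, mtry=2,
                                          seed=seed))
            cc = confusion_from_predictions(
                oob_similarity(model, table.table), permuted
            )
            g_means.append(cc.g_mean)
        assert 0.35 <= float(np.mean(g_means)) <= 0.65

    def test_model_json_roundtrip(self, moderate_table):
        config = RFConfig(number_trees=5, mtry=3, seed=4)
        model = train_forest(moderate_table.table, moderate_table.labels,
                             config)
        restored = model_from_json(model_to_json(model))
        same = full_similarity(restored, moderate_table.table)
        orig = full_similarity(model, moderate_table.table)
        assert [p.positive_similarity for p in same] == \
            [p.positive_similarity for p in orig]


class TestOOBScheme:
    def test_single_tree_inbag_observations_undefined(self, moderate_table):
        model = train_forest(moderate_table.table, moderate_table.labels,
                             RFConfig(number_trees=1, mtry=3, seed=5))
        predictions = oob_similarity(model, moderate_table.table)
        boot = set(model.bootstrap_indices[0].tolist())
        for i, pred in enumerate(predictions):
            if i in boot:
                assert not pred.defined
                assert pred.positive_similarity is None
            else:
                assert pred.eligible_trees == 1

    def test_oob_tree_fraction_near_inverse_e(self):
        table = synth.gen_feature_table(synth.SyntheticTableConfig(
            n_pos=50, n_unl=50, n_noise_features=2, seed=26,
        ))
        model = train_forest(table.table, table.labels,
                             RFConfig(number_trees=300, mtry=1, seed=6,
                                      min_node_size=100))
        predictions = oob_similarity(model, table.table)
        fraction = np.mean([p.eligible_trees for p in predictions]) / 300
        assert fraction == pytest.approx(math.exp(-1), abs=0.05)

    def test_vote_shares_form_a_probability(self, moderate_table):
        model = train_forest(moderate_table.table, moderate_table.labels,
                             RFConfig(number_trees=40, mtry=3, seed=7))
        for pred in oob_similarity(model, moderate_table.table):
            if pred.defined:
                assert 0.0 <= pred.positive_similarity <= 1.0
                pos_votes = pred.positive_similarity * pred.eligible_trees
                assert pos_votes == pytest.approx(round(pos_votes))

    def test_wrong_row_count_rejected(self, moderate_table):
        model = train_forest(moderate_table.table, moderate_table.labels,
                             RFConfig(number_trees=5, mtry=3, seed=8))
        with pytest.raises(ValueError):
            oob_similarity(model, moderate_table.table.iloc[:10])


class TestFullSimilarity:
    def test_single_tree_votes_are_binary(self, moderate_table):
        model = train_forest(moderate_table.table, moderate_table.labels,
                             RFConfig(number_trees=1, mtry=3, seed=9))
        for pred in full_similarity(model, moderate_table.table):
            assert pred.positive_similarity in (0.0, 1.0)

    def test_all_trees_always_eligible(self, moderate_table):
        model = train_forest(moderate_table.table, moderate_table.labels,
                             RFConfig(number_trees=7, mtry=3, seed=10))
        for pred in full_similarity(model, moderate_table.table):
            assert pred.eligible_trees == 7
            assert pred.mode == "full"

    def test_training_cluster_scored_toward_own_class(self, separable_table):
        model = train_forest(separable_table.table, separable_table.labels,
                             RFConfig(number_trees=60, mtry=3, seed=11))
        predictions = full_similarity(model, separable_table.table)
        sims = np.array([p.positive_similarity for p in predictions])
        assert sims[separable_table.labels == 1].mean() >= 0.9
        assert sims[separable_table.labels == 0].mean() <= 0.1

    def test_feature_count_mismatch_rejected(self, moderate_table):
        model = train_forest(moderate_table.table, moderate_table.labels,
                             RFConfig(number_trees=3, mtry=3, seed=12))
        with pytest.raises(ValueError):
            full_similarity(model, moderate_table.table.iloc[:, :4])


class TestClassify:
    @pytest.mark.parametrize(
        "similarity, expected",
        [(0.51, "positive"), (0.50, "unlabelled"), (0.49, "unlabelled")],
    )
    def test_strictly_above_cutoff(self, similarity, expected):
        pred = PUPrediction("A", similarity, 10, "positive", "oob")
        assert classify([pred], cutoff=0.5) == [expected]

    def test_undefined_similarity_called_unlabelled(self):
        pred = PUPrediction("A", None, 0, "unlabelled", "oob")
        assert classify([pred]) == ["unlabelled"]

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify([], cutoff=1.5)


class TestHistogram:
    def test_all_mass_in_first_bin(self):
        preds = [PUPrediction(str(i), 0.05, 10, "unlabelled", "oob")
                 for i in range(6)]
        hist = similarity_histogram(preds, [1, 1, 0, 0, 0, 0])
        assert hist["positive"].iloc[0] == 2
        assert hist["unlabelled"].iloc[0] == 4
        assert hist["positive"].iloc[1:].sum() == 0

    def test_totals_conserved(self, moderate_table):
        model = train_forest(moderate_table.table, moderate_table.labels,
                             RFConfig(number_trees=30, mtry=3, seed=13))
        preds = oob_similarity(model, moderate_table.table)
        hist = similarity_histogram(preds, moderate_table.labels)
        defined = sum(p.defined for p in preds)
        assert (hist["positive"].sum() + hist["unlabelled"].sum()) == defined

    def test_separable_positive_mass_in_top_bins(self, separable_table):
        model = train_forest(separable_table.table, separable_table.labels,
                             RFConfig(number_trees=60, mtry=3, seed=14))
        preds = oob_similarity(model, separable_table.table)
        hist = similarity_histogram(preds, separable_table.labels)
        top = hist["positive"].iloc[7:].sum()
        assert top >= 0.8 * hist["positive"].sum()


class TestWeighting:
    def test_higher_positive_weight_raises_sensitivity(self):
        table = synth.gen_feature_table(synth.SyntheticTableConfig(
            n_pos=25, n_unl=150,
            features=[synth.FeatureSpec(f"sig_{k}", 0.75) for k in range(3)],
            n_noise_features=5, seed=27,
        ))
        sensitivities = []
        for weight in (1.0, 2.0, 5.0, 10.0):
            model = train_forest(
                table.table, table.labels,
                RFConfig(number_trees=80, mtry=3, positive_weight=weight,
                         seed=15),
            )
            cc = confusion_from_predictions(
                oob_similarity(model, table.table), table.labels
            )
            sensitivities.append(cc.sensitivity)
        # Monotone trend: ends dominate, no strict per-step requirement.
        assert sensitivities[-1] > sensitivities[0]
        assert min(sensitivities[2:]) >= max(sensitivities[:2])

    def test_permutation_importance_ranks_informative_features(self):
        table = synth.gen_feature_table(synth.SyntheticTableConfig(
            n_pos=80, n_unl=80,
            features=[synth.FeatureSpec(f"sig_{k}", 0.8) for k in range(2)],
            n_noise_features=6, seed=28,
        ))
        model = train_forest(table.table, table.labels,
                             RFConfig(number_trees=60, mtry=3, seed=16))
        imp = permutation_importance(model, table.table, table.labels,
                                     seed=17)
        scores = imp.set_index("feature")["importance"]
        informative = scores[["sig_0", "sig_1"]].mean()
        noise = scores[[f"noise_{k}" for k in range(6)]].mean()
        assert informative > noise


class TestGridSearch:
    def test_singleton_grid_returns_that_combination(self, moderate_table):
        result = grid_search(
            moderate_table.table, moderate_table.labels,
            mtry_grid=[3], weight_grid=[2.0], n_forests=2,
            number_trees=20, seed_list=[1, 2],
        )
        assert result.best_mtry == 3
        assert result.best_weight == 2.0
        assert len(result.grid) == 1

    def test_identical_seed_lists_reproduce_grid_bitwise(self,
                                                         moderate_table):
        kwargs = dict(
            mtry_grid=[2, 3], weight_grid=[1.0, 3.0], n_forests=2,
            number_trees=15, seed_list=[11, 12],
        )
        a = grid_search(moderate_table.table, moderate_table.labels,
                        **kwargs)
        b = grid_search(moderate_table.table, moderate_table.labels,
                        **kwargs)
        pd.testing.assert_frame_equal(a.grid, b.grid)
        assert a.grid.to_csv() == b.grid.to_csv()

    def test_pooled_counts_scale_with_forest_count(self, moderate_table):
        result = grid_search(
            moderate_table.table, moderate_table.labels,
            mtry_grid=[3], weight_grid=[1.0], n_forests=3,
            number_trees=30, seed_list=[5, 6, 7],
        )
        row = result.grid.iloc[0]
        n_pos = int(moderate_table.labels.sum())
        # Every positive is OOB-defined at 30 trees in practice; pooled
        # positives can be at most n_forests * n_pos.
        assert row["TP"] + row["FN"] <= 3 * n_pos
        assert row["TP"] + row["FN"] >= 3 * n_pos * 0.95

    def test_seed_list_length_must_match(self, moderate_table):
        with pytest.raises(TrainingError):
            grid_search(moderate_table.table, moderate_table.labels,
                        mtry_grid=[2], weight_grid=[1.0], n_forests=3,
                        number_trees=5, seed_list=[1])

    def test_empty_grid_rejected(self, moderate_table):
        with pytest.raises(TrainingError):
            grid_search(moderate_table.table, moderate_table.labels,
                        mtry_grid=[], weight_grid=[1.0], n_forests=1,
                        number_trees=5, seed_list=[1])
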