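import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncsig import (
    ValidationError,
    WeightedVotingModel,
    predict,
    predict_samples,
    restrict_model,
    roc_auc,
    snr,
    train,
)
from lncsig.voting import vote_components
from _oracles import vote_oracle


def make_model(weights, boundaries, majority="GCB"):
    stats = pd.DataFrame(
        {
            "mu_abc": np.zeros(len(weights)),
            "mu_gcb": np.zeros(len(weights)),
            "sigma_abc": np.ones(len(weights)),
            "sigma_gcb": np.ones(len(weights)),
            "w": weights,
            "b": boundaries,
        },
        index=[f"g{i}" for i in range(len(weights))],
    )
    return WeightedVotingModel(stats=stats, majority_class=majority)


class TestSNR:
    def test_direct_substitution(self):
        assert snr(1.0, 0.0, 0.5, 0.5, mode="sum") == pytest.approx(1.0)

    def test_equal_means_give_zero_in_both_modes(self):
        assert snr(2.0, 2.0, 0.5, 0.3, mode="sum") == 0.0
        assert snr(2.0, 2.0, 0.5, 0.3, mode="difference") == 0.0

    def test_class_swap_negates(self):
        assert snr(1.0, 0.2, 0.4, 0.6) == pytest.approx(-snr(0.2, 1.0, 0.6, 0.4))

    def test_difference_mode_uses_printed_denominator(self):
        assert snr(1.0, 0.0, 0.75, 0.25, mode="difference") == pytest.approx(2.0)

    def test_zero_denominator_flagged_nan(self):
        assert np.isnan(snr(1.0, 0.0, 0.5, 0.5, mode="difference"))
        assert np.isnan(snr(1.0, 0.0, 0.0, 0.0, mode="sum"))


class TestTrain:
    def test_hand_computed_single_gene(self):
        matrix = pd.DataFrame([[1.0, 3.0, -1.0, -3.0]], index=["g"],
                              columns=["a1", "a2", "g1", "g2"])
        labels = pd.Series(["ABC", "ABC", "GCB", "GCB"], index=matrix.columns)
        model = train(matrix, labels)
        row = model.stats.loc["g"]
        assert row["mu_abc"] == pytest.approx(2.0)
        assert row["mu_gcb"] == pytest.approx(-2.0)
        assert row["sigma_abc"] == pytest.approx(math.sqrt(2))
        assert row["w"] == pytest.approx(4 / (2 * math.sqrt(2)))
        assert row["b"] == pytest.approx(0.0)

    def test_degenerate_gene_dropped_then_empty_set_errors(self):
        matrix = pd.DataFrame([[2.0, 2.0, 0.0, 0.0]], index=["g"],
                              columns=["a1", "a2", "g1", "g2"])
        labels = pd.Series(["ABC", "ABC", "GCB", "GCB"], index=matrix.columns)
        with pytest.raises(ValidationError, match="no usable genes"):
            train(matrix, labels)

    def test_identical_genes_get_identical_weights(self, separable_cohort):
        c = separable_cohort
        matrix = c.lnc_matrix.iloc[:1]
        twin = pd.concat([matrix, matrix.rename(index={matrix.index[0]: "twin"})])
        model = train(twin, c.annotation["subtype"])
        assert model.stats.iloc[0]["w"] == pytest.approx(model.stats.iloc[1]["w"])


class TestPredict:
    def test_single_positive_gene(self):
        model = make_model([1.0], [0.0])
        res = predict(model, {"g0": 2.0})
        assert (res.v_abc, res.v_gcb, res.predicted) == (2.0, 0.0, "ABC")
        assert res.score == pytest.approx(1.0)

    def test_symmetric_negative_expression(self):
        model = make_model([1.0], [0.0])
        res = predict(model, {"g0": -1.0})
        assert (res.v_gcb, res.predicted) == (1.0, "GCB")
        assert res.score == pytest.approx(-1.0)

    def test_gene_on_its_boundary_votes_zero(self):
        model = make_model([1.0, -0.5], [0.0, 1.0])
        res = predict(model, {"g0": 1.0, "g1": 1.0})
        assert (res.v_abc, res.v_gcb, res.predicted) == (1.0, 0.0, "ABC")

    def test_score_and_prob_consistent(self):
        model = make_model([1.0, -2.0], [0.0, 0.5])
        res = predict(model, {"g0": 0.7, "g1": 1.5})
        assert res.score == pytest.approx(2 * res.prob_abc - 1)

    def test_missing_gene_directs_to_restrict(self):
        model = make_model([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValidationError, match="restrict_model"):
            predict(model, {"g0": 1.0})

    def test_tie_goes_to_majority_class(self):
        model = make_model([1.0, -1.0], [0.0, 0.0], majority="ABC")
        res = predict(model, {"g0": 1.0, "g1": 1.0})
        assert res.v_abc == res.v_gcb
        assert res.predicted == "ABC"

    @given(
        st.integers(1, 5).flatmap(
            lambda k: st.tuples(
                st.lists(st.floats(-3, 3).filter(lambda v: abs(v) > 1e-6),
                         min_size=k, max_size=k),
                st.lists(st.floats(-3, 3), min_size=k, max_size=k),
                st.lists(st.floats(-3, 3), min_size=k, max_size=k),
            )
        )
    )
    def test_agrees_with_per_gene_tabulation_oracle(self, case):
        weights, boundaries, expression = case
        model = make_model(weights, boundaries)
        res = predict(model, dict(zip(model.gene_ids, expression)))
        v_abc, v_gcb, predicted = vote_oracle(weights, boundaries, expression)
        assert res.v_abc == pytest.approx(v_abc, abs=1e-9)
        assert res.v_gcb == pytest.approx(v_gcb, abs=1e-9)
        if abs(v_abc - v_gcb) > 1e-9:  # away from the tie boundary
            assert res.predicted == predicted


class TestRestrictModel:
    def test_restrict_to_all_is_identity(self):
        model = make_model([1.0, 2.0], [0.0, 0.5])
        restricted = restrict_model(model, model.gene_ids)
        assert restricted.stats.equals(model.stats)

    def test_subset_keeps_parameters_verbatim(self):
        model = make_model(list(np.linspace(-1, 1, 17)), list(np.linspace(0, 1, 17)))
        nine = model.gene_ids[:9]
        restricted = restrict_model(model, nine)
        assert len(restricted) == 9
        assert restricted.stats.equals(model.stats.loc[nine])

    def test_restriction_composes_as_intersection(self):
        model = make_model([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        a, b = ["g0", "g1"], ["g1", "g2"]
        twice = restrict_model(restrict_model(model, a), b)
        once = restrict_model(model, ["g1"])
        assert twice.stats.equals(once.stats)

    def test_empty_intersection_errors(self):
        model = make_model([1.0], [0.0])
        with pytest.raises(ValidationError, match="no overlap"):
            restrict_model(model, ["nope"])


class TestModelProperties:
    def test_global_affine_transform_preserves_predictions(self, separable_cohort):
        c = separable_cohort
        labels = c.annotation["subtype"]
        genes = c.truth_gene_ids[:10]
        model = train(c.lnc_matrix, labels, genes=genes)
        preds = predict_samples(model, c.lnc_matrix.loc[genes])
        transformed = 2.5 * c.lnc_matrix + 7.0
        model_t = train(transformed, labels, genes=genes)
        preds_t = predict_samples(model_t, transformed.loc[genes])
        assert (preds["predicted"] == preds_t["predicted"]).all()
        # weights are scale-free, votes scale by a
        assert np.allclose(preds_t["v_abc"], 2.5 * preds["v_abc"])

    def test_label_swap_swaps_vote_totals(self, separable_cohort):
        c = separable_cohort
        labels = c.annotation["subtype"]
        genes = c.truth_gene_ids[:8]
        model = train(c.lnc_matrix, labels, genes=genes)
        swapped = train(c.lnc_matrix, labels.map({"ABC": "GCB", "GCB": "ABC"}), genes=genes)
        p1 = predict_samples(model, c.lnc_matrix)
        p2 = predict_samples(swapped, c.lnc_matrix)
        assert np.allclose(p1["v_abc"], p2["v_gcb"])
        assert (p1["predicted"].map({"ABC": "GCB", "GCB": "ABC"}) == p2["predicted"]).all()

    def test_training_accuracy_on_separated_data(self, separable_cohort):
        c = separable_cohort
        labels = c.annotation["subtype"]
        model = train(c.lnc_matrix, labels, genes=c.truth_gene_ids)
        preds = predict_samples(model, c.lnc_matrix)
        assert (preds["predicted"] == labels).mean() == 1.0

    def test_json_roundtrip(self, tmp_path, separable_cohort):
        c = separable_cohort
        model = train(c.lnc_matrix, c.annotation["subtype"], genes=c.truth_gene_ids[:5])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = WeightedVotingModel.from_json(path)
        assert back.mode == model.mode
        assert np.allclose(back.stats.to_numpy(), model.stats.to_numpy())
        p1 = predict_samples(model, c.lnc_matrix)
        p2 = predict_samples(back, c.lnc_matrix)
        assert (p1["predicted"] == p2["predicted"]).all()
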