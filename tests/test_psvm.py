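"""Binary vote vectors, rank-weighted signature vectors and
nearest-reference matching."""

import numpy as np
import pytest

from prognosig import (
    PSV,
    RiskClass,
    build_pbvv,
    build_reference_psvs,
    compute_weights,
    match_nearest,
    pbvv_to_psv,
    planted_ddg_models,
    predict_psvm,
    rank_scores,
    simulate_cohort,
    three_class_spec,
)
from prognosig.io import signature_to_models
from prognosig.psvm import PBVV
from prognosig.swvg import SwvgModel, assign_risk_class, fit_awr_thresholds, risk_calls_matrix


def _weights(values, scheme="C"):
    return compute_weights(np.asarray(values), np.ones(len(values)), scheme)


class TestBuildPbvv:
    def test_reference_signature_age_call(self, table1):
        models = signature_to_models(table1)
        i = [m.variable_id for m in models].index("age")
        values = table1["cutoff"].to_numpy() - 0.5  # just below each cutoff
        values[i] = 70.0
        pbvv = build_pbvv(models, values, "patient-x")
        assert pbvv.bits[i] == 1

    def test_all_low_values_all_design2_gives_zero_vector(self):
        spec = three_class_spec(1, n_patients=10, n_variables=5)
        cohort = simulate_cohort(spec)
        models = planted_ddg_models(spec, cohort)
        assert all(m.design == 2 for m in models)
        pbvv = build_pbvv(models, np.full(5, -100.0))
        assert not pbvv.bits.any()

    def test_missing_value_errors_unless_imputed(self, table1):
        models = signature_to_models(table1)[:3]
        vals = np.array([np.nan, 5.0, 5.0])
        with pytest.raises(ValueError, match="missing"):
            build_pbvv(models, vals)
        medians = np.array([1.0, 1.0, 1.0])
        pbvv = build_pbvv(models, vals, impute=medians)
        assert pbvv.bits.size == 3


class TestPsvTransform:
    def test_all_zero_pbvv_gives_zero_psv(self):
        w = _weights([0.01, 0.02, 0.03])
        psv = pbvv_to_psv(PBVV("q", np.zeros(3, dtype=int)), w)
        assert not psv.components.any()

    def test_reverse_rank_definition(self):
        # weights (0.5, 0.3, 0.2) -> ranks 1,2,3 -> scores 3,2,1
        w = _weights([0.001, 0.01, 0.1], scheme="B")
        assert w.weights[0] > w.weights[1] > w.weights[2]
        psv = pbvv_to_psv(PBVV("q", np.ones(3, dtype=int)), w)
        assert np.array_equal(psv.components, [3.0, 2.0, 1.0])

    def test_rank_then_mask(self):
        w = _weights([0.1, 0.001, 0.01], scheme="B")  # ranks: 3,1,2 -> scores 1,3,2
        psv = pbvv_to_psv(PBVV("q", np.array([0, 1, 1])), w)
        assert np.array_equal(psv.components, [0.0, 3.0, 2.0])

    def test_components_are_integers_up_to_n(self):
        rng = np.random.default_rng(8)
        w = _weights(rng.uniform(1e-4, 0.5, 12))
        bits = rng.integers(0, 2, 12)
        psv = pbvv_to_psv(PBVV("q", bits), w)
        assert np.array_equal(psv.components, np.round(psv.components))
        assert psv.components.max() <= 12
        assert psv.un_scaled

    def test_equal_weights_tie_broken_by_signature_order(self):
        w = compute_weights(np.full(4, 0.01), np.ones(4), "A")
        assert np.array_equal(rank_scores(w), [4.0, 3.0, 2.0, 1.0])


class TestMatchNearest:
    def test_exact_match_distance_zero(self):
        refs = [PSV("a", np.array([0.0, 3.0, 2.0])), PSV("b", np.array([3.0, 2.0, 1.0]))]
        classes = [RiskClass.HIGH, RiskClass.LOW]
        m = match_nearest(PSV("q", np.array([0.0, 3.0, 2.0])), refs, classes)
        assert (m.reference_id, m.distance, m.predicted_class) == ("a", 0.0, RiskClass.HIGH)

    def test_equals_all_pairs_scan(self):
        rng = np.random.default_rng(13)
        n_ref, n_query, p = 200, 50, 10
        refs = [PSV(f"r{i}", rng.integers(0, p + 1, p).astype(float)) for i in range(n_ref)]
        classes = [RiskClass(int(c)) for c in rng.integers(0, 3, n_ref)]
        for j in range(n_query):
            q = PSV(f"q{j}", rng.integers(0, p + 1, p).astype(float))
            m = match_nearest(q, refs, classes)
            dists = np.array(
                [np.sqrt(np.sum((r.components - q.components) ** 2)) for r in refs]
            )
            assert m.distance == pytest.approx(dists.min())
            assert np.isclose(dists[[r.patient_id for r in refs].index(m.reference_id)], dists.min())

    def test_tie_majority_then_lowest_risk(self):
        refs = [
            PSV("a", np.array([1.0, 0.0])),
            PSV("b", np.array([0.0, 1.0])),
            PSV("c", np.array([0.0, 1.0])),
        ]
        q = PSV("q", np.array([0.5, 0.5]))  # equidistant from all three
        m = match_nearest(q, refs, [RiskClass.HIGH, RiskClass.LOW, RiskClass.LOW])
        assert m.predicted_class is RiskClass.LOW  # majority among tied
        m2 = match_nearest(
            PSV("q", np.array([0.5, 0.5])),
            refs[:2],
            [RiskClass.HIGH, RiskClass.LOW],
        )
        assert m2.predicted_class is RiskClass.LOW  # residual tie -> lowest risk

    def test_empty_references_error(self):
        with pytest.raises(ValueError):
            match_nearest(PSV("q", np.array([1.0])), [], [])


@pytest.fixture(scope="module")
def trained():
    spec = three_class_spec(seed=31)
    cohort = simulate_cohort(spec)
    models = planted_ddg_models(spec, cohort)
    wv = compute_weights(
        np.array([m.wald_p for m in models]),
        np.array([m.hazard_ratio for m in models]),
        "C",
        variable_ids=tuple(m.variable_id for m in models),
    )
    calls = risk_calls_matrix(models, cohort.expression)
    awr = calls @ wv.weights
    t_low, t_high, res = fit_awr_thresholds(awr, cohort.survival, 0.10)
    model = SwvgModel(models, wv, t_low, t_high, res)
    classes = [assign_risk_class(a, model) for a in awr]
    refs = build_reference_psvs(model, cohort.expression)
    return spec, cohort, model, refs, classes


class TestPredictPsvm:
    def test_training_patient_self_matches_to_own_class(self, trained):
        _, cohort, model, refs, classes = trained
        for j in [0, 57, 113, 299]:
            m = predict_psvm(
                cohort.expression.iloc[:, j].to_numpy(), model, refs, classes,
                query_id=cohort.survival.ids[j],
            )
            assert m.distance == 0.0
            assert m.predicted_class is classes[j]

    def test_planted_class_agreement_on_held_out_cohort(self, trained):
        spec, _, model, refs, classes = trained
        test = simulate_cohort(three_class_spec(seed=spec.seed + 1, n_patients=150))
        preds = [
            predict_psvm(test.expression[c].to_numpy(), model, refs, classes, query_id=c)
            for c in test.expression.columns
        ]
        agree = np.mean([int(m.predicted_class) for m in preds] == test.classes)
        assert agree >= 0.80

    def test_variable_permutation_invariance(self, trained):
        _, cohort, model, refs, classes = trained
        perm = np.random.default_rng(1).permutation(len(model.ddg_models))
        model_p = SwvgModel(
            tuple(model.ddg_models[i] for i in perm),
            compute_weights(
                np.array([model.ddg_models[i].wald_p for i in perm]),
                np.array([model.ddg_models[i].hazard_ratio for i in perm]),
                "C",
                variable_ids=tuple(model.ddg_models[i].variable_id for i in perm),
            ),
            model.t_low,
            model.t_high,
            model.training_logrank,
        )
        refs_p = build_reference_psvs(model_p, cohort.expression)
        q = simulate_cohort(three_class_spec(seed=99, n_patients=5)).expression
        for c in q.columns:
            a = predict_psvm(q[c].to_numpy(), model, refs, classes, query_id=c)
            b = predict_psvm(q[c].to_numpy()[perm], model_p, refs_p, classes, query_id=c)
            assert a.distance == pytest.approx(b.distance)
            assert a.predicted_class is b.predicted_class

    def test_adding_high_rank_bit_moves_away_from_zero_reference(self):
        w = _weights([0.001, 0.01, 0.1], scheme="B")
        zero_ref = [PSV("z", np.zeros(3))]
        base = match_nearest(pbvv_to_psv(PBVV("q", np.array([0, 0, 1])), w), zero_ref, [RiskClass.LOW])
        more = match_nearest(pbvv_to_psv(PBVV("q", np.array([1, 0, 1])), w), zero_ref, [RiskClass.LOW])
        assert more.distance > base.distance

    def test_zero_query_matches_zero_low_risk_reference(self, trained):
        _, _, model, _, _ = trained
        n = len(model.ddg_models)
        refs = [PSV("zero", np.zeros(n)), PSV("other", np.full(n, 2.0))]
        m = predict_psvm(
            np.full(n, -100.0), model, refs, [RiskClass.LOW, RiskClass.HIGH]
        )
        assert (m.reference_id, m.predicted_class) == ("zero", RiskClass.LOW)
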