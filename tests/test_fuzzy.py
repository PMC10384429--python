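"""Takagi-Sugeno engine: membership algebra, inference, ANFIS fitting."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lycosense import (
    RuleCoverageError,
    TakagiSugenoModel,
    TriangularMF,
    build_default_model,
    fit_anfis,
    fit_consequents,
    generate_feature_table,
    membership,
    predict,
    r_squared,
    rule_strengths,
)
from lycosense.fuzzy import A_DOMAIN, B_DOMAIN, L_DOMAIN, build_default_variables


def _planted_model(seed=7, low=0.0, high=0.05):
    rng = np.random.default_rng(seed)
    base = build_default_model()
    rules = tuple(
        replace(r, coeffs=tuple(rng.uniform(low, high, 3)), intercept=float(rng.uniform(0, 20)))
        for r in base.rules
    )
    return replace(base, rules=rules)


def _table_from(model, n, seed):
    law = lambda L, a, b: predict(model, np.column_stack([L, a, b]))
    return generate_feature_table(n, seed=seed, noise_sd=0.0, law=law)


class TestMembership:
    def test_low_a_near_zero_is_one(self):
        low_a = build_default_variables()[1].mfs[0]
        assert membership(low_a, 1e-9) == pytest.approx(1.0, abs=1e-9)

    def test_a_boundary_at_753(self):
        _, a_var, _ = build_default_variables()
        low, med, high = a_var.mfs
        assert membership(med, 753.0) == 1.0
        assert membership(high, 753.0) == 0.0
        assert membership(low, 753.0) == 0.0

    def test_low_b_clips_to_one_below_210(self):
        b_var = build_default_variables()[2]
        low_b = b_var.mfs[0]
        # raw line (358 - b)/148 = 3.838 at b = -210; degree must clip to 1
        assert membership(low_b, -210.0 + 1e-9) == 1.0
        assert membership(low_b, 250.0) == pytest.approx((358 - 250) / 148)

    def test_outside_domain_is_zero(self):
        L_var = build_default_variables()[0]
        for mf in L_var.mfs:
            assert membership(mf, -1.0) == 0.0
            assert membership(mf, 3000.0) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-500, 3000, allow_nan=False))
    def test_degrees_always_in_unit_interval(self, x):
        for var in build_default_variables():
            for mf in var.mfs:
                assert 0.0 <= membership(mf, x) <= 1.0

    def test_degenerate_mf_rejected(self):
        with pytest.raises(ValueError):
            TriangularMF("bad", 1.0, 1.0, 1.0, (0.0, 2.0))
        with pytest.raises(ValueError):
            TriangularMF("bad", 2.0, 1.0, 3.0, (0.0, 4.0))


class TestPartitionOfUnity:
    def test_a_and_b_neighbours_sum_to_one_exactly(self):
        _, a_var, b_var = build_default_variables()
        low_a, med_a, high_a = a_var.mfs
        low_b, high_b = b_var.mfs
        a1 = np.linspace(1e-9, 753.0, 10_000)
        assert np.max(np.abs(low_a(a1) + med_a(a1) - 1.0)) < 1e-12
        a2 = np.linspace(753.0 + 1e-9, 1736.0, 10_000)
        assert np.max(np.abs(med_a(a2) + high_a(a2) - 1.0)) < 1e-12
        b = np.linspace(210.0, 358.0, 10_000)
        assert np.max(np.abs(low_b(b) + high_b(b) - 1.0)) < 1e-12

    def test_every_domain_point_covered_by_some_mf(self):
        for var, dom in zip(build_default_variables(), (L_DOMAIN, A_DOMAIN, B_DOMAIN)):
            xs = np.linspace(dom[0] + 1e-6, dom[1], 2000)
            total = sum(mf(xs) for mf in var.mfs)
            assert np.all(total > 0)


class TestModelStructure:
    def test_default_model_has_8_mfs_and_18_rules(self):
        m = build_default_model()
        assert m.n_membership_functions == 8
        assert m.n_rules == 18
        assert m.n_rules == np.prod([len(v.mfs) for v in m.variables])

    def test_rule_antecedents_cover_full_grid_uniquely(self):
        m = build_default_model()
        assert len({r.antecedent for r in m.rules}) == 18

    def test_json_round_trip_is_identical(self, tmp_path):
        m = fit_consequents(_planted_model(), *_xy(_table_from(_planted_model(), 80, 3)))
        p = tmp_path / "model.json"
        m.to_json(p)
        m2 = TakagiSugenoModel.from_json(p)
        assert m2 == replace(m, fit_report=None)
        # round trip again: serialization is stable byte-for-byte
        p2 = tmp_path / "model2.json"
        m2.to_json(p2)
        assert p.read_text() == p2.read_text()


def _xy(tab):
    return tab[["L_feat", "a_feat", "b_feat"]].to_numpy(), tab["lycopene_ppm"].to_numpy()


class TestRuleStrengths:
    def test_crisp_corner_fires_exactly_one_rule(self):
        m = build_default_model()
        w = rule_strengths(m, np.array([2558.3, 1736.0, 358.0]))
        assert np.sum(w == 1.0) == 1
        assert np.sum(w) == 1.0

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        m = build_default_model()
        X = np.column_stack(
            [
                rng.uniform(1, 2558.3, 20),
                rng.uniform(1, 1736, 20),
                rng.uniform(-209, 358, 20),
            ]
        )
        W = rule_strengths(m, X)
        for k in range(20):
            degs = [var.degrees(X[k, j]) for j, var in enumerate(m.variables)]
            for i, rule in enumerate(m.rules):
                expect = np.prod([degs[j][idx] for j, idx in enumerate(rule.antecedent)])
                assert W[k, i] == pytest.approx(expect, abs=1e-14)

    def test_min_tnorm_variant(self, rng):
        m = build_default_model(t_norm="min")
        x = np.array([400.0, 900.0, 100.0])
        W = rule_strengths(m, x)
        degs = [var.degrees(x[j]) for j, var in enumerate(m.variables)]
        for i, rule in enumerate(m.rules):
            assert W[i] == pytest.approx(min(degs[j][idx] for j, idx in enumerate(rule.antecedent)))

    def test_outside_all_supports_gives_zero_strengths(self):
        m = build_default_model()
        assert np.all(rule_strengths(m, np.array([-5.0, -5.0, 400.0])) == 0.0)


class TestPredict:
    def test_single_firing_rule_returns_its_output_level(self):
        m = build_default_model(order="zero")
        rules = list(m.rules)
        # crisp corner (L=2558.3, a=1736, b=358) fires only rule (High, High, High)
        idx = [r.antecedent for r in rules].index((2, 2, 1))
        rules[idx] = replace(rules[idx], intercept=42.0)
        m = replace(m, rules=tuple(rules))
        assert predict(m, np.array([2558.3, 1736.0, 358.0])) == pytest.approx(42.0)

    def test_two_equal_weights_average_symmetrically(self):
        # hand-built single-variable zero-order system: w = (0.5, 0.5), Z = (0, 10)
        var = build_default_variables()[2]  # b: Low/High partition of unity
        m = TakagiSugenoModel(
            variables=(var,),
            rules=(
                # membership crossover Low_b = High_b = 0.5 at b = 284
                replace_rule_1d(0, 0.0),
                replace_rule_1d(1, 10.0),
            ),
            order="zero",
        )
        assert predict(m, np.array([284.0])) == pytest.approx(5.0)

    def test_no_coverage_raises_explicit_error(self):
        m = build_default_model()
        with pytest.raises(RuleCoverageError, match="outside rule coverage"):
            predict(m, np.array([-5.0, -5.0, 400.0]))

    def test_zero_order_output_is_convex_combination(self, rng):
        m = _planted_model(seed=3)
        m = replace(
            m,
            order="zero",
            rules=tuple(replace(r, coeffs=(0.0, 0.0, 0.0)) for r in m.rules),
        )
        Z = np.array([r.intercept for r in m.rules])
        X = np.column_stack(
            [rng.uniform(1, 2558.3, 500), rng.uniform(1, 1736, 500), rng.uniform(-209, 358, 500)]
        )
        out = predict(m, X)
        assert np.all(out >= Z.min() - 1e-9) and np.all(out <= Z.max() + 1e-9)

    def test_continuity_under_small_perturbation(self, rng):
        m = fit_consequents(build_default_model(), *_xy(generate_feature_table(60, seed=5)))
        X = np.column_stack(
            [rng.uniform(100, 2400, 200), rng.uniform(50, 1700, 200), rng.uniform(-180, 350, 200)]
        )
        step = 1e-4
        out0 = predict(m, X)
        out1 = predict(m, X + step)
        assert np.max(np.abs(out1 - out0)) < 1.0  # no jumps from a 1e-4 nudge


def replace_rule_1d(mf_idx, z):
    from lycosense import FuzzyRule

    return FuzzyRule(antecedent=(mf_idx,), coeffs=(0.0,), intercept=z)


class TestFitConsequents:
    def test_planted_model_recovered_to_1e8(self):
        planted = _planted_model(seed=11)
        tab = _table_from(planted, 100, seed=21)
        X, y = _xy(tab)
        fitted = fit_consequents(build_default_model(), X, y)
        pred = predict(fitted, X)
        assert np.max(np.abs(pred - y)) < 1e-8

    def test_constant_target_reproduced(self):
        tab = generate_feature_table(40, seed=2)
        X, _ = _xy(tab)
        y = np.full(40, 7.25)
        fitted = fit_consequents(build_default_model(), X, y)
        np.testing.assert_allclose(predict(fitted, X), 7.25, atol=1e-9)

    def test_underdetermined_fit_is_minimum_norm_with_zero_residual(self):
        planted = _planted_model(seed=4)
        tab = _table_from(planted, 30, seed=8)  # 30 samples < 72 parameters
        X, y = _xy(tab)
        fitted = fit_consequents(build_default_model(), X, y)
        assert fitted.fit_report["residual_norm"] < 1e-8
        # oracle: pseudo-inverse solution on the same design matrix
        from lycosense.fuzzy import _design_matrix

        W = rule_strengths(build_default_model(), X)
        A = _design_matrix(build_default_model(), X, W)
        theta_star = np.linalg.pinv(A) @ y
        theta_fit = np.concatenate([list(r.coeffs) + [r.intercept] for r in fitted.rules])
        np.testing.assert_allclose(theta_fit, theta_star, atol=1e-6)

    def test_beats_any_constant_predictor(self):
        tab = generate_feature_table(120, seed=9)
        X, y = _xy(tab)
        fitted = fit_consequents(build_default_model(), X, y)
        resid = predict(fitted, X) - y
        const_resid = y - y.mean()
        assert np.sum(resid**2) <= np.sum(const_resid**2) + 1e-9

    def test_non_firing_samples_rejected_with_warning(self):
        X = np.array([[100.0, 100.0, 100.0], [-5.0, -5.0, 400.0], [500.0, 700.0, 200.0]])
        y = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="fire no rule"):
            fitted = fit_consequents(build_default_model(), X, y)
        assert fitted.fit_report["n_samples"] == 2
        assert fitted.fit_report["n_rejected"] == 1

    def test_premise_tuning_never_worsens_training_mse(self):
        tab = generate_feature_table(80, seed=13)
        X, y = _xy(tab)
        base = fit_consequents(build_default_model(), X, y)
        tuned = fit_anfis(build_default_model(), X, y, epochs=3, learn_premises=True)
        assert tuned.fit_report["training_mse"] <= base.fit_report["training_mse"] + 1e-12
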