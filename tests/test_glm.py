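"""Normative GLM: design construction, OLS fit, prediction, deviation maps."""

import numpy as np
import pytest

from deviate.errors import DataError
from deviate.glm import (
    build_design,
    design_row,
    fit_normative,
    load_model,
    predict_case,
    region_summary,
    save_model,
    studentized_residual,
)
from deviate.mesh import VertexMap, vertex_areas
from deviate.synthetic import default_truth, generate_cohort, generate_thickness
from deviate.validation import _ols_oracle, null_deviation_variance


class TestDesign:
    def test_centering_zeroes_age_terms(self):
        assert np.array_equal(design_row(43, 0, 0, 43), [1, 0, 0, 0, 0])

    def test_interaction_arithmetic(self):
        assert np.array_equal(design_row(53, 1, 1, 43), [1, 10, 1, 10, 1])

    def test_case_ages_centered_on_middle_case(self):
        # the three case ages, centred on the middle one
        import pandas as pd

        cohort = pd.DataFrame(
            {"age": [43.0, 49.0, 54.0], "sex": [0, 1, 1], "handedness": [0, 0, 1]}
        )
        d = build_design(cohort, center_age=49.0)
        assert np.array_equal(d.X[:, 1], [-6.0, 0.0, 5.0])

    def test_centered_age_column_mean(self):
        cohort = generate_cohort(n=80, seed=1)
        d = build_design(cohort, center_age=49.0)
        assert np.isclose(d.X[:, 1].mean(), cohort["age"].mean() - 49.0, atol=1e-10)
        assert (d.X[:, 0] == 1).all()

    def test_single_sex_cohort_warns_rank_deficient(self):
        cohort = generate_cohort(n=30, p_female=1.0, seed=2)
        with pytest.warns(UserWarning, match="rank deficient"):
            d = build_design(cohort, 50.0)
        assert d.rank < 5


class TestFit:
    def test_matches_normal_equations_oracle(self, rng):
        cohort = generate_cohort(n=40, seed=7)
        design = build_design(cohort, 43.0)
        Y = 2.5 + 0.3 * rng.standard_normal((40, 10))
        model = fit_normative(Y, design)
        coef_o, sd_o = _ols_oracle(design.X, Y, design.rank)
        assert np.allclose(model.coef, coef_o, rtol=1e-8)
        assert np.allclose(model.resid_sd, sd_o, rtol=1e-8)

    def test_noise_free_fit_recovers_truth(self, ico2):
        truth = default_truth(ico2, center_age=43.0, sigma=0.0, seed=5)
        cohort = generate_cohort(n=30, seed=5)
        stack = generate_thickness(ico2, cohort, truth)
        model = fit_normative(stack, build_design(cohort, 43.0))
        assert np.allclose(model.coef, truth.coef, atol=1e-8)
        assert np.allclose(model.resid_sd, 0.0, atol=1e-8)

    def test_constant_data(self):
        cohort = generate_cohort(n=20, seed=3)
        design = build_design(cohort, 43.0)
        model = fit_normative(np.full((20, 4), 2.5), design)
        assert np.allclose(model.coef[0], 2.5)
        assert np.allclose(model.coef[1:], 0.0, atol=1e-10)
        assert np.allclose(model.resid_sd, 0.0, atol=1e-10)

    def test_nonfinite_value_named(self):
        cohort = generate_cohort(n=10, seed=1)
        design = build_design(cohort, 43.0)
        Y = np.ones((10, 3))
        Y[4, 2] = np.nan
        with pytest.raises(DataError, match="subject 4 at vertex 2"):
            fit_normative(Y, design)

    def test_dof_is_n_minus_rank(self):
        cohort = generate_cohort(n=60, seed=8)
        design = build_design(cohort, 43.0)
        model = fit_normative(np.random.default_rng(0).normal(2.5, 0.2, (60, 5)), design)
        assert model.dof == 60 - design.rank

    def test_constant_shift_moves_only_intercept(self, ico2, rng):
        truth = default_truth(ico2, seed=6)
        cohort = generate_cohort(n=25, seed=6)
        stack = generate_thickness(ico2, cohort, truth)
        design = build_design(cohort, 43.0)
        m0 = fit_normative(stack, design)
        m1 = fit_normative(stack + 0.37, design)
        assert np.allclose(m1.coef[0] - m0.coef[0], 0.37, atol=1e-10)
        assert np.allclose(m1.coef[1:], m0.coef[1:], atol=1e-10)
        case = {"age": 43.0, "sex": 0, "handedness": 0}
        actual = VertexMap(stack[0], kind="thickness")
        actual1 = VertexMap(stack[0] + 0.37, kind="thickness")
        d0 = studentized_residual(actual, predict_case(m0, case), m0)
        d1 = studentized_residual(actual1, predict_case(m1, case), m1)
        assert np.allclose(d0.values, d1.values, atol=1e-8, equal_nan=True)


class TestPredict:
    def test_noise_free_interpolation_of_training_control(self, ico2):
        truth = default_truth(ico2, center_age=50.0, sigma=0.0, seed=7)
        cohort = generate_cohort(n=30, seed=7)
        stack = generate_thickness(ico2, cohort, truth)
        model = fit_normative(stack, build_design(cohort, 50.0))
        row = cohort.iloc[3]
        with pytest.warns(UserWarning, match="centring age"):
            pred = predict_case(
                model, {"age": row.age, "sex": row.sex, "handedness": row.handedness}
            )
        assert np.allclose(pred.values, stack[3], atol=1e-8)

    def test_intercept_only_model(self):
        from deviate.glm import NormativeModel

        coef = np.zeros((5, 6))
        coef[0] = 2.33
        model = NormativeModel(coef=coef, resid_sd=np.full(6, 0.2), dof=100, rank=5,
                               center_age=43.0)
        pred = predict_case(model, {"age": 43.0, "sex": 1, "handedness": 1})
        assert np.allclose(pred.values, 2.33)

    def test_named_covariates_use_model_coding(self):
        from deviate.glm import NormativeModel

        coef = np.zeros((5, 2))
        coef[0], coef[2], coef[4] = 2.0, 0.1, 0.05
        model = NormativeModel(coef=coef, resid_sd=np.ones(2), dof=10, rank=5, center_age=49.0)
        a = predict_case(model, {"age": 49.0, "sex": "male", "handedness": "left"})
        b = predict_case(model, {"age": 49.0, "sex": 1, "handedness": 1})
        assert np.array_equal(a.values, b.values)


class TestDeviation:
    def test_exact_arithmetic_and_zero_sd_branch(self):
        from deviate.validation import studentized_exactness

        r = studentized_exactness()
        assert r["zero_sd_flagged"]
        assert r["max_abs_err"] == 0.0

    def test_identity_gives_zero(self, ico2):
        truth = default_truth(ico2, seed=8)
        cohort = generate_cohort(n=25, seed=8)
        stack = generate_thickness(ico2, cohort, truth)
        model = fit_normative(stack, build_design(cohort, 43.0))
        pred = predict_case(model, {"age": 43.0, "sex": 0, "handedness": 0})
        dev = studentized_residual(pred, pred, model)
        assert np.allclose(dev.values[~dev.excluded], 0.0)

    def test_null_pseudo_case_variance_near_unity(self):
        # the plain ratio slightly inflates: prediction variance is not
        # removed, so pooled variance sits just above 1
        r = null_deviation_variance(seed=0, n_reps=100)
        assert 0.9 <= r["pooled_variance"] <= 1.15

    def test_inflation_shrinks_deviations(self):
        from deviate.glm import NormativeModel

        model = NormativeModel(
            coef=np.zeros((5, 3)), resid_sd=np.full(3, 0.5), dof=20, rank=5,
            center_age=43.0, gram_inv=np.eye(5) * 0.05,
        )
        actual = VertexMap(np.array([1.0, 2.0, 3.0]))
        pred = VertexMap(np.zeros(3))
        case = {"age": 43.0, "sex": 0, "handedness": 0}
        plain = studentized_residual(actual, pred, model, case=case)
        infl = studentized_residual(actual, pred, model, case=case, inflate=True)
        assert (np.abs(infl.values) < np.abs(plain.values)).all()

    def test_size_mismatch(self):
        from deviate.glm import NormativeModel

        model = NormativeModel(coef=np.zeros((5, 3)), resid_sd=np.ones(3), dof=10,
                               rank=5, center_age=43.0)
        with pytest.raises(DataError, match="mismatch"):
            studentized_residual(VertexMap(np.ones(2)), VertexMap(np.ones(3)), model)


class TestRegionSummary:
    def test_constant_maps_report_printed_means(self, ico2):
        # format illustration: observed 3.05 mm vs predicted 2.33 mm
        areas = vertex_areas(ico2)
        region = np.arange(40)
        actual = VertexMap(np.full(ico2.n_vertices, 3.05), kind="thickness")
        pred = VertexMap(np.full(ico2.n_vertices, 2.33), kind="thickness")
        ma, mp = region_summary(actual, pred, region, areas)
        assert np.isclose(ma, 3.05, rtol=1e-12) and np.isclose(mp, 2.33, rtol=1e-12)

    def test_whole_mesh_uniform_areas_is_plain_mean(self, tetra, rng):
        areas = vertex_areas(tetra)  # regular tetra: equal areas
        vals = rng.normal(2.5, 0.3, 4)
        ma, _ = region_summary(VertexMap(vals), VertexMap(vals), np.arange(4), areas)
        assert np.isclose(ma, vals.mean())

    def test_two_vertex_equal_area_mean(self, tetra):
        areas = vertex_areas(tetra)
        ma, mp = region_summary(
            VertexMap([2.0, 4.0, 0.0, 0.0]), VertexMap([1.0, 3.0, 0.0, 0.0]),
            np.array([0, 1]), areas,
        )
        assert (ma, mp) == (3.0, 2.0)

    def test_empty_region(self, tetra):
        with pytest.raises(DataError):
            region_summary(VertexMap(np.ones(4)), VertexMap(np.ones(4)),
                           np.array([], dtype=int), vertex_areas(tetra))


class TestModelIO:
    def test_roundtrip(self, ico2, tmp_path):
        truth = default_truth(ico2, seed=9)
        cohort = generate_cohort(n=25, seed=9)
        stack = generate_thickness(ico2, cohort, truth)
        model = fit_normative(stack, build_design(cohort, 43.0))
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert np.array_equal(back.coef, model.coef)
        assert np.array_equal(back.resid_sd, model.resid_sd)
        assert back.dof == model.dof and back.center_age == model.center_age
        assert np.allclose(back.gram_inv, model.gram_inv)
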