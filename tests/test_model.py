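"""Curve PCA, score regression, cross-validation and influence diagnostics."""

import warnings

import numpy as np
import pytest
import statsmodels.api as sm

from kbplan.cohort import cohort_cases, cohort_truth, generate_cohort
from kbplan.model import (
    CurvePCA,
    StructureDVHModel,
    cross_validate,
    detect_outliers,
    fit_pca,
    regression_diagnostics,
    score,
    train_models,
    training_report,
)

from conftest import linear_cohort


class TestCurvePCA:
    def test_identical_curves_zero_components(self, grid):
        X = np.tile(np.linspace(1, 0, grid.size), (5, 1))
        basis = fit_pca(X)
        assert basis.n_components_ == 0
        np.testing.assert_allclose(basis.mean_, X[0])

    def test_rank_one_family(self, grid):
        mean = np.linspace(1, 0, 50)
        shape = np.sin(np.linspace(0, np.pi, 50))
        shape /= np.linalg.norm(shape)
        X = np.array([mean + a * shape for a in (-2, -1, 0, 1, 2)])
        basis = fit_pca(X)
        assert basis.n_components_ == 1
        assert basis.explained_variance_ratio_[0] == pytest.approx(1.0)
        assert abs(np.dot(basis.components_[0], shape)) == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 40))
        basis = CurvePCA(n_components=5).fit(X)
        # oracle: eigendecomposition of the dense covariance matrix
        C = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(basis.explained_variance_, evals[:5], rtol=1e-9)
        for j in range(5):
            dot = abs(np.dot(basis.components_[j], evecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_with_all_components_is_exact(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 25))
        basis = CurvePCA(n_components=25).fit(X)
        rec = basis.inverse_transform(basis.transform(X))
        assert np.sqrt(np.mean((rec - X) ** 2)) < 1e-9

    def test_explained_variance_non_increasing_and_bounded(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 30)) * np.linspace(3, 0.1, 30)
        basis = CurvePCA(n_components=8).fit(X)
        assert np.all(np.diff(basis.explained_variance_) <= 1e-12)
        assert basis.explained_variance_ratio_.sum() <= 1 + 1e-12
        # orthogonality
        G = basis.components_ @ basis.components_.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_pca(np.ones((1, 10)))


@pytest.fixture(scope="module")
def basis():
    rng = np.random.default_rng(3)
    return CurvePCA(n_components=3).fit(rng.normal(size=(20, 30)))


class TestScores:

    def test_mean_curve_scores_zero(self, basis):
        np.testing.assert_allclose(score(basis, basis.mean_), 0.0, atol=1e-10)

    def test_constructed_curve(self, basis):
        curve = basis.mean_ + 2.0 * basis.components_[0]
        np.testing.assert_allclose(score(basis, curve), [2.0, 0.0, 0.0], atol=1e-10)

    def test_projection_equals_least_squares(self, basis):
        rng = np.random.default_rng(4)
        curve = rng.normal(size=30)
        s = score(basis, curve)
        # oracle: normal-equations least-squares fit of the components
        A = basis.components_.T
        s_ls, *_ = np.linalg.lstsq(A, curve - basis.mean_, rcond=None)
        np.testing.assert_allclose(s, s_ls, atol=1e-9)

    def test_grid_mismatch(self, basis):
        with pytest.raises(ValueError, match="grid mismatch"):
            score(basis, np.zeros(31))


class TestStructureModelFit:
    def test_noise_free_linear_cohort_recovers_slope(self, grid):
        cases, s, u, g = linear_cohort(grid, n=25, slope=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = StructureDVHModel(min_cases=20, feature_names=()).fit(cases)
        (idx,) = [i for i, n in enumerate(model.predictor_names_) if n == "ged_pc1"]
        assert model.coef_raw_[idx, 0] == pytest.approx(2.0, abs=1e-6)
        assert model.resid_stderr_[0] == pytest.approx(0.0, abs=1e-7)

    def test_recovered_coefficients_within_three_se(self):
        cohort = generate_cohort(n_patients=200, seed=42)
        truth = cohort_truth(cohort)
        cases = cohort_cases(cohort, structures=("normal_liver",))["normal_liver"]
        model = StructureDVHModel().fit(cases)
        p = model.partition_index_
        gen = truth["components"][:, p:]
        align = model.dvh_pca_.components_ @ gen.T
        signs = np.sign(np.diag(align))
        sd = truth["ged_score_sd"]["normal_liver"]
        B = truth["true_beta"]
        names = model.predictor_names_
        for j in range(model.dvh_pca_.n_components_):
            for i, nm in enumerate(names):
                if nm == "ged_pc1":
                    true = B[j, 0] / sd[0]
                elif nm == "ged_pc2":
                    true = B[j, 1] / sd[1]
                else:
                    true = 0.0
                est = model.coef_raw_[i, j] * signs[j]
                se = model.coef_raw_stderr_[i, j]
                assert abs(est - true) <= 3 * se + 1e-12

    def test_duplicated_predictor_rejected(self, grid):
        cases, *_ = linear_cohort(grid, n=25)
        for c in cases:
            c.features["dup"] = c.features["target_volume_cm3"]
        with pytest.raises(ValueError, match="collinear"):
            StructureDVHModel(
                feature_names=("target_volume_cm3", "dup")
            ).fit(cases)

    def test_insufficient_cases(self, grid):
        cases, *_ = linear_cohort(grid, n=10)
        with pytest.raises(ValueError, match="insufficient cases"):
            StructureDVHModel(min_cases=20).fit(cases)

    def test_mismatched_grids_rejected(self, grid):
        cases, *_ = linear_cohort(grid, n=21)
        other = np.linspace(0, 60, grid.size)
        cases[3].dvh.dose_gy = other
        with pytest.raises(ValueError, match="grid"):
            StructureDVHModel(min_cases=20).fit(cases)


class TestCrossValidation:
    def test_noise_free_goodness_is_zero(self, grid):
        cases, *_ = linear_cohort(grid, n=30)
        cv = cross_validate(cases, folds=10, seed=0, feature_names=())
        assert cv < 1e-6

    def test_goodness_matches_injected_noise_floor(self):
        cohort = generate_cohort(n_patients=200, seed=3)
        cases = cohort_cases(cohort, structures=("normal_liver",))["normal_liver"]
        cv = cross_validate(cases, folds=10, seed=0)
        sigma2 = cohort.config.noise_sd**2
        assert abs(cv - sigma2) <= 0.25 * sigma2

    def test_loo_equals_explicit_loop(self, grid):
        cases, *_ = linear_cohort(grid, n=12, noise_sd=0.004, seed=5)
        params = dict(feature_names=(), min_cases=2)
        got = cross_validate(cases, folds=12, seed=0, **params)
        errs = []
        for i in range(12):
            train = [c for j, c in enumerate(cases) if j != i]
            m = StructureDVHModel(**params).fit(train)
            pred = m.predict(cases[i]).most_probable / 100
            errs.append(np.mean((pred - cases[i].dvh.volume_pct / 100) ** 2))
        assert got == pytest.approx(np.mean(errs), rel=1e-9)

    def test_fold_shuffle_invariant_to_case_order(self, grid):
        cases, *_ = linear_cohort(grid, n=30, noise_sd=0.003, seed=6)
        a = cross_validate(cases, folds=10, seed=1, feature_names=())
        rng = np.random.default_rng(0)
        perm = rng.permutation(30)
        b = cross_validate([cases[i] for i in perm], folds=10, seed=1, feature_names=())
        # folds are assigned by patient id, so ordering cannot matter
        assert b == pytest.approx(a, rel=1e-12)

    def test_too_few_cases(self, grid):
        cases, *_ = linear_cohort(grid, n=5)
        with pytest.raises(ValueError):
            cross_validate(cases, folds=10)


class TestDiagnostics:
    def test_perfect_fit_has_unit_model_fit(self, grid):
        cases, *_ = linear_cohort(grid, n=25)
        model = StructureDVHModel(feature_names=()).fit(cases)
        d = regression_diagnostics(model)
        assert d["model_fit"] == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_predictors_give_near_zero_fit(self, grid):
        rng = np.random.default_rng(8)
        cases, s, u, g = linear_cohort(grid, n=300, seed=8)
        # break the geometry-dose link: shuffle the DVHs across patients
        dvhs = [c.dvh for c in cases]
        rng.shuffle(dvhs)
        for c, dvh in zip(cases, dvhs):
            c.dvh = dvh
        model = StructureDVHModel(feature_names=()).fit(cases)
        d = regression_diagnostics(model)
        assert d["model_fit"] < 0.1

    def test_chi_square_calibrated_on_correct_specification(self):
        cohort = generate_cohort(n_patients=500, seed=4)
        cases = cohort_cases(cohort, structures=("normal_liver",))["normal_liver"]
        model = StructureDVHModel().fit(cases)
        d = regression_diagnostics(model)
        assert 0.8 <= d["average_chi_square"] <= 1.2
        assert d["model_fit"] <= 1.0


class TestOutliers:
    def test_no_outliers_on_exact_line(self, grid):
        cases, *_ = linear_cohort(grid, n=25)
        model = StructureDVHModel(feature_names=()).fit(cases)
        assert detect_outliers(model) == []

    def test_planted_outlier_dominates_and_matches_loo_refit(self, grid):
        cases, s, u, g = linear_cohort(grid, n=20, noise_sd=0.003, seed=9)
        # corrupt one patient's DVH with a gross dosimetric deviation
        bad = cases[7].dvh.volume_pct / 100.0
        bad = np.minimum.accumulate(np.clip(bad + 0.25 * u, 0, 1))
        bad[0] = 1.0
        cases[7].dvh.volume_pct = 100 * bad
        model = StructureDVHModel(feature_names=()).fit(cases)
        diag = model.case_diagnostics()
        comp1 = diag[diag["component"] == 1].reset_index(drop=True)
        assert comp1.loc[comp1["cooks_distance"].idxmax(), "patient_id"] == "p07"

        # oracle: explicit leave-one-out refits
        X = model.design_
        y = model.dvh_scores_[:, 0]
        fit = sm.OLS(y, X).fit()
        p = X.shape[1]
        s2 = fit.ssr / fit.df_resid
        n = len(y)
        for i in range(n):
            mask = np.arange(n) != i
            beta_i = sm.OLS(y[mask], X[mask]).fit()
            delta = fit.params - beta_i.params
            cooks_oracle = float(delta @ (X.T @ X) @ delta) / (p * s2)
            assert comp1.loc[i, "cooks_distance"] == pytest.approx(
                cooks_oracle, rel=1e-6, abs=1e-10
            )
            s_i = np.sqrt(beta_i.ssr / beta_i.df_resid)
            h_ii = comp1.loc[i, "leverage"]
            student_oracle = fit.resid[i] / (s_i * np.sqrt(1 - h_ii))
            assert comp1.loc[i, "studentized_residual"] == pytest.approx(
                student_oracle, rel=1e-6, abs=1e-10
            )

    def test_duplicating_a_point_reduces_its_influence(self, grid):
        cases, s, u, g = linear_cohort(grid, n=15, noise_sd=0.004, seed=10)
        bad = cases[4].dvh.volume_pct / 100.0
        bad = np.minimum.accumulate(np.clip(bad + 0.15 * u, 0, 1))
        bad[0] = 1.0
        cases[4].dvh.volume_pct = 100 * bad
        params = dict(feature_names=(), min_cases=2)
        m1 = StructureDVHModel(**params).fit(cases)
        d1 = m1.case_diagnostics()
        base = d1[(d1["component"] == 1) & (d1["patient_id"] == "p04")]

        import copy

        extra = [copy.deepcopy(cases[4]) for _ in range(6)]
        m2 = StructureDVHModel(**params).fit(cases + extra)
        d2 = m2.case_diagnostics()
        dup = d2[(d2["component"] == 1) & (d2["patient_id"] == "p04")]
        assert float(dup["leverage"].iloc[0]) < float(base["leverage"].iloc[0])
        assert float(dup["cooks_distance"].iloc[0]) < float(
            base["cooks_distance"].iloc[0]
        )

    def test_outlier_records_carry_reasons(self, grid):
        cases, s, u, g = linear_cohort(grid, n=20, noise_sd=0.002, seed=11)
        bad = cases[3].dvh.volume_pct / 100.0
        bad = np.minimum.accumulate(np.clip(bad + 0.3 * u, 0, 1))
        bad[0] = 1.0
        cases[3].dvh.volume_pct = 100 * bad
        model = StructureDVHModel(feature_names=()).fit(cases)
        records = detect_outliers(model, cooks_threshold=0.5, studentized_threshold=3)
        assert any(r.patient_id == "p03" and r.reasons for r in records)


class TestTrainingReport:
    def test_recommended_n_reported_only_when_short(self, grid):
        # 7 regression parameters (intercept + 2 GED scores + 4 features)
        # -> recommended 35; reported for n=21, absent for n=45
        for n, expected in ((21, 35), (45, None)):
            cohort = generate_cohort(n_patients=n, seed=12)
            cases = cohort_cases(cohort, structures=("spinal_cord",))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models, report = train_models(cases, seed=0)
            row = report.structures[0]
            assert row.recommended_n == expected
            assert row.n_cases == n

    def test_understaffed_structure_excluded_with_warning(self, grid):
        cohort = generate_cohort(n_patients=19, seed=13)
        cases = cohort_cases(cohort, structures=("stomach",))
        with pytest.warns(UserWarning, match="no model built"):
            models, report = train_models(cases, seed=0)
        assert models == {}

    def test_report_frames(self):
        cohort = generate_cohort(n_patients=25, seed=14)
        cases = cohort_cases(cohort, structures=("left_kidney",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models, report = train_models(cases, seed=0)
        frame = report.to_frame()
        assert set(frame["structure"]) == {"left_kidney"}
        assert (frame["goodness_of_estimation"] >= 0).all()
        assert (frame["model_fit"] <= 1).all()
        report.outlier_frame()  # well-formed even when empty
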