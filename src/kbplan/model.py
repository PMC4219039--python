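"""Knowledge-based DVH model: curve PCA, score regression, diagnostics.

The modeling assumption is that any DVH in a population can be written as
the population-average curve plus a weighted sum of a few principal
components and a residual.  A structure's model couples the PC scores of
its DVH to the PC scores of its geometry-based expected dose (GED) plus a
few scalar geometric features through ordinary least squares, for the
in-field (high-GED) part of the curve; the out-of-field part is described
by a pointwise mean and standard deviation over the training population.

Estimators follow scikit-learn conventions (``fit``/``predict``/
``transform``, fitted attributes with a trailing underscore); the
module-level functions are thin wrappers kept for a functional call style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.isotonic import IsotonicRegression
from sklearn.model_selection import KFold
from statsmodels.stats.outliers_influence import OLSInfluence

from .dvh import DVHCurve
from .predict import PredictedDVH

__all__ = [
    "CurvePCA",
    "StructureCase",
    "StructureDVHModel",
    "OutlierRecord",
    "StructureReport",
    "TrainingReport",
    "fit_pca",
    "score",
    "fit_structure_model",
    "cross_validate",
    "regression_diagnostics",
    "detect_outliers",
    "training_report",
    "train_models",
    "MIN_TRAINING_CASES",
]

#: Below this many cases no model is built for a structure.
MIN_TRAINING_CASES = 20

DEFAULT_FEATURES = (
    "target_volume_cm3",
    "structure_volume_cm3",
    "in_field_fraction",
    "n_arcs",
)


# ---------------------------------------------------------------------------
# PCA of curves
# ---------------------------------------------------------------------------


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic sign convention for a unit-norm component.

    Positive sum when the sum is decisively non-zero; otherwise the first
    significantly non-zero entry is made positive.  (A max-magnitude rule
    is unstable for shapes whose extrema tie exactly.)
    """
    s = v.sum()
    if abs(s) > 1e-8:
        return v if s > 0 else -v
    nz = np.nonzero(np.abs(v) > 1e-6 * max(np.abs(v).max(), 1e-30))[0]
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


class CurvePCA(TransformerMixin, BaseEstimator):
    """Principal components of a set of curves sampled on a common grid.

    The first component maximizes the training variance explained; each
    further component accounts for the residual variance.  The number of
    retained components is the smallest count reaching ``variance_target``,
    capped at ``max_components`` (or fixed via ``n_components``).

    Component signs follow a deterministic convention (positive sum, or
    positive largest-magnitude entry when the sum vanishes) so repeated
    fits on the same data are identical.
    """

    def __init__(
        self,
        variance_target: float = 0.95,
        max_components: int = 5,
        n_components: int | None = None,
    ):
        self.variance_target = variance_target
        self.max_components = max_components
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "CurvePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("insufficient data: PCA needs at least 2 curves")
        n, m = X.shape
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        ev = s**2 / (n - 1)
        total = ev.sum()
        if total <= 1e-18:  # all curves identical
            k = 0
            ratio = np.zeros(0)
        else:
            ratio = ev / total
            if self.n_components is not None:
                k = min(self.n_components, ev.size)
            else:
                k = int(np.searchsorted(np.cumsum(ratio), self.variance_target - 1e-12) + 1)
                k = min(k, self.max_components, ev.size)
            # drop numerically null directions
            while k > 0 and ev[k - 1] <= 1e-15 * max(total, 1.0):
                k -= 1
        comps = vt[:k].copy()
        for j in range(k):
            comps[j] = _fix_sign(comps[j])
        self.components_ = comps
        self.explained_variance_ = ev[:k]
        self.explained_variance_ratio_ = ratio[:k]
        self.n_components_ = k
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_.size:
            raise ValueError("grid mismatch: curve length differs from basis")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return self.mean_ + scores @ self.components_


# ---------------------------------------------------------------------------
# Training cases and the per-structure model
# ---------------------------------------------------------------------------


@dataclass
class StructureCase:
    """One training/prediction case for one structure of one patient."""

    patient_id: str
    ged: DVHCurve
    dvh: DVHCurve | None
    prescription: float
    features: dict = field(default_factory=dict)


def _isotonic_decreasing(grid: np.ndarray, y: np.ndarray) -> np.ndarray:
    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(grid, y)


class StructureDVHModel(BaseEstimator):
    """Per-structure knowledge-based DVH model (fit on cases, predict DVHs).

    Parameters
    ----------
    ged_threshold : float
        In-field partition threshold as a fraction of the reference
        prescription; grid points at doses above it are modeled by the
        PC regression, points below by the out-of-field mean/SD model.
    variance_target, max_components, n_dvh_components, n_ged_components :
        PC retention rules for the DVH and GED bases.
    min_cases : int
        Minimum number of training cases (no model below it).
    fade_points : int
        Width (grid points) of the linear cross-fade between the two
        model regions.
    feature_names : tuple of str
        Scalar predictors taken from ``StructureCase.features``.
    """

    def __init__(
        self,
        ged_threshold: float = 0.2,
        variance_target: float = 0.95,
        max_components: int = 5,
        n_dvh_components: int | None = None,
        n_ged_components: int | None = None,
        min_cases: int = MIN_TRAINING_CASES,
        fade_points: int = 5,
        reference_prescription: float | None = None,
        feature_names: tuple = DEFAULT_FEATURES,
    ):
        self.ged_threshold = ged_threshold
        self.variance_target = variance_target
        self.max_components = max_components
        self.n_dvh_components = n_dvh_components
        self.n_ged_components = n_ged_components
        self.min_cases = min_cases
        self.fade_points = fade_points
        self.reference_prescription = reference_prescription
        self.feature_names = feature_names

    # -- fitting --------------------------------------------------------

    def fit(self, cases: list[StructureCase], y=None) -> "StructureDVHModel":
        n = len(cases)
        if n < self.min_cases:
            raise ValueError(
                f"insufficient cases: {n} < minimum {self.min_cases}"
            )
        grid = cases[0].dvh.dose_gy
        for c in cases:
            if not (
                np.allclose(c.dvh.dose_gy, grid) and np.allclose(c.ged.dose_gy, grid)
            ):
                raise ValueError("all cases must share the model dose grid")
        self.structure_name_ = cases[0].dvh.structure_name
        self.grid_ = np.asarray(grid, dtype=float)
        self.n_cases_ = n
        self.patient_ids_ = [c.patient_id for c in cases]

        D = np.stack([c.dvh.volume_pct / 100.0 for c in cases])
        G = np.stack([c.ged.volume_pct / 100.0 for c in cases])

        rx_ref = (
            self.reference_prescription
            if self.reference_prescription is not None
            else float(np.mean([c.prescription for c in cases]))
        )
        self.reference_prescription_ = rx_ref
        cut = self.ged_threshold * rx_ref
        p = int(np.searchsorted(self.grid_, cut))
        p = min(max(p, 0), self.grid_.size - 10)  # keep an in-field segment
        self.partition_index_ = p

        self.dvh_pca_ = CurvePCA(
            variance_target=self.variance_target,
            max_components=self.max_components,
            n_components=self.n_dvh_components,
        ).fit(D[:, p:])
        self.ged_pca_ = CurvePCA(
            variance_target=self.variance_target,
            max_components=self.max_components,
            n_components=self.n_ged_components,
        ).fit(G)

        self.out_mean_ = D.mean(axis=0)
        self.out_sd_ = D.std(axis=0, ddof=1)

        # --- predictor matrix: GED scores + scalar geometric features ---
        ged_scores = self.ged_pca_.transform(G)
        names = [f"ged_pc{j + 1}" for j in range(ged_scores.shape[1])]
        cols = [ged_scores]
        for fname in self.feature_names:
            col = np.array([float(c.features.get(fname, np.nan)) for c in cases])
            if np.any(np.isnan(col)):
                raise ValueError(f"feature {fname!r} missing from some cases")
            cols.append(col[:, None])
            names.append(fname)
        X = np.hstack(cols)

        sd = X.std(axis=0, ddof=1)
        keep = sd > 1e-12
        for nm in np.array(names)[~keep]:
            warnings.warn(f"dropping constant predictor {nm!r}", stacklevel=2)
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
        mu, sig = X.mean(axis=0), X.std(axis=0, ddof=1)
        Z = (X - mu) / sig
        self.predictor_names_ = names
        self.predictor_mean_ = mu
        self.predictor_scale_ = sig

        design = sm.add_constant(Z, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            corr = np.corrcoef(Z, rowvar=False)
            bad = [
                f"{names[a]}~{names[b]}"
                for a in range(len(names))
                for b in range(a + 1, len(names))
                if abs(corr[a, b]) > 1 - 1e-8
            ]
            raise ValueError(
                "rank-deficient predictor matrix; collinear predictors: "
                + (", ".join(bad) if bad else "undetermined")
            )

        dvh_scores = self.dvh_pca_.transform(D[:, p:])
        self.design_ = design
        self.dvh_scores_ = dvh_scores
        self.fits_ = [
            sm.OLS(dvh_scores[:, j], design).fit()
            for j in range(self.dvh_pca_.n_components_)
        ]
        k = len(self.fits_)
        self.coef_ = np.array([f.params for f in self.fits_]).T if k else np.zeros((design.shape[1], 0))
        self.coef_stderr_ = np.array([f.bse for f in self.fits_]).T if k else np.zeros((design.shape[1], 0))
        self.resid_stderr_ = np.array([np.sqrt(f.mse_resid) for f in self.fits_])
        return self

    @property
    def coef_raw_(self) -> np.ndarray:
        """Slopes on the raw (unstandardized) predictor scale, without intercept."""
        return self.coef_[1:] / self.predictor_scale_[:, None]

    @property
    def coef_raw_stderr_(self) -> np.ndarray:
        return self.coef_stderr_[1:] / self.predictor_scale_[:, None]

    # -- prediction -----------------------------------------------------

    def _design_row(self, case: StructureCase) -> np.ndarray:
        gscores = self.ged_pca_.transform(case.ged.volume_pct / 100.0)[0]
        vals = list(gscores)
        for fname in self.predictor_names_[len(gscores):]:
            if fname not in case.features:
                raise ValueError(f"feature {fname!r} missing from case")
            vals.append(float(case.features[fname]))
        z = (np.array(vals) - self.predictor_mean_) / self.predictor_scale_
        return np.concatenate([[1.0], z])

    def predict_scores(self, case: StructureCase) -> np.ndarray:
        """Predicted DVH PC scores for a new case."""
        if self.coef_.shape[1] == 0:
            return np.zeros(0)
        return self._design_row(case) @ self.coef_

    def predict(self, case: StructureCase) -> PredictedDVH:
        """Most-probable DVH with a pointwise uncertainty band.

        In-field half-width adds the PCs scaled by their regression
        standard errors in quadrature; out-of-field it is one pointwise
        standard deviation of the training curves.  The two segments are
        cross-faded at the partition and each band curve is projected onto
        the non-increasing cone.
        """
        if not np.allclose(case.ged.dose_gy, self.grid_):
            raise ValueError("case GED not on the model grid")
        p = self.partition_index_
        G = self.grid_.size

        scores = self.predict_scores(case)
        in_seg = self.dvh_pca_.inverse_transform(scores)[0]
        if self.resid_stderr_.size:
            hw_seg = np.sqrt(
                ((self.resid_stderr_[:, None] * self.dvh_pca_.components_) ** 2).sum(axis=0)
            )
        else:
            hw_seg = np.zeros(G - p)

        in_curve = np.empty(G)
        in_curve[p:] = in_seg
        in_curve[:p] = in_seg[0]
        hw_in = np.empty(G)
        hw_in[p:] = hw_seg
        hw_in[:p] = hw_seg[0] if hw_seg.size else 0.0

        # cross-fade weights: 0 in the out-of-field region, ramping to 1
        # over fade_points grid points centered at the partition
        w = np.ones(G)
        if p > 0:
            start = max(p - self.fade_points // 2, 0)
            stop = min(start + self.fade_points, G)
            w[:start] = 0.0
            w[start:stop] = np.linspace(0.0, 1.0, stop - start)

        mp = (1 - w) * self.out_mean_ + w * in_curve
        hw = (1 - w) * self.out_sd_ + w * hw_in

        lower = np.clip(_isotonic_decreasing(self.grid_, mp - hw), 0.0, 1.0)
        most = np.clip(_isotonic_decreasing(self.grid_, mp), 0.0, 1.0)
        upper = np.clip(_isotonic_decreasing(self.grid_, mp + hw), 0.0, 1.0)
        return PredictedDVH(
            structure_name=self.structure_name_,
            dose_gy=self.grid_.copy(),
            most_probable=100.0 * most,
            lower=100.0 * lower,
            upper=100.0 * upper,
        )

    # -- diagnostics ----------------------------------------------------

    def case_diagnostics(self) -> pd.DataFrame:
        """Per-case, per-component influence measures (Cook's distance,
        externally studentized residual, leverage)."""
        rows = []
        for j, fit in enumerate(self.fits_):
            infl = OLSInfluence(fit)
            lev = infl.hat_matrix_diag
            cooks = infl.cooks_distance[0]
            student = infl.resid_studentized_external
            # exact-leverage points: infinite influence, not a crash
            exact = lev >= 1 - 1e-12
            cooks = np.where(exact | ~np.isfinite(cooks), np.inf, cooks)
            unbounded = np.where(np.asarray(fit.resid) >= 0, np.inf, -np.inf)
            student = np.where(exact | ~np.isfinite(student), unbounded, student)
            for i, pid in enumerate(self.patient_ids_):
                rows.append(
                    {
                        "patient_id": pid,
                        "component": j + 1,
                        "cooks_distance": cooks[i],
                        "studentized_residual": student[i],
                        "leverage": lev[i],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "component",
                "cooks_distance",
                "studentized_residual",
                "leverage",
            ],
        )


# ---------------------------------------------------------------------------
# Reports and diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlierRecord:
    patient_id: str
    structure: str
    cooks_distance: float
    studentized_residual: float
    reasons: tuple

    def __post_init__(self) -> None:
        if not self.reasons:
            raise ValueError("an outlier record needs at least one reason")


@dataclass
class StructureReport:
    structure: str
    n_cases: int
    goodness_of_estimation: float
    average_chi_square: float
    model_fit: float
    recommended_n: int | None
    outliers: list


@dataclass
class TrainingReport:
    structures: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "structure": s.structure,
                    "n_cases": s.n_cases,
                    "recommended_n": s.recommended_n,
                    "average_chi_square": s.average_chi_square,
                    "model_fit": s.model_fit,
                    "goodness_of_estimation": s.goodness_of_estimation,
                    "n_outliers": len(s.outliers),
                }
                for s in self.structures
            ]
        )

    def outlier_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "structure": s.structure,
                    "patient_id": o.patient_id,
                    "cooks_distance": o.cooks_distance,
                    "studentized_residual": o.studentized_residual,
                    "reasons": "+".join(o.reasons),
                }
                for s in self.structures
                for o in s.outliers
            ],
            columns=[
                "structure",
                "patient_id",
                "cooks_distance",
                "studentized_residual",
                "reasons",
            ],
        )


def regression_diagnostics(model: StructureDVHModel) -> dict:
    """Training-quality metrics of the score regressions.

    ``average_chi_square`` compares, per component, the least-squares
    residual variance with a robust (MAD-based) estimate of the same
    residuals' variance: ~1 for well-behaved Gaussian residuals, inflated
    when a few influential cases carry unusually large residuals.
    ``model_fit`` is the pooled coefficient of determination over all
    component regressions (<= 1, near 1 for a tight regression).
    """
    if not len(model.fits_):
        raise ValueError("model retained no DVH components; no regression to assess")
    chis = []
    rss_total = tss_total = 0.0
    for fit in model.fits_:
        if fit.df_resid <= 0:
            raise ValueError("zero residual degrees of freedom")
        resid = fit.resid
        n = resid.size
        rss = float(fit.ssr)
        tss = float(fit.centered_tss)
        rss_total += rss
        tss_total += tss
        mad = np.median(np.abs(resid - np.median(resid)))
        robust_var = (1.4826 * mad) ** 2
        if robust_var <= 1e-30:
            chis.append(1.0 if rss / n <= 1e-30 else np.inf)
        else:
            chis.append((rss / n) / robust_var)
    model_fit = 1.0 if tss_total <= 1e-30 else 1.0 - rss_total / tss_total
    return {"average_chi_square": float(np.mean(chis)), "model_fit": float(model_fit)}


def detect_outliers(
    model: StructureDVHModel,
    cooks_threshold: float = 4.0,
    studentized_threshold: float = 3.0,
) -> list[OutlierRecord]:
    """Flag influential / poorly fit training cases.

    A case is reported when, in any component regression, its Cook's
    distance reaches ``cooks_threshold`` or its externally studentized
    residual magnitude reaches ``studentized_threshold``.  Outliers are
    reported, never removed.
    """
    diag = model.case_diagnostics()
    records = []
    if diag.empty:
        return records
    for pid, sub in diag.groupby("patient_id", sort=False):
        cooks = float(sub["cooks_distance"].max())
        srow = sub.loc[sub["studentized_residual"].abs().idxmax()]
        student = float(srow["studentized_residual"])
        reasons = []
        if cooks >= cooks_threshold:
            reasons.append("cooks")
        if abs(student) >= studentized_threshold:
            reasons.append("studentized")
        if reasons:
            records.append(
                OutlierRecord(
                    patient_id=pid,
                    structure=model.structure_name_,
                    cooks_distance=cooks,
                    studentized_residual=student,
                    reasons=tuple(reasons),
                )
            )
    return records


def cross_validate(
    cases: list[StructureCase],
    folds: int = 10,
    seed: int = 0,
    **model_params,
) -> float:
    """K-fold cross-validated goodness of estimation for one structure.

    The cases are split into ``folds`` parts; a model is trained on each
    complement and scored on the held-out part.  Returned is the average
    over folds of the mean squared error between held-out DVH curves and
    their predicted most-probable curves, in fractional volume units.

    Fold assignment is a seeded shuffle of the patient-id order, so the
    statistic does not depend on how the cases are listed.
    """
    n = len(cases)
    if n < folds:
        raise ValueError(f"need at least {folds} cases for {folds}-fold CV")
    model_params.setdefault("min_cases", 2)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mse = []
    idx = np.argsort([c.patient_id for c in cases], kind="stable")
    for train_idx, test_idx in (
        (idx[tr], idx[te]) for tr, te in kf.split(idx)
    ):
        model = StructureDVHModel(**model_params).fit([cases[i] for i in train_idx])
        errs = []
        for i in test_idx:
            pred = model.predict(cases[i]).most_probable / 100.0
            actual = cases[i].dvh.volume_pct / 100.0
            errs.append(float(np.mean((pred - actual) ** 2)))
        fold_mse.append(float(np.mean(errs)))
    return float(np.mean(fold_mse))


def training_report(
    models: dict,
    goodness: dict,
    cooks_threshold: float = 4.0,
    studentized_threshold: float = 3.0,
) -> TrainingReport:
    """Assemble the per-structure training summary.

    The recommended number of cases is five times the number of regression
    parameters, reported only when the structure has fewer cases than that.
    """
    structures = []
    for name, model in models.items():
        diags = regression_diagnostics(model)
        n_params = model.coef_.shape[0]  # intercept + predictors
        rec = 5 * n_params
        structures.append(
            StructureReport(
                structure=name,
                n_cases=model.n_cases_,
                goodness_of_estimation=float(goodness.get(name, np.nan)),
                average_chi_square=diags["average_chi_square"],
                model_fit=diags["model_fit"],
                recommended_n=rec if model.n_cases_ < rec else None,
                outliers=detect_outliers(model, cooks_threshold, studentized_threshold),
            )
        )
    return TrainingReport(structures=structures)


def train_models(
    cases_by_structure: dict,
    cv_folds: int = 10,
    seed: int = 0,
    **model_params,
) -> tuple[dict, TrainingReport]:
    """Train one model per structure, skipping under-populated structures.

    Structures with fewer than the minimum number of cases are excluded
    with a warning (no prediction model is provided for them).
    """
    min_cases = model_params.get("min_cases", MIN_TRAINING_CASES)
    models: dict = {}
    goodness: dict = {}
    for name, cases in cases_by_structure.items():
        if len(cases) < min_cases:
            warnings.warn(
                f"structure {name!r} has {len(cases)} cases "
                f"(< {min_cases}); no model built",
                stacklevel=2,
            )
            continue
        params = dict(model_params)
        params["feature_names"] = _independent_features(
            cases, params.get("feature_names", DEFAULT_FEATURES), name
        )
        models[name] = StructureDVHModel(**params).fit(cases)
        folds = min(cv_folds, len(cases))
        goodness[name] = cross_validate(cases, folds=folds, seed=seed, **params)
    return models, training_report(models, goodness)


def _independent_features(cases, feature_names, structure: str) -> tuple:
    """Drop redundant scalar features for one structure (pipeline-level;
    ``fit`` itself still rejects collinear designs).  E.g. for the target
    structure the structure volume duplicates the target volume."""
    X = np.array(
        [[float(c.features.get(f, np.nan)) for f in feature_names] for c in cases]
    )
    keep: list = []
    for j, fname in enumerate(feature_names):
        col = X[:, j]
        redundant = False
        if col.std() > 1e-12:
            for i in keep:
                other = X[:, i]
                if other.std() > 1e-12:
                    r = np.corrcoef(col, other)[0, 1]
                    if abs(r) > 1 - 1e-8:
                        redundant = True
                        warnings.warn(
                            f"{structure}: dropping feature {fname!r} "
                            f"(collinear with {feature_names[i]!r})",
                            stacklevel=3,
                        )
                        break
        if not redundant:
            keep.append(j)
    return tuple(feature_names[i] for i in keep)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_pca(
    curves: np.ndarray, variance_target: float = 0.95, max_components: int = 5
) -> CurvePCA:
    """Fit a PCA basis to curves stacked as rows on a common grid."""
    return CurvePCA(variance_target=variance_target, max_components=max_components).fit(
        np.asarray(curves, dtype=float)
    )


def score(basis: CurvePCA, curve: np.ndarray) -> np.ndarray:
    """Component scores of one curve: projections onto the basis."""
    return basis.transform(curve)[0]


def fit_structure_model(cases: list[StructureCase], **config) -> StructureDVHModel:
    return StructureDVHModel(**config).fit(cases)
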