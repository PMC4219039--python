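import numpy as np
import pytest

from kbplan.dvh import DVHCurve
from kbplan.geometry import default_grid
from kbplan.model import CurvePCA, StructureCase, StructureDVHModel


@pytest.fixture(scope="session")
def grid():
    return default_grid(60.0, 100)


def unit_bump(grid, lo, hi):
    """Smooth unit-norm shape supported on doses in [lo, hi]."""
    mask = (grid >= lo) & (grid <= hi)
    u = np.zeros_like(grid)
    seg = grid[mask]
    u[mask] = np.sin(np.pi * (seg - seg[0]) / (seg[-1] - seg[0]))
    return u / np.linalg.norm(u)


def linear_cohort(
    grid,
    n=25,
    slope=2.0,
    noise_sd=0.0,
    seed=0,
    score_lim=0.5,
    prescription=60.0,
):
    """Hand-built noise-free (or noisy) rank-1 linear cohort:
    ged = base + s*g, dvh = mean + (slope*s)*u with u, g unit-norm.

    The GED variation is exactly rank one, so PCA on any subset recovers
    the same generating direction and the truth is exactly linear in the
    fitted scores."""
    rng = np.random.default_rng(seed)
    mean = 1.0 - 0.9 * (grid / grid[-1]) ** 0.95
    u = unit_bump(grid, 15.0, 64.0)
    gbase = np.clip(1.0 - 0.8 * (grid / grid[-1]), 0.0, 1.0)
    g = unit_bump(grid, 10.0, 60.0)
    s = rng.uniform(-score_lim, score_lim, n)
    cases = []
    for i in range(n):
        dvh = mean + slope * s[i] * u + rng.normal(0, noise_sd, grid.size)
        dvh[0] = 1.0
        dvh = np.minimum.accumulate(np.clip(dvh, 0, 1))
        ged = np.minimum.accumulate(np.clip(gbase + s[i] * g, 0, 1))
        ged[0] = 1.0
        cases.append(
            StructureCase(
                patient_id=f"p{i:02d}",
                ged=DVHCurve("toy", grid, 100 * ged, 100.0),
                dvh=DVHCurve("toy", grid, 100 * dvh, 100.0),
                prescription=prescription,
                features={
                    "target_volume_cm3": float(rng.uniform(100, 2000)),
                    "structure_volume_cm3": float(rng.uniform(30, 400)),
                    "in_field_fraction": float(rng.uniform(0.1, 0.9)),
                    "n_arcs": float(rng.integers(2, 5)),
                },
            )
        )
    return cases, s, u, g


def toy_band_model(
    grid,
    partition_index=0,
    n_components=1,
    resid_se=(0.0,),
    coef=None,
    out_sd_level=0.0,
    seed=0,
):
    """Assemble a fitted StructureDVHModel by hand (bypassing fit)."""
    rng = np.random.default_rng(seed)
    p = partition_index
    seg = grid[p:]
    m = StructureDVHModel(fade_points=5)
    m.structure_name_ = "toy"
    m.grid_ = grid.copy()
    m.n_cases_ = 30
    m.patient_ids_ = []
    m.reference_prescription_ = 60.0
    m.partition_index_ = p

    dvh_pca = CurvePCA(n_components=n_components)
    dvh_pca.mean_ = 1.0 - 0.85 * (seg / grid[-1]) ** 0.9
    comps = []
    for j in range(n_components):
        lo = 14.0 + 6 * j
        c = unit_bump(grid, lo, 60.0 - 4 * j)[p:]
        comps.append(c / np.linalg.norm(c))
    dvh_pca.components_ = np.array(comps) if comps else np.zeros((0, seg.size))
    dvh_pca.explained_variance_ = np.ones(n_components)
    dvh_pca.explained_variance_ratio_ = np.ones(n_components) / max(n_components, 1)
    dvh_pca.n_components_ = n_components
    m.dvh_pca_ = dvh_pca

    ged_pca = CurvePCA(n_components=1)
    ged_pca.mean_ = np.clip(1.0 - 0.8 * grid / grid[-1], 0, 1)
    gcomp = unit_bump(grid, 8.0, 58.0)
    ged_pca.components_ = gcomp[None, :]
    ged_pca.explained_variance_ = np.ones(1)
    ged_pca.explained_variance_ratio_ = np.ones(1)
    ged_pca.n_components_ = 1
    m.ged_pca_ = ged_pca

    m.out_mean_ = 1.0 - 0.85 * (grid / grid[-1]) ** 0.9
    m.out_sd_ = np.full(grid.size, out_sd_level)
    m.out_sd_[0] = 0.0
    m.predictor_names_ = ["ged_pc1"]
    m.predictor_mean_ = np.zeros(1)
    m.predictor_scale_ = np.ones(1)
    if coef is None:
        coef = np.vstack(
            [rng.normal(0, 0.02, n_components), rng.normal(0, 0.05, n_components)]
        )
    m.coef_ = np.asarray(coef, dtype=float).reshape(2, n_components)
    m.coef_stderr_ = np.zeros_like(m.coef_)
    m.resid_stderr_ = np.asarray(resid_se, dtype=float)
    m.fits_ = []
    return m


def case_with_ged_score(grid, score, features=None):
    """A prediction case whose GED projects to the given score on the
    toy model's single GED component."""
    ged_pca_mean = np.clip(1.0 - 0.8 * grid / grid[-1], 0, 1)
    gcomp = unit_bump(grid, 8.0, 58.0)
    ged = np.minimum.accumulate(np.clip(ged_pca_mean + score * gcomp, 0, 1))
    ged[0] = 1.0
    return StructureCase(
        patient_id="case",
        ged=DVHCurve("toy", grid, 100 * ged, 50.0),
        dvh=None,
        prescription=60.0,
        features=features or {},
    )
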