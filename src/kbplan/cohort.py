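"""Virtual-patient cohorts with a known geometry -> DVH ground truth.

The generator emulates the variability of a hepatocellular-cancer VMAT
population — right-skewed target volumes (mean 596 cm3, SD 538 cm3, range
54-2188 cm3), a 55/40/5 prescription mix at representative levels of
60/42/36 Gy, 2-4 partial arcs with a high non-coplanar fraction — while
embedding an exactly linear mapping from GED principal-component scores to
DVH principal-component scores.  That latent linear structure is what the
knowledge-based model assumes, so trained models can be audited for
parameter recovery, band calibration and diagnostics against a recorded
truth.

Generation is two-pass: geometries and GED curves are drawn first; the GED
curves are then decomposed by PCA (the same algorithm the model uses, so
the generating score coordinates coincide with the training ones), and each
OAR DVH is built as a fixed organ mean curve plus ``true_beta``-weighted
component shapes plus i.i.d. grid noise, projected onto the monotone cone.
Target (PTV) DVHs are drawn from a sigmoid coverage family instead — target
coverage is not part of the linear truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .dvh import DVHCurve
from .geometry import (
    FieldConfig,
    KernelParams,
    StructureGeometry,
    compute_ged,
    default_grid,
)
from .model import CurvePCA, StructureCase, _isotonic_decreasing

__all__ = [
    "CohortConfig",
    "VirtualPatient",
    "Cohort",
    "generate_cohort",
    "cohort_truth",
    "cohort_cases",
    "OAR_NAMES",
    "TARGET_NAME",
]

log = logging.getLogger(__name__)

TARGET_NAME = "ptv"
OAR_NAMES = (
    "normal_liver",
    "spinal_cord",
    "left_kidney",
    "right_kidney",
    "stomach",
    "esophagus",
)

# per-organ geometry family: (volume cm3, distance shift mm, gamma shape,
# gamma scale mm) and mean-DVH tail level.  Declared assumptions — the
# source population reports no OAR-level geometric statistics.
ORGAN_PARAMS = {
    "normal_liver": dict(volume=1100.0, shift=0.5, shape=1.2, scale=18.0, tail=0.15),
    "spinal_cord": dict(volume=40.0, shift=12.0, shape=2.0, scale=14.0, tail=0.10),
    "left_kidney": dict(volume=160.0, shift=18.0, shape=2.2, scale=12.0, tail=0.12),
    "right_kidney": dict(volume=160.0, shift=8.0, shape=2.0, scale=12.0, tail=0.13),
    "stomach": dict(volume=320.0, shift=6.0, shape=1.8, scale=15.0, tail=0.14),
    "esophagus": dict(volume=35.0, shift=10.0, shape=2.0, scale=16.0, tail=0.12),
}

#: number of latent DVH/GED components carrying the linear truth
N_TRUE_COMPONENTS = 2
#: truth predictors: standardized GED PC1/PC2 scores + standardized target volume
TRUE_PREDICTOR_NAMES = ("ged_z1", "ged_z2", "target_volume_z")


def _default_beta() -> np.ndarray:
    # rows: DVH components; columns: (ged_z1, ged_z2, target_volume_z).
    # Diagonal by default: the latent score covariance is then exactly
    # diagonal in-sample, so the generating shapes are the population
    # eigenvectors and the truth is identified without rotation ambiguity.
    # Magnitudes keep latent curve deflections within the monotone
    # headroom of the organ mean curves (see docs/methods.md).
    return np.array([[0.16, 0.0, 0.0], [0.0, 0.08, 0.0]])


@dataclass
class CohortConfig:
    """Population parameters of the virtual cohort."""

    n_patients: int = 45
    seed: int = 0
    target_volume_mean: float = 596.0
    target_volume_sd: float = 538.0
    volume_range: tuple = (54.0, 2188.0)
    prescription_mix: tuple = (0.55, 0.40, 0.05)
    prescription_levels: tuple = (60.0, 42.0, 36.0)
    arcs_range: tuple = (2, 4)
    noncoplanar_fraction: float = 40.0 / 45.0
    true_beta: np.ndarray = field(default_factory=_default_beta)
    noise_sd: float = 0.003
    n_grid: int = 100
    kernel: KernelParams = field(default_factory=KernelParams)
    ged_threshold: float = 0.2
    organs: tuple = OAR_NAMES

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        lo, hi = self.volume_range
        if not (0 < lo < hi):
            raise ValueError("volume bounds must be positive with low < high")
        mix = np.asarray(self.prescription_mix, dtype=float)
        if mix.min() < 0 or mix.sum() <= 0:
            raise ValueError("prescription mix must be non-negative and non-trivial")
        if abs(mix.sum() - 1.0) > 1e-9:
            log.info(
                "prescription mix %s does not sum to 1; normalizing", tuple(mix)
            )
        self.prescription_mix = tuple(mix / mix.sum())
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        if self.true_beta.shape != (N_TRUE_COMPONENTS, len(TRUE_PREDICTOR_NAMES)):
            raise ValueError(
                f"true_beta must have shape "
                f"({N_TRUE_COMPONENTS}, {len(TRUE_PREDICTOR_NAMES)})"
            )


@dataclass
class VirtualPatient:
    id: str
    field: FieldConfig
    target_volume_cm3: float
    geometries: dict
    geds: dict
    dvhs: dict
    latent_scores: dict  # organ -> true DVH component scores


@dataclass
class Cohort:
    patients: list
    config: CohortConfig
    grid: np.ndarray
    _truth: dict = field(default_factory=dict, repr=False)

    @property
    def synthetic(self) -> bool:
        return bool(self._truth) or not self.patients


# ---------------------------------------------------------------------------
# generating shapes
# ---------------------------------------------------------------------------


def _mean_curve(grid: np.ndarray, tail: float, power: float = 0.95) -> np.ndarray:
    """Organ mean DVH: strictly decreasing from 1 to ``tail`` over the grid.

    The minimum per-bin slope bounds the admissible latent deflections:
    curves built as mean + scores x components stay monotone by
    construction for |score| within the clamp used below.
    """
    u = grid / grid[-1]
    return 1.0 - (1.0 - tail) * u**power


def generating_components(grid: np.ndarray, partition_dose: float = 12.0) -> np.ndarray:
    """Two smooth, orthonormal component shapes supported above the
    in-field partition dose (half-sine and full-sine modes)."""
    mask = grid >= partition_dose
    u = np.zeros_like(grid)
    seg = grid[mask]
    u[mask] = (seg - seg[0]) / (seg[-1] - seg[0])
    c1 = np.where(mask, np.sin(np.pi * u), 0.0)
    c2 = np.where(mask, np.sin(2 * np.pi * u), 0.0)
    comps = np.stack([c1, c2])
    comps /= np.linalg.norm(comps, axis=1, keepdims=True)
    from .model import _fix_sign  # same sign convention as CurvePCA

    return np.stack([_fix_sign(c) for c in comps])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_target_volume(rng: np.random.Generator, cfg: CohortConfig) -> float:
    m, s = cfg.target_volume_mean, cfg.target_volume_sd
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    lo, hi = cfg.volume_range
    for _ in range(10000):  # rejection into the observed range
        v = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if lo <= v <= hi:
            return v
    raise RuntimeError("target-volume rejection sampling failed")


def _draw_geometry(
    rng: np.random.Generator, organ: str, target_volume: float, n_arcs: int
) -> StructureGeometry:
    p = ORGAN_PARAMS[organ]
    r_t = (3.0 * target_volume * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    r_ref = (3.0 * 596.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    shift = p["shift"] * rng.lognormal(0.0, 0.35) * (r_ref / r_t) ** 0.4
    scale = p["scale"] * rng.lognormal(0.0, 0.30)
    volume = p["volume"] * rng.lognormal(0.0, 0.40)
    # 20 equal-probability distance bins of the shifted gamma family
    q = (np.arange(20) + 0.5) / 20.0
    distances = shift + scale * sps.gamma.ppf(q, a=p["shape"])
    fractions = np.full(20, 1.0 / 20.0)
    reach = (25.0 + 6.0 * n_arcs) * rng.lognormal(0.0, 0.15)
    in_field = float(np.clip((distances <= reach).mean() + rng.normal(0, 0.05), 0.02, 1.0))
    return StructureGeometry(
        name=organ,
        volume_cm3=volume,
        distance_mm=distances,
        volume_fraction=fractions,
        in_field_fraction=in_field,
    )


def _target_dvh(
    rng: np.random.Generator, grid: np.ndarray, rx: float
) -> np.ndarray:
    """Sigmoid target-coverage curve around the prescription."""
    center = rx * rng.normal(1.0, 0.01)
    width = 1.2 * rng.lognormal(0.0, 0.25)
    v = 1.0 / (1.0 + np.exp((grid - center) / width))
    v = v / v[0]
    v[0] = 1.0
    return v


def generate_cohort(config: CohortConfig | None = None, **overrides) -> Cohort:
    """Draw a reproducible virtual cohort with recorded latent truth."""
    cfg = replace(config, **overrides) if config is not None else CohortConfig(**overrides)
    rng = np.random.default_rng(cfg.seed)
    grid = default_grid(max(cfg.prescription_levels), cfg.n_grid)
    partition_dose = cfg.ged_threshold * max(cfg.prescription_levels)

    if cfg.n_patients == 0:
        return Cohort(patients=[], config=cfg, grid=grid)

    # ---- pass 1: fields, anatomy, GED curves ----
    patients: list[VirtualPatient] = []
    for i in range(cfg.n_patients):
        rx = float(
            rng.choice(np.asarray(cfg.prescription_levels), p=cfg.prescription_mix)
        )
        n_arcs = int(rng.integers(cfg.arcs_range[0], cfg.arcs_range[1] + 1))
        coplanar = bool(rng.random() >= cfg.noncoplanar_fraction)
        fieldcfg = FieldConfig(n_arcs=n_arcs, coplanar=coplanar, prescription=rx)
        tvol = _draw_target_volume(rng, cfg)
        geometries = {
            organ: _draw_geometry(rng, organ, tvol, n_arcs) for organ in cfg.organs
        }
        geometries[TARGET_NAME] = StructureGeometry(
            name=TARGET_NAME,
            volume_cm3=tvol,
            distance_mm=np.array([-1.0]),
            volume_fraction=np.array([1.0]),
            in_field_fraction=1.0,
        )
        geds = {
            name: compute_ged(geom, fieldcfg, cfg.kernel, grid)
            for name, geom in geometries.items()
        }
        patients.append(
            VirtualPatient(
                id=f"vp{i:03d}",
                field=fieldcfg,
                target_volume_cm3=tvol,
                geometries=geometries,
                geds=geds,
                dvhs={},
                latent_scores={},
            )
        )

    # ---- pass 2: DVHs from the latent linear model ----
    comps = generating_components(grid, partition_dose)
    tvols = np.array([p.target_volume_cm3 for p in patients])
    tv_sd = tvols.std(ddof=1) if cfg.n_patients >= 3 else 1.0
    tv_z = (tvols - tvols.mean()) / tv_sd if tv_sd > 0 else np.zeros_like(tvols)

    truth: dict = {
        "true_beta": cfg.true_beta.copy(),
        "predictor_names": TRUE_PREDICTOR_NAMES,
        "components": comps,
        "ged_basis": {},
        "ged_score_sd": {},
        "latent_scores": {},
        "noise_sd": cfg.noise_sd,
    }

    for organ in cfg.organs:
        G = np.stack([p.geds[organ].volume_pct / 100.0 for p in patients])
        if cfg.n_patients >= 3:
            basis = CurvePCA(n_components=N_TRUE_COMPONENTS).fit(G)
            raw = basis.transform(G)
            sd = raw.std(axis=0, ddof=1)
            sd[sd <= 1e-12] = 1.0
            z = raw / sd
        else:
            basis, sd = None, np.ones(N_TRUE_COMPONENTS)
            z = np.zeros((cfg.n_patients, N_TRUE_COMPONENTS))
        if z.shape[1] < N_TRUE_COMPONENTS:  # degenerate GED population
            z = np.pad(z, ((0, 0), (0, N_TRUE_COMPONENTS - z.shape[1])))
            sd = np.pad(sd, (0, N_TRUE_COMPONENTS - sd.size), constant_values=1.0)
        # clamp extreme standardized draws: keeps mean + t.C monotone
        x = np.clip(np.column_stack([z, tv_z]), -4.0, 4.0)
        t = x @ cfg.true_beta.T
        mean = _mean_curve(grid, ORGAN_PARAMS[organ]["tail"])
        truth["ged_basis"][organ] = basis
        truth["ged_score_sd"][organ] = sd
        for i, pat in enumerate(patients):
            curve = mean + t[i] @ comps
            if cfg.noise_sd > 0:
                eps = rng.normal(0.0, cfg.noise_sd, grid.size)
                eps[0] = 0.0
                curve = curve + eps
                curve = _isotonic_decreasing(grid, curve)
            curve = np.clip(curve, 0.0, 1.0)
            curve[0] = 1.0
            pat.dvhs[organ] = DVHCurve(
                structure_name=organ,
                dose_gy=grid,
                volume_pct=100.0 * curve,
                volume_cm3=pat.geometries[organ].volume_cm3,
            )
            pat.latent_scores[organ] = t[i].copy()
            truth["latent_scores"].setdefault(pat.id, {})[organ] = t[i].copy()

    for pat in patients:
        v = _target_dvh(rng, grid, pat.field.prescription)
        pat.dvhs[TARGET_NAME] = DVHCurve(
            structure_name=TARGET_NAME,
            dose_gy=grid,
            volume_pct=100.0 * v,
            volume_cm3=pat.target_volume_cm3,
        )

    return Cohort(patients=patients, config=cfg, grid=grid, _truth=truth)


def cohort_truth(cohort: Cohort) -> dict:
    """Exact generating parameters of a synthetic cohort.

    Kept separate from the training path: models are fit from
    ``cohort_cases`` output only, never from this record.
    """
    if not cohort.synthetic:
        raise ValueError("cohort carries no synthetic ground truth")
    return cohort._truth


def cohort_cases(cohort: Cohort, structures=None) -> dict:
    """Arrange a cohort as per-structure training cases for the model."""
    names = structures if structures is not None else (*cohort.config.organs, TARGET_NAME)
    out: dict = {}
    for organ in names:
        cases = []
        for pat in cohort.patients:
            geom = pat.geometries[organ]
            cases.append(
                StructureCase(
                    patient_id=pat.id,
                    ged=pat.geds[organ],
                    dvh=pat.dvhs[organ],
                    prescription=pat.field.prescription,
                    features={
                        "target_volume_cm3": pat.target_volume_cm3,
                        "structure_volume_cm3": geom.volume_cm3,
                        "in_field_fraction": geom.in_field_fraction,
                        "n_arcs": pat.field.n_arcs,
                    },
                )
            )
        out[organ] = cases
    return out
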