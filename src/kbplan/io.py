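"""File formats: DVH CSV, geometry JSON, model archive, packaged fixtures.

Everything is plain text (CSV/JSON) so artifacts are inspectable and
diff-able.  Every artifact embeds the hash of the configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, cohort_truth
from .dvh import DVHCurve
from .geometry import FieldConfig, KernelParams, StructureGeometry
from .model import CurvePCA, StructureDVHModel

__all__ = [
    "RunConfig",
    "config_hash",
    "write_dvh_csv",
    "read_dvh_csv",
    "write_geometry_json",
    "read_geometry_json",
    "write_cohort",
    "read_cohort_plans",
    "save_models",
    "load_models",
    "load_table5",
]

SCHEMA_VERSION = 1


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    payload = json.dumps(obj, sort_keys=True, default=_default)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Validated run-level configuration for the command-line tool."""

    seed: int = 0
    endpoints: str = "default"
    cooks_threshold: float = 4.0
    studentized_threshold: float = 3.0
    variance_target: float = 0.95
    max_components: int = 5
    ged_threshold: float = 0.2
    objective_margin: float = 0.02
    kernel_k_in: float = 0.05
    kernel_k_out: float = 0.15
    kernel_f_out: float = 0.3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must lie in (0, 1]")
        if not 0 < self.ged_threshold < 1:
            raise ValueError("ged_threshold must lie in (0, 1)")
        if self.cooks_threshold <= 0 or self.studentized_threshold <= 0:
            raise ValueError("outlier thresholds must be positive")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if not 0 <= self.objective_margin < 1:
            raise ValueError("objective_margin must lie in [0, 1)")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# DVH CSV  (header: structure,dose_gy,volume_pct; sidecar volume lines)
# ---------------------------------------------------------------------------


def write_dvh_csv(path, curves: dict) -> None:
    path = Path(path)
    lines = [f"# volume_cm3:{name}={c.volume_cm3:.6g}" for name, c in curves.items()]
    lines.append("structure,dose_gy,volume_pct")
    for name, c in curves.items():
        for d, v in zip(c.dose_gy, c.volume_pct):
            lines.append(f"{name},{d:.6g},{v:.8g}")
    path.write_text("\n".join(lines) + "\n")


def read_dvh_csv(path) -> dict:
    path = Path(path)
    volumes: dict = {}
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            try:
                key, val = line.lstrip("# ").split("=", 1)
                volumes[key.split(":", 1)[1]] = float(val)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed volume header") from exc
            continue
        if line.startswith("structure,"):
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 fields, got {len(parts)}")
        try:
            rows.append((parts[0], float(parts[1]), float(parts[2])))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric dose/volume") from exc
    frame = pd.DataFrame(rows, columns=["structure", "dose_gy", "volume_pct"])
    curves: dict = {}
    for name, sub in frame.groupby("structure", sort=False):
        vol = sub["volume_pct"].to_numpy()
        if vol.min() < -1e-9 or vol.max() > 100 + 1e-6:
            raise ValueError(f"{path}: structure {name!r}: volume outside [0, 100]%")
        curves[name] = DVHCurve(
            structure_name=name,
            dose_gy=sub["dose_gy"].to_numpy(),
            volume_pct=vol,
            volume_cm3=volumes.get(name, float("nan")),
        )
    return curves


# ---------------------------------------------------------------------------
# Geometry JSON
# ---------------------------------------------------------------------------


def write_geometry_json(path, patient_id: str, fieldcfg: FieldConfig, geometries: dict) -> None:
    data = {
        "schema_version": SCHEMA_VERSION,
        "patient_id": patient_id,
        "fields": {
            "n_arcs": fieldcfg.n_arcs,
            "coplanar": fieldcfg.coplanar,
            "prescription_gy": fieldcfg.prescription,
        },
        "structures": {
            name: {
                "volume_cm3": g.volume_cm3,
                "distance_mm": g.distance_mm.tolist(),
                "volume_fraction": g.volume_fraction.tolist(),
                "in_field_fraction": g.in_field_fraction,
            }
            for name, g in geometries.items()
        },
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_geometry_json(path) -> tuple[str, FieldConfig, dict]:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}") from exc
    try:
        f = data["fields"]
        fieldcfg = FieldConfig(
            n_arcs=int(f["n_arcs"]),
            coplanar=bool(f["coplanar"]),
            prescription=float(f["prescription_gy"]),
        )
        geometries = {
            name: StructureGeometry(
                name=name,
                volume_cm3=float(s["volume_cm3"]),
                distance_mm=np.asarray(s["distance_mm"], dtype=float),
                volume_fraction=np.asarray(s["volume_fraction"], dtype=float),
                in_field_fraction=float(s["in_field_fraction"]),
            )
            for name, s in data["structures"].items()
        }
    except KeyError as exc:
        raise ValueError(f"{path}: missing field {exc}") from exc
    return str(data.get("patient_id", path.stem)), fieldcfg, geometries


# ---------------------------------------------------------------------------
# Cohort directories
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir) -> None:
    """One geometry JSON + DVH CSV per patient, truth.json kept separate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(cohort.config)
    cfg["true_beta"] = np.asarray(cfg["true_beta"]).tolist()
    cfg["kernel"] = vars(cohort.config.kernel)
    meta = {"schema_version": SCHEMA_VERSION, "config": cfg, "config_hash": config_hash(cfg)}
    (outdir / "cohort_config.json").write_text(json.dumps(meta, indent=1))
    for pat in cohort.patients:
        write_geometry_json(
            outdir / f"{pat.id}_geometry.json", pat.id, pat.field, pat.geometries
        )
        write_dvh_csv(outdir / f"{pat.id}_dvh.csv", pat.dvhs)
    if cohort.synthetic and cohort.patients:
        truth = cohort_truth(cohort)
        payload = {
            "true_beta": truth["true_beta"].tolist(),
            "predictor_names": list(truth["predictor_names"]),
            "noise_sd": truth["noise_sd"],
            "latent_scores": {
                pid: {org: s.tolist() for org, s in organs.items()}
                for pid, organs in truth["latent_scores"].items()
            },
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def read_cohort_plans(cohort_dir) -> list:
    """Load (patient_id, field, geometries, curves) tuples from a cohort dir."""
    cohort_dir = Path(cohort_dir)
    plans = []
    for geo_path in sorted(cohort_dir.glob("*_geometry.json")):
        pid, fieldcfg, geometries = read_geometry_json(geo_path)
        dvh_path = cohort_dir / f"{pid}_dvh.csv"
        curves = read_dvh_csv(dvh_path) if dvh_path.exists() else {}
        plans.append((pid, fieldcfg, geometries, curves))
    return plans


# ---------------------------------------------------------------------------
# Model archive (JSON)
# ---------------------------------------------------------------------------


def _pca_to_dict(pca: CurvePCA) -> dict:
    return {
        "params": pca.get_params(),
        "mean": pca.mean_.tolist(),
        "components": pca.components_.tolist(),
        "explained_variance": pca.explained_variance_.tolist(),
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }


def _pca_from_dict(d: dict) -> CurvePCA:
    pca = CurvePCA(**d["params"])
    pca.mean_ = np.asarray(d["mean"], dtype=float)
    pca.components_ = np.asarray(d["components"], dtype=float).reshape(
        -1, pca.mean_.size
    )
    pca.explained_variance_ = np.asarray(d["explained_variance"], dtype=float)
    pca.explained_variance_ratio_ = np.asarray(
        d["explained_variance_ratio"], dtype=float
    )
    pca.n_components_ = pca.components_.shape[0]
    return pca


def save_models(models: dict, path, extra_meta: dict | None = None) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "meta": extra_meta or {},
        "structures": {},
    }
    for name, m in models.items():
        payload["structures"][name] = {
            "params": m.get_params(),
            "structure_name": m.structure_name_,
            "grid": m.grid_.tolist(),
            "n_cases": m.n_cases_,
            "patient_ids": m.patient_ids_,
            "reference_prescription": m.reference_prescription_,
            "partition_index": m.partition_index_,
            "dvh_pca": _pca_to_dict(m.dvh_pca_),
            "ged_pca": _pca_to_dict(m.ged_pca_),
            "out_mean": m.out_mean_.tolist(),
            "out_sd": m.out_sd_.tolist(),
            "predictor_names": m.predictor_names_,
            "predictor_mean": m.predictor_mean_.tolist(),
            "predictor_scale": m.predictor_scale_.tolist(),
            "coef": m.coef_.tolist(),
            "coef_stderr": m.coef_stderr_.tolist(),
            "resid_stderr": m.resid_stderr_.tolist(),
        }
    payload["config_hash"] = config_hash(
        {n: s["params"] for n, s in payload["structures"].items()}
    )
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path) -> dict:
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported model archive schema version")
    models: dict = {}
    for name, s in data["structures"].items():
        m = StructureDVHModel(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in s["params"].items()
        })
        m.structure_name_ = s["structure_name"]
        m.grid_ = np.asarray(s["grid"], dtype=float)
        m.n_cases_ = int(s["n_cases"])
        m.patient_ids_ = list(s["patient_ids"])
        m.reference_prescription_ = float(s["reference_prescription"])
        m.partition_index_ = int(s["partition_index"])
        m.dvh_pca_ = _pca_from_dict(s["dvh_pca"])
        m.ged_pca_ = _pca_from_dict(s["ged_pca"])
        m.out_mean_ = np.asarray(s["out_mean"], dtype=float)
        m.out_sd_ = np.asarray(s["out_sd"], dtype=float)
        m.predictor_names_ = list(s["predictor_names"])
        m.predictor_mean_ = np.asarray(s["predictor_mean"], dtype=float)
        m.predictor_scale_ = np.asarray(s["predictor_scale"], dtype=float)
        n_params = len(m.predictor_names_) + 1
        m.coef_ = np.asarray(s["coef"], dtype=float).reshape(n_params, -1)
        m.coef_stderr_ = np.asarray(s["coef_stderr"], dtype=float).reshape(n_params, -1)
        m.resid_stderr_ = np.asarray(s["resid_stderr"], dtype=float)
        m.fits_ = []
        models[name] = m
    return models


# ---------------------------------------------------------------------------
# Packaged fixtures: published violation-pattern tables
# ---------------------------------------------------------------------------


def load_table5(which: str = "closed_loop") -> pd.DataFrame:
    """Packaged transcription of the published constraint-violation table.

    ``which`` is ``closed_loop`` (45-patient training set, columns
    ``clinical``/``closed_loop``) or ``open_loop`` (25-patient validation
    set, columns ``clinical``/``open_loop_1``/``open_loop_2``).  Only
    (patient, endpoint) cells violated in at least one plan set are listed;
    all other cells pass by convention.
    """
    if which not in ("closed_loop", "open_loop"):
        raise ValueError("which must be 'closed_loop' or 'open_loop'")
    ref = resources.files("kbplan.data") / f"table5_{which}.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def table5_value_frames(which: str = "closed_loop") -> dict:
    """Pivot the fixture into per-plan-set patient x endpoint value tables."""
    df = load_table5(which)
    value_cols = [c for c in df.columns if c not in ("patient", "endpoint")]
    return {
        col: df.pivot(index="patient", columns="endpoint", values=col)
        for col in value_cols
    }
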