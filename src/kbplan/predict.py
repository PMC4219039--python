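"""DVH prediction bands, automatic optimization objectives, name mapping.

A trained structure model predicts, for a new patient, a most-probable DVH
together with a pointwise band.  Optimization objectives for the inverse
planner are then placed just below the lower limit of the band, so the
optimizer is asked for a plan slightly better than what the knowledge base
deems most likely achievable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PredictedDVH",
    "DoseObjective",
    "ObjectiveRule",
    "predict_dvh",
    "generate_objectives",
    "map_ontology",
    "DEFAULT_SYNONYMS",
]


@dataclass
class PredictedDVH:
    """Most-probable DVH with pointwise lower/upper band (volumes in %)."""

    structure_name: str
    dose_gy: np.ndarray
    most_probable: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.most_probable = np.asarray(self.most_probable, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        tol = 1e-9
        if np.any(self.lower > self.most_probable + tol) or np.any(
            self.most_probable > self.upper + tol
        ):
            raise ValueError("band ordering violated: need lower <= most_probable <= upper")
        for curve in (self.lower, self.most_probable, self.upper):
            if np.any(np.diff(curve) > 1e-7):
                raise ValueError("band curves must be non-increasing")

    def dose_at_volume(self, curve: np.ndarray, volume_pct: float) -> float:
        """Smallest dose at which ``curve`` drops to ``volume_pct``."""
        idx = np.nonzero(curve <= volume_pct + 1e-9)[0]
        if idx.size == 0:
            return float(self.dose_gy[-1])
        i = int(idx[0])
        if i == 0 or curve[i] >= volume_pct:
            return float(self.dose_gy[i])
        v0, v1 = curve[i - 1], curve[i]
        frac = (v0 - volume_pct) / (v0 - v1)
        return float(self.dose_gy[i - 1] + frac * (self.dose_gy[i] - self.dose_gy[i - 1]))


@dataclass(frozen=True)
class DoseObjective:
    """A single optimization objective (point or line sample)."""

    structure: str
    kind: str  # upper_point | lower_point | line
    dose_gy: float
    volume_pct: float
    priority: int

    def __post_init__(self) -> None:
        if self.kind not in ("upper_point", "lower_point", "line"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.priority <= 0:
            raise ValueError("priority must be positive")


@dataclass(frozen=True)
class ObjectiveRule:
    """Per-structure template describing which objectives to generate.

    For OARs (``kind='upper_point'``) one point objective is placed per
    entry of ``volume_levels``, at the band's lower-limit dose minus
    ``margin_fraction`` x prescription.  ``kind='lower_point'`` states a
    target-coverage objective at the prescription-coverage level.
    ``kind='line'`` samples the lower limit on a volume grid.
    """

    structure: str
    kind: str = "upper_point"
    volume_levels: tuple = (10.0, 50.0, 90.0)
    priority: int = 50
    margin_fraction: float = 0.02
    coverage_volume_pct: float = 98.0
    coverage_dose_fraction: float = 0.95
    line_points: int = 20


def predict_dvh(model, case) -> PredictedDVH:
    """Predict the DVH band for one case (wrapper over the estimator)."""
    return model.predict(case)


def generate_objectives(
    pred: PredictedDVH,
    rule: ObjectiveRule,
    prescription: float,
) -> list[DoseObjective]:
    """Place optimization objectives below the band's lower limit.

    Every emitted OAR objective lies strictly below the lower prediction
    curve; volume levels where the lower-limit dose is already zero carry
    no achievable headroom and are skipped.
    """
    margin = rule.margin_fraction * prescription
    objectives: list[DoseObjective] = []
    if rule.kind == "lower_point":
        objectives.append(
            DoseObjective(
                structure=pred.structure_name,
                kind="lower_point",
                dose_gy=rule.coverage_dose_fraction * prescription,
                volume_pct=rule.coverage_volume_pct,
                priority=rule.priority,
            )
        )
        return objectives
    if rule.kind == "line":
        levels = np.linspace(2.0, 98.0, rule.line_points)
    else:
        levels = np.asarray(rule.volume_levels, dtype=float)
    for v in levels:
        if not 0 < v < 100:
            raise ValueError(f"volume level {v} outside (0, 100)")
        d_lower = pred.dose_at_volume(pred.lower, v)
        if d_lower <= 0:
            continue
        objectives.append(
            DoseObjective(
                structure=pred.structure_name,
                kind="upper_point" if rule.kind == "upper_point" else "line",
                dose_gy=max(d_lower - margin, 0.0),
                volume_pct=float(v),
                priority=rule.priority,
            )
        )
    return objectives


# ---------------------------------------------------------------------------
# Structure-name ontology matching
# ---------------------------------------------------------------------------

DEFAULT_SYNONYMS = {
    "liver-ptv": "normal_liver",
    "liver_ptv": "normal_liver",
    "normal liver": "normal_liver",
    "healthy liver": "normal_liver",
    "spine": "spinal_cord",
    "cord": "spinal_cord",
    "kidney l": "left_kidney",
    "kidney r": "right_kidney",
}


def _normalize(name: str) -> str:
    return "_".join(name.strip().lower().replace("-", " ").replace("_", " ").split())


def map_ontology(
    plan_structures: list[str],
    model_structures: list[str],
    synonyms: dict | None = None,
) -> tuple[dict, list[str]]:
    """Match plan structure names onto model structure names.

    Case-insensitive normalized exact matches are tried first, then the
    synonym table.  Returns the mapping and the unmatched plan names.
    Two plan structures resolving to the same model structure is an error.
    """
    syn = {_normalize(k): _normalize(v) for k, v in (synonyms or DEFAULT_SYNONYMS).items()}
    model_by_norm = {_normalize(m): m for m in model_structures}
    mapping: dict = {}
    unmatched: list[str] = []
    for name in plan_structures:
        norm = _normalize(name)
        target = model_by_norm.get(norm)
        if target is None and norm in syn:
            target = model_by_norm.get(syn[norm])
        if target is None:
            unmatched.append(name)
            continue
        clash = [p for p, m in mapping.items() if m == target]
        if clash:
            raise ValueError(
                f"ambiguous mapping: {clash[0]!r} and {name!r} both map to {target!r}"
            )
        mapping[name] = target
    return mapping, unmatched
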