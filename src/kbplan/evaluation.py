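"""Clinical-endpoint pass/fail analysis and cohort comparison.

Plans are audited against a fixed set of dose-volume objectives (8 by
default, covering spinal cord, kidneys, stomach, esophagus, normal liver
and target coverage).  A value passes when it satisfies its comparator;
a value exactly at the limit passes (strict-exceedance convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import DVHCurve, MetricKind, MetricSpec, dvh_metric

__all__ = [
    "ClinicalEndpoint",
    "PassFailReport",
    "DEFAULT_ENDPOINTS",
    "TABLE3_VARIANT_ENDPOINTS",
    "ENDPOINT_SETS",
    "evaluate_endpoints",
    "violation_summary",
    "compare_cohorts",
    "plan_metric_values",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClinicalEndpoint:
    """One dose-volume objective: metric, comparator and limit."""

    id: str
    structure: str
    metric: MetricSpec
    comparator: str  # "<" or ">"
    limit: float
    unit: str

    def __post_init__(self) -> None:
        if self.comparator not in ("<", ">"):
            raise ValueError("comparator must be '<' or '>'")

    def violated(self, value: float) -> bool:
        """Strict-exceedance convention: a value exactly at the limit passes."""
        if self.comparator == "<":
            return value > self.limit
        return value < self.limit


def _ep(id, structure, kind, thr, comp, limit, unit) -> ClinicalEndpoint:
    return ClinicalEndpoint(
        id=id,
        structure=structure,
        metric=MetricSpec(kind=MetricKind(kind), threshold=thr),
        comparator=comp,
        limit=limit,
        unit=unit,
    )


#: The 8 objectives used for clinical acceptance of the plans.
DEFAULT_ENDPOINTS = (
    _ep("spinal_cord_d1cc", "spinal_cord", "dose_at_volume_cm3", 1.0, "<", 45.0, "Gy"),
    _ep("left_kidney_v15", "left_kidney", "volume_pct_at_dose", 15.0, "<", 35.0, "%"),
    _ep("right_kidney_v15", "right_kidney", "volume_pct_at_dose", 15.0, "<", 35.0, "%"),
    _ep("stomach_v36", "stomach", "volume_pct_at_dose", 36.0, "<", 5.0, "%"),
    _ep("esophagus_d1cc", "esophagus", "dose_at_volume_cm3", 1.0, "<", 60.0, "Gy"),
    _ep("esophagus_v55", "esophagus", "volume_pct_at_dose", 55.0, "<", 30.0, "%"),
    _ep("normal_liver_v30", "normal_liver", "volume_pct_at_dose", 30.0, "<", 30.0, "%"),
    _ep("ptv_d98", "ptv", "dose_at_volume_pct", 98.0, ">", 90.0, "%"),
)

#: Variant with the stomach V35 / esophagus V30 thresholds used in the
#: summary tables; neither set is silently preferred.
TABLE3_VARIANT_ENDPOINTS = tuple(
    _ep("stomach_v35", "stomach", "volume_pct_at_dose", 35.0, "<", 5.0, "%")
    if e.id == "stomach_v36"
    else _ep("esophagus_v30", "esophagus", "volume_pct_at_dose", 30.0, "<", 30.0, "%")
    if e.id == "esophagus_v55"
    else e
    for e in DEFAULT_ENDPOINTS
)

ENDPOINT_SETS = {"default": DEFAULT_ENDPOINTS, "table3": TABLE3_VARIANT_ENDPOINTS}


@dataclass
class PassFailReport:
    """Per-patient, per-endpoint violation flags plus cohort totals."""

    values: pd.DataFrame  # patients x endpoints, NaN = not reported (pass)
    flags: pd.DataFrame  # same shape, boolean
    n_patients: int
    n_endpoints: int
    denominator: int

    @property
    def total_violations(self) -> int:
        return int(self.flags.to_numpy().sum())

    @property
    def patients_with_violations(self) -> int:
        return int((self.flags.sum(axis=1) > 0).sum())

    @property
    def max_simultaneous(self) -> int:
        return int(self.flags.sum(axis=1).max()) if len(self.flags) else 0

    @property
    def violation_rate_pct(self) -> float:
        return 100.0 * self.total_violations / self.denominator

    def violated_cells(self) -> set:
        arr = self.flags
        return {
            (pid, col)
            for pid in arr.index
            for col in arr.columns
            if bool(arr.loc[pid, col])
        }


def evaluate_endpoints(
    values: pd.DataFrame,
    endpoints=DEFAULT_ENDPOINTS,
    n_patients: int | None = None,
    denominator: int | None = None,
) -> PassFailReport:
    """Apply the endpoint set to a table of per-patient metric values.

    ``values`` has one row per patient and one column per endpoint id;
    missing cells (or endpoints absent from a violations-only table)
    count as passes.  ``n_patients`` sets the cohort size when the table
    lists only patients with reported values; ``denominator`` overrides
    the number of analyzed dose-volume points when reproducing published
    percentages.
    """
    by_id = {e.id: e for e in endpoints}
    unknown = [c for c in values.columns if c not in by_id]
    if unknown:
        raise ValueError(f"unknown endpoint columns: {unknown}")
    full = values.reindex(columns=[e.id for e in endpoints])
    flags = {}
    for e in endpoints:
        col = full[e.id].to_numpy(dtype=float)
        # strict exceedance, vectorized; NaN comparisons are False (= pass)
        with np.errstate(invalid="ignore"):
            flags[e.id] = col > e.limit if e.comparator == "<" else col < e.limit
    flags = pd.DataFrame(flags, index=full.index)
    n_pat = n_patients if n_patients is not None else len(full)
    if n_pat < len(full):
        raise ValueError("n_patients smaller than number of listed patients")
    nominal = n_pat * len(endpoints)
    denom = denominator if denominator is not None else nominal
    if denom != nominal:
        log.warning(
            "analyzed-points denominator %d differs from patients x endpoints = %d; "
            "using %d to reproduce published percentages",
            denom,
            nominal,
            denom,
        )
    return PassFailReport(
        values=full,
        flags=flags,
        n_patients=n_pat,
        n_endpoints=len(endpoints),
        denominator=denom,
    )


def violation_summary(clinical: PassFailReport, test: PassFailReport) -> dict:
    """Set algebra on violated (patient, endpoint) cells of two reports.

    ``net_improvement_pct`` is the clinical violation rate minus the test
    violation rate, each rounded to one decimal first (matching the way
    published rates are differenced).
    """
    if set(clinical.flags.index) != set(test.flags.index) or list(
        clinical.flags.columns
    ) != list(test.flags.columns):
        raise ValueError("mismatched patient sets or endpoint sets")
    c_cells = clinical.violated_cells()
    t_cells = test.violated_cells()
    shared = c_cells & t_cells
    return {
        "shared_failures": len(shared),
        "new_failures": len(t_cells - c_cells),
        "resolved_failures": len(c_cells - t_cells),
        "clinical_failures": len(c_cells),
        "test_failures": len(t_cells),
        "clinical_rate_pct": round(clinical.violation_rate_pct, 1),
        "test_rate_pct": round(test.violation_rate_pct, 1),
        "net_improvement_pct": round(
            round(clinical.violation_rate_pct, 1) - round(test.violation_rate_pct, 1), 1
        ),
    }


def plan_metric_values(
    curves: dict,
    endpoints=DEFAULT_ENDPOINTS,
    prescription: float | None = None,
) -> dict:
    """Evaluate each endpoint metric on one plan's DVH set.

    Endpoints whose structure is absent get NaN (treated as pass).  Target
    coverage endpoints with unit '%' are reported relative to the
    prescription (100 x dose / prescription).
    """
    out: dict = {}
    for e in endpoints:
        curve: DVHCurve | None = curves.get(e.structure)
        if curve is None:
            out[e.id] = float("nan")
            continue
        value = dvh_metric(curve, e.metric)
        if e.unit == "%" and e.metric.kind in (
            MetricKind.dose_at_volume_pct,
            MetricKind.dose_at_volume_cm3,
        ):
            if prescription is None:
                raise ValueError(
                    f"endpoint {e.id}: prescription needed for a relative dose"
                )
            value = 100.0 * value / prescription
        out[e.id] = float(value)
    return out


def compare_cohorts(values_a, values_b) -> dict:
    """Paired comparison of one metric between two plan sets.

    Reports mean +/- SD and range per set and a Wilcoxon signed-rank
    p-value on the paired differences (reported as 1 when all pairs tie).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length paired samples with n >= 2")
    diff = a - b
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    def _summary(x):
        return {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "min": float(x.min()),
            "max": float(x.max()),
        }
    return {
        "a": _summary(a),
        "b": _summary(b),
        "mean_difference": float(diff.mean()),
        "p_value": p,
        "n": int(a.size),
    }
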