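"""Cumulative dose-volume histograms and the standard plan-quality metrics.

A cumulative DVH gives, for each dose level d, the fraction of a structure's
volume receiving at least d.  It is the central object of knowledge-based
planning: models are trained on DVHs, predictions are DVHs, and clinical
acceptance is judged on scalar DVH metrics (D_x, V_x, mean dose, homogeneity
and conformity indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DVHCurve",
    "MetricKind",
    "MetricSpec",
    "build_dvh",
    "normalize_to_target_mean",
    "dvh_metric",
]

_MONOTONE_TOL = 1e-6


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve on a uniform dose grid.

    Parameters
    ----------
    structure_name : str
        Name of the anatomical structure.
    dose_gy : ndarray
        Strictly increasing dose grid in Gy, starting at 0.
    volume_pct : ndarray
        Cumulative relative volume in percent (0-100), non-increasing,
        with ``volume_pct[0] == 100`` (all volume receives >= 0 Gy).
    volume_cm3 : float
        Absolute structure volume, used for cm3 <-> % conversions.
    """

    structure_name: str
    dose_gy: np.ndarray
    volume_pct: np.ndarray
    volume_cm3: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_pct = np.asarray(self.volume_pct, dtype=float)
        if self.dose_gy.ndim != 1 or self.volume_pct.ndim != 1:
            raise ValueError("dose and volume must be 1-D")
        if self.dose_gy.size != self.volume_pct.size:
            raise ValueError("dose and volume grids differ in length")
        if self.dose_gy.size < 2:
            raise ValueError("a DVH needs at least two grid points")
        if self.dose_gy[0] != 0.0:
            raise ValueError("dose grid must start at 0 Gy")
        if np.any(np.diff(self.dose_gy) <= 0):
            raise ValueError("dose grid must be strictly increasing")
        if np.any(np.diff(self.volume_pct) > _MONOTONE_TOL):
            raise ValueError("cumulative volume must be non-increasing")
        if abs(self.volume_pct[0] - 100.0) > 100 * _MONOTONE_TOL:
            raise ValueError("volume at 0 Gy must be 100%")
        if self.volume_pct.min() < -_MONOTONE_TOL or self.volume_pct.max() > 100 + 100 * _MONOTONE_TOL:
            raise ValueError("volumes must lie in [0, 100]%")

    # -- scalar metrics -------------------------------------------------

    def volume_pct_at_dose(self, dose: float) -> float:
        """V_x: interpolated cumulative volume (%) at ``dose`` Gy."""
        return float(np.interp(dose, self.dose_gy, self.volume_pct))

    def dose_at_volume_pct(self, volume: float) -> float:
        """D_x%: smallest dose whose cumulative volume is <= ``volume``%.

        Linear interpolation between bins; on plateaus the tie is broken
        toward the lower dose.
        """
        if not 0.0 <= volume <= 100.0:
            raise ValueError("volume percentage outside [0, 100]")
        v = self.volume_pct
        d = self.dose_gy
        idx = np.nonzero(v <= volume + _MONOTONE_TOL)[0]
        if idx.size == 0:  # curve never drops to the requested level
            return float(d[-1])
        i = int(idx[0])
        if i == 0 or v[i] >= volume:
            return float(d[i])
        # interpolate on the segment (i-1, i) that brackets the level
        v0, v1 = v[i - 1], v[i]
        frac = (v0 - volume) / (v0 - v1)
        return float(d[i - 1] + frac * (d[i] - d[i - 1]))

    def dose_at_volume_cm3(self, volume_cm3: float) -> float:
        """D_xcm3 via the absolute structure volume."""
        if not np.isfinite(self.volume_cm3) or self.volume_cm3 <= 0:
            raise ValueError("absolute volume required for cm3 metrics")
        pct = 100.0 * volume_cm3 / self.volume_cm3
        return self.dose_at_volume_pct(min(pct, 100.0))

    def mean_dose(self) -> float:
        """Mean dose from the differential curve (trapezoidal integral)."""
        return float(np.trapezoid(self.volume_pct / 100.0, self.dose_gy))

    # -- transforms -----------------------------------------------------

    def rescale_dose(self, factor: float) -> "DVHCurve":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, dose_gy=self.dose_gy * factor)

    def resample(self, grid: np.ndarray) -> "DVHCurve":
        """Interpolate the curve onto a new dose grid (flat beyond range)."""
        grid = np.asarray(grid, dtype=float)
        vol = np.interp(grid, self.dose_gy, self.volume_pct)
        return replace(self, dose_gy=grid, volume_pct=vol)


class MetricKind(str, Enum):
    dose_at_volume_pct = "dose_at_volume_pct"
    dose_at_volume_cm3 = "dose_at_volume_cm3"
    volume_pct_at_dose = "volume_pct_at_dose"
    mean_dose = "mean_dose"
    homogeneity_index = "homogeneity_index"
    conformity_index = "conformity_index"


@dataclass(frozen=True)
class MetricSpec:
    """A scalar DVH metric: kind plus its threshold argument.

    ``threshold`` is the metric's argument (the x of D_x / V_x), in the
    units implied by the kind; it is unused for mean dose, HI and CI.
    """

    kind: MetricKind
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        k = MetricKind(self.kind)
        object.__setattr__(self, "kind", k)
        if k is MetricKind.dose_at_volume_pct and not 0 <= self.threshold <= 100:
            raise ValueError("volume percentage outside [0, 100]")
        if k in (MetricKind.dose_at_volume_cm3, MetricKind.volume_pct_at_dose):
            if not self.threshold >= 0:
                raise ValueError("threshold must be non-negative")


def build_dvh(
    dose_samples: Sequence[float],
    voxel_volume: float,
    bin_width: float = 0.05,
    structure_name: str = "",
    max_dose: float | None = None,
) -> DVHCurve:
    """Build a cumulative DVH from per-voxel dose samples.

    ``volume_pct(d)`` is 100 x the fraction of samples with dose >= d.
    The grid spans 0 to 110% of the maximum sample (or ``max_dose``).
    """
    samples = np.asarray(dose_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty structure")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = max_dose if max_dose is not None else 1.1 * float(samples.max())
    top = max(top, bin_width)
    n_bins = int(np.ceil(top / bin_width)) + 1
    grid = np.arange(n_bins + 1) * bin_width
    # fraction of samples >= each grid dose
    vol = 100.0 * (samples[None, :] >= grid[:, None] - _MONOTONE_TOL).mean(axis=1)
    return DVHCurve(
        structure_name=structure_name,
        dose_gy=grid,
        volume_pct=vol,
        volume_cm3=float(samples.size * voxel_volume),
    )


def normalize_to_target_mean(
    curves: Mapping[str, DVHCurve], target_name: str, prescription: float
) -> dict[str, DVHCurve]:
    """Rescale all dose axes so the target's mean dose equals the prescription.

    Mirrors the clinical convention of normalizing plans to the mean PTV
    dose: every structure's dose grid is multiplied by
    ``prescription / mean_dose(target)``.
    """
    if target_name not in curves:
        raise KeyError(f"target structure {target_name!r} not present")
    mean = curves[target_name].mean_dose()
    if mean <= 0:
        raise ValueError("target mean dose must be positive")
    factor = prescription / mean
    return {name: c.rescale_dose(factor) for name, c in curves.items()}


def dvh_metric(
    curve: DVHCurve,
    spec: MetricSpec,
    reference: DVHCurve | None = None,
    body_v95_cm3: float | None = None,
) -> float:
    """Evaluate a scalar metric on a DVH curve.

    For the conformity index the target curve (``reference``, supplying the
    target volume) and the absolute body volume receiving >= 95% of the
    prescription (``body_v95_cm3``) are required, since CI is not computable
    from the target DVH alone.
    """
    kind = MetricKind(spec.kind)
    if kind is MetricKind.dose_at_volume_pct:
        return curve.dose_at_volume_pct(spec.threshold)
    if kind is MetricKind.dose_at_volume_cm3:
        return curve.dose_at_volume_cm3(spec.threshold)
    if kind is MetricKind.volume_pct_at_dose:
        return curve.volume_pct_at_dose(spec.threshold)
    if kind is MetricKind.mean_dose:
        return curve.mean_dose()
    if kind is MetricKind.homogeneity_index:
        mean = curve.mean_dose()
        if mean <= 0:
            raise ValueError("mean dose must be positive for HI")
        return (curve.dose_at_volume_pct(5.0) - curve.dose_at_volume_pct(95.0)) / mean
    if kind is MetricKind.conformity_index:
        target = reference if reference is not None else curve
        if body_v95_cm3 is None:
            raise ValueError("conformity index needs the body V95 volume")
        if not np.isfinite(target.volume_cm3) or target.volume_cm3 <= 0:
            raise ValueError("conformity index needs the target volume")
        return body_v95_cm3 / target.volume_cm3
    raise ValueError(f"unknown metric kind {spec.kind}")
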