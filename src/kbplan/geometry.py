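"""Geometry-based expected dose (GED).

The GED assigns each sub-volume of a structure an expected dose based only
on its signed distance to the target surface and the beam arrangement, and
accumulates those doses into a DVH-shaped curve.  It is the geometric
feature the knowledge-based model regresses on: structures close to (or
overlapping) the target get GED curves close to the prescription step,
distant structures get low-dose curves.

The fall-off law of the commercial engine is not public; this module uses
exponential kernels with separate in-field and out-of-field decay rates.
All kernel parameters are configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dvh import DVHCurve

__all__ = [
    "KernelParams",
    "FieldConfig",
    "StructureGeometry",
    "GEDCurve",
    "ged_voxel_dose",
    "compute_ged",
    "split_in_out_field",
    "default_grid",
]

#: GED curves share the DVH container (same grid/monotonicity invariants).
GEDCurve = DVHCurve


@dataclass(frozen=True)
class KernelParams:
    """Exponential dose fall-off kernel.

    k_in / k_out are decay rates (1/mm) for sub-volumes inside and outside
    the beam aperture union; f_out is the out-of-field dose fraction at the
    target surface (scatter/leakage level).
    """

    k_in: float = 0.05
    k_out: float = 0.15
    f_out: float = 0.3

    def __post_init__(self) -> None:
        if self.k_in <= 0 or self.k_out <= 0:
            raise ValueError("kernel decay rates must be positive")
        if not 0 <= self.f_out <= 1:
            raise ValueError("f_out must lie in [0, 1]")


@dataclass(frozen=True)
class FieldConfig:
    """Arc arrangement and prescription of a plan."""

    n_arcs: int
    coplanar: bool
    prescription: float

    def __post_init__(self) -> None:
        if self.n_arcs < 1:
            raise ValueError("need at least one arc")
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")


@dataclass
class StructureGeometry:
    """Distance-to-target-surface summary of one structure.

    distance_mm / volume_fraction describe a histogram of signed distances
    from the structure's sub-volumes to the target surface (negative =
    inside the target).  in_field_fraction is the fraction of the
    structure's volume inside the union of beam apertures.
    """

    name: str
    volume_cm3: float
    distance_mm: np.ndarray
    volume_fraction: np.ndarray
    in_field_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.volume_cm3 <= 0:
            raise ValueError("structure volume must be positive")
        if self.distance_mm.size != self.volume_fraction.size:
            raise ValueError("distance and fraction arrays differ in length")
        if self.distance_mm.size and abs(self.volume_fraction.sum() - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")
        if self.distance_mm.size and self.volume_fraction.min() < 0:
            raise ValueError("volume fractions must be non-negative")
        if not 0 <= self.in_field_fraction <= 1:
            raise ValueError("in_field_fraction must lie in [0, 1]")


def default_grid(max_prescription: float = 60.0, n_points: int = 100) -> np.ndarray:
    """Uniform model dose grid from 0 to 110% of the maximum prescription."""
    return np.linspace(0.0, 1.1 * max_prescription, n_points)


def ged_voxel_dose(
    signed_distance: float | np.ndarray,
    in_field: bool,
    field: FieldConfig,
    kernel: KernelParams = KernelParams(),
) -> float | np.ndarray:
    """Expected dose (Gy) of a sub-volume at a signed distance to the target.

    Inside the target (distance <= 0) the expected dose is the prescription;
    outside it decays exponentially, with a reduced amplitude and faster
    decay out of field.
    """
    d = np.asarray(signed_distance, dtype=float)
    rx = field.prescription
    if in_field:
        dose = rx * np.exp(-kernel.k_in * np.maximum(d, 0.0))
    else:
        dose = np.where(
            d <= 0, rx, rx * kernel.f_out * np.exp(-kernel.k_out * np.maximum(d, 0.0))
        )
    if np.isscalar(signed_distance):
        return float(dose)
    return dose


def _voxel_doses_and_weights(
    geometry: StructureGeometry, field: FieldConfig, kernel: KernelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Point masses (dose, weight) from the distance histogram, splitting
    each bin into its in-field and out-of-field parts."""
    f = geometry.in_field_fraction
    dose_in = ged_voxel_dose(geometry.distance_mm, True, field, kernel)
    dose_out = ged_voxel_dose(geometry.distance_mm, False, field, kernel)
    doses = np.concatenate([np.atleast_1d(dose_in), np.atleast_1d(dose_out)])
    weights = np.concatenate(
        [geometry.volume_fraction * f, geometry.volume_fraction * (1.0 - f)]
    )
    return doses, weights


def compute_ged(
    geometry: StructureGeometry,
    field: FieldConfig,
    kernel: KernelParams = KernelParams(),
    grid: np.ndarray | None = None,
) -> GEDCurve:
    """Accumulate per-sub-volume expected doses into a cumulative GED curve."""
    if geometry.distance_mm.size == 0:
        raise ValueError("empty distance histogram")
    if grid is None:
        grid = default_grid(field.prescription)
    doses, weights = _voxel_doses_and_weights(geometry, field, kernel)
    vol = 100.0 * (weights[None, :] * (doses[None, :] >= grid[:, None] - 1e-12)).sum(axis=1)
    vol = np.clip(vol, 0.0, 100.0)
    vol[0] = 100.0
    return GEDCurve(
        structure_name=geometry.name,
        dose_gy=np.asarray(grid, dtype=float),
        volume_pct=vol,
        volume_cm3=geometry.volume_cm3,
    )


def split_in_out_field(
    geometry: StructureGeometry,
    field: FieldConfig,
    kernel: KernelParams = KernelParams(),
    ged_threshold: float = 0.2,
) -> tuple[float, float]:
    """Volume fractions whose GED dose is >=, resp. <, threshold x prescription.

    This is the partition the model uses: the high-GED region is modeled by
    PC regression, the low-GED region by a mean +/- SD model.
    """
    if not 0 < ged_threshold < 1:
        raise ValueError("ged_threshold must lie in (0, 1)")
    doses, weights = _voxel_doses_and_weights(geometry, field, kernel)
    cut = ged_threshold * field.prescription
    in_frac = float(weights[doses >= cut].sum())
    return in_frac, 1.0 - in_frac
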