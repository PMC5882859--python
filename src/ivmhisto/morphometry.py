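"""3D bone and suture volumetry and derived cellular-dynamics metrics.

New bone is the region bound between the old front (calcein blue,
Day 0) and the new front (tetracycline, Day 28) of each bone.  Per-slice
bound areas are computed from the manually segmented polylines, summed
over a standardized 50-slice (50 um at 1 um spacing) layer, and
converted to mm^3.  Osteocytes are counted inside the new-bone region
(boundary-inclusive: a cell sitting right on a labelled front counts),
and cell dynamics are normalized as cell density (count per mm^3 of new
bone) and fractional change dM = (M_D28 - M_D0) / M_D0 x 100 against
the Day-0 baseline of the same region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .geometry import RegionGeometry, SliceFronts  # noqa: F401  (re-export)
from .preprocess import BinaryMask
from .seed3d import SeedSet

__all__ = [
    "RegionGeometry",
    "VolumeReport",
    "CellMetrics",
    "slice_area_between_fronts",
    "suture_slice_area",
    "measure_volumes",
    "classify_osteocytes",
    "cell_density",
    "fractional_change",
    "cell_metrics",
    "DEFAULT_DEPTH_SLICES",
]

#: Standardized analysis depth: 50 slices at 1 um spacing = 50 um.
DEFAULT_DEPTH_SLICES = 50

_UM3_PER_MM3 = 1e9  # the single place where um^3 -> mm^3 conversion lives

#: Distance tolerance (px) for "right at the border line" inclusion.
BOUNDARY_TOL_PX = 0.5


def _close_between(old: np.ndarray, new: np.ndarray) -> list[tuple[float, float]]:
    """Ring of the region bound between two fronts (old + reversed new)."""
    return [tuple(p) for p in old] + [tuple(p) for p in new[::-1]]


def slice_area_between_fronts(
    old_front: np.ndarray,
    new_front: np.ndarray,
    pixel_size: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Area (um^2) of the region bound between two front polylines.

    The polygon is closed by joining corresponding polyline endpoints
    (equivalently, by the slice-frame edges when both fronts span the
    frame's transverse extent).  Identical fronts give zero; crossing
    fronts raise.
    """
    old = np.asarray(old_front, dtype=float)
    new = np.asarray(new_front, dtype=float)
    if old.shape[0] < 2 or new.shape[0] < 2:
        raise ValueError("degenerate front: need >= 2 vertices")
    if np.array_equal(old, new):
        return 0.0
    if LineString(old).crosses(LineString(new)):
        raise ValueError("fronts intersect")
    poly = Polygon(_close_between(old, new))
    if not poly.is_valid:
        poly = poly.buffer(0)
    dy, dx = pixel_size
    return float(poly.area) * dy * dx


def suture_slice_area(
    boundary: np.ndarray, pixel_size: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Area (um^2) enclosed by a closed suture-boundary outline."""
    boundary = np.asarray(boundary, dtype=float)
    if boundary.shape[0] < 3:
        raise ValueError("degenerate suture boundary: need >= 3 vertices")
    poly = Polygon(boundary)
    if not poly.is_valid:
        raise ValueError("self-intersecting suture boundary")
    dy, dx = pixel_size
    return float(poly.area) * dy * dx


@dataclass(frozen=True)
class VolumeReport:
    """New-bone and suture volumes of one region, in mm^3."""

    new_bone_frontal: float
    new_bone_parietal: float
    suture_volume: float
    n_slices: int
    depth_um: float

    @property
    def new_bone_total(self) -> float:
        return self.new_bone_frontal + self.new_bone_parietal


def _side_area(fronts: dict[str, np.ndarray], side: str, pixel_size) -> float:
    old_key, new_key = f"old_front_{side}", f"new_front_{side}"
    has_old, has_new = old_key in fronts, new_key in fronts
    if has_old != has_new:
        raise ValueError(f"slice has only one of {old_key}/{new_key}")
    if not has_old:
        return 0.0
    return slice_area_between_fronts(fronts[old_key], fronts[new_key], pixel_size)


def measure_volumes(
    geometry: RegionGeometry, depth_slices: int = DEFAULT_DEPTH_SLICES
) -> VolumeReport:
    """Sum per-slice bound areas over the analysis depth -> volumes in mm^3.

    Per-label areas of the first ``depth_slices`` slices are summed,
    multiplied by the z-spacing, and converted from um^3 to mm^3.
    """
    if geometry.n_slices < depth_slices:
        raise ValueError(
            f"geometry covers {geometry.n_slices} slices; {depth_slices} requested"
        )
    dz, dy, dx = geometry.voxel_size
    pixel_size = (dy, dx)
    a_frontal = a_parietal = a_suture = 0.0
    for s in geometry.slices[:depth_slices]:
        a_frontal += _side_area(s.fronts, "frontal", pixel_size)
        a_parietal += _side_area(s.fronts, "parietal", pixel_size)
        if "suture_boundary" in s.fronts:
            a_suture += suture_slice_area(s.fronts["suture_boundary"], pixel_size)
    return VolumeReport(
        new_bone_frontal=a_frontal * dz / _UM3_PER_MM3,
        new_bone_parietal=a_parietal * dz / _UM3_PER_MM3,
        suture_volume=a_suture * dz / _UM3_PER_MM3,
        n_slices=depth_slices,
        depth_um=depth_slices * dz,
    )


def _new_bone_polygons(s: SliceFronts) -> list[Polygon]:
    polys = []
    for side in ("frontal", "parietal"):
        old_key, new_key = f"old_front_{side}", f"new_front_{side}"
        if old_key in s.fronts and new_key in s.fronts:
            ring = _close_between(s.fronts[old_key], s.fronts[new_key])
            poly = Polygon(ring)
            if not poly.is_valid:
                poly = poly.buffer(0)
            if poly.area > 0:
                polys.append(poly)
    return polys


def classify_osteocytes(
    seeds: SeedSet,
    geometry: RegionGeometry,
    exclusion_mask: BinaryMask | None = None,
    boundary_tol: float = BOUNDARY_TOL_PX,
) -> int:
    """Count seeds lying inside the new-bone region of their slice.

    Inclusion is boundary-inclusive with a ``boundary_tol`` pixel
    tolerance (cells localizing right at the labelled front lines are
    included).  Seeds inside the optional exclusion mask (vessel walls,
    marrow cavities, old bone) are never counted; a seed on a slice
    without geometry is skipped with a warning.
    """
    polys_by_z: dict[int, list[Polygon]] = {
        s.z: _new_bone_polygons(s) for s in geometry.slices
    }
    count = 0
    skipped = 0
    for seed in seeds.seeds:
        z, y, x = seed.position
        zi = int(round(z))
        if exclusion_mask is not None:
            shape = exclusion_mask.shape
            vi = (
                min(max(zi, 0), shape[0] - 1),
                min(max(int(round(y)), 0), shape[1] - 1),
                min(max(int(round(x)), 0), shape[2] - 1),
            )
            if exclusion_mask.voxels[vi]:
                continue
        if zi not in polys_by_z:
            skipped += 1
            continue
        pt = Point(y, x)
        if any(poly.distance(pt) <= boundary_tol for poly in polys_by_z[zi]):
            count += 1
    if skipped:
        warnings.warn(
            f"{skipped} seed(s) on slices without geometry were skipped",
            stacklevel=2,
        )
    return count


def cell_density(count: int, volume_report: VolumeReport) -> float:
    """Osteocyte count per mm^3 of new bone."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if volume_report.new_bone_total <= 0:
        raise ValueError("no new bone: total new-bone volume is zero")
    return count / volume_report.new_bone_total


def fractional_change(m_d0: float, m_d28: float) -> float:
    """dM = (M_D28 - M_D0) / M_D0 x 100, the Day-0-normalized change (%)."""
    if m_d0 <= 0:
        raise ValueError("Day-0 baseline must be > 0")
    return (m_d28 - m_d0) / m_d0 * 100.0


@dataclass(frozen=True)
class CellMetrics:
    """Cellular-dynamics summary for one region."""

    osteocytes_in_new_bone: int
    cell_density_per_mm3: float
    normalized_incorporation_pct: float  # osteocytes / Day-0 cell count x 100
    population_change_pct: float  # dM of the total labelled population


def cell_metrics(
    osteocyte_count: int,
    volume_report: VolumeReport,
    d0_cell_count: int,
    d28_cell_count: int,
) -> CellMetrics:
    """Derive the per-region cellular-dynamics metrics."""
    if d0_cell_count <= 0:
        raise ValueError("Day-0 cell count must be > 0")
    return CellMetrics(
        osteocytes_in_new_bone=int(osteocyte_count),
        cell_density_per_mm3=cell_density(osteocyte_count, volume_report),
        normalized_incorporation_pct=osteocyte_count / d0_cell_count * 100.0,
        population_change_pct=fractional_change(d0_cell_count, d28_cell_count),
    )
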