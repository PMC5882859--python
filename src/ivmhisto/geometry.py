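"""Per-slice bone-front geometry: container, validation, and JSON IO.

Bone fronts are manually segmented in each z-slice (the tool consumes
polylines; it never infers anatomy).  Five labels are recognized:

* ``old_front_frontal`` / ``new_front_frontal`` — frontal-bone fronts at
  Day 0 (calcein blue) and Day 28 (tetracycline);
* ``old_front_parietal`` / ``new_front_parietal`` — same for the
  parietal bone;
* ``suture_boundary`` — closed outline of the coronal suture space.

Coordinates are 0-based ``(y, x)`` voxel indices in the frame of the
associated stack.  The JSON schema is::

    {"voxel_size": [dz, dy, dx],
     "slices": [{"z": 0, "fronts": {"old_front_frontal": [[y, x], ...],
                                    ...}}, ...]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = [
    "FRONT_LABELS",
    "POLYLINE_LABELS",
    "SliceFronts",
    "RegionGeometry",
    "read_geometry",
    "write_geometry",
]

POLYLINE_LABELS = (
    "old_front_frontal",
    "new_front_frontal",
    "old_front_parietal",
    "new_front_parietal",
)
FRONT_LABELS = POLYLINE_LABELS + ("suture_boundary",)


def _validate_polyline(label: str, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ValueError(f"degenerate front {label!r}: need >= 2 (y, x) vertices")
    if not np.isfinite(coords).all():
        raise ValueError(f"non-finite coordinate in front {label!r}")
    if label == "suture_boundary":
        if coords.shape[0] >= 3 and not Polygon(coords).is_valid:
            raise ValueError(f"self-intersecting boundary {label!r}")
    elif coords.shape[0] > 2:
        # 2-vertex polylines are simple by construction.
        if not LineString(coords).is_simple:
            raise ValueError(f"self-intersecting polyline {label!r}")
    return coords


@dataclass
class SliceFronts:
    """Labeled front polylines of one z-slice."""

    z: int
    fronts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.z = int(self.z)
        validated: dict[str, np.ndarray] = {}
        for label, coords in self.fronts.items():
            if label not in FRONT_LABELS:
                raise ValueError(f"unknown front label {label!r}")
            validated[label] = _validate_polyline(label, coords)
        self.fronts = validated


@dataclass
class RegionGeometry:
    """All segmented fronts of one imaged region, ordered by slice index."""

    slices: list[SliceFronts]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        zs = [s.z for s in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slice indices must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def slice_at(self, z: int) -> SliceFronts | None:
        for s in self.slices:
            if s.z == z:
                return s
        return None

    def subset(self, z_lo: int, z_hi: int) -> "RegionGeometry":
        """Slices with z_lo <= z < z_hi (used for block-wise volumetry)."""
        return RegionGeometry(
            [s for s in self.slices if z_lo <= s.z < z_hi], self.voxel_size
        )


def write_geometry(geometry: RegionGeometry, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "voxel_size": list(geometry.voxel_size),
        "slices": [
            {"z": s.z, "fronts": {k: np.asarray(v).tolist() for k, v in s.fronts.items()}}
            for s in geometry.slices
        ],
    }
    path.write_text(json.dumps(doc))
    return path


def read_geometry(path: str | Path, n_slices: int | None = None) -> RegionGeometry:
    """Read a region-geometry JSON file.

    Parameters
    ----------
    n_slices:
        When given (the z-extent of the associated stack), slice indices
        outside ``[0, n_slices)`` raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    doc = json.loads(path.read_text())
    slices = [SliceFronts(entry["z"], dict(entry["fronts"])) for entry in doc["slices"]]
    if n_slices is not None:
        bad = [s.z for s in slices if not 0 <= s.z < n_slices]
        if bad:
            raise ValueError(f"slice index out of stack range: {bad}")
    return RegionGeometry(slices, tuple(doc.get("voxel_size", (1.0, 1.0, 1.0))))
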