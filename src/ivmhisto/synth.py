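"""Synthetic two-photon scenes with exact ground truth.

Every pipeline stage is testable without microscope data: this module
renders multi-channel stacks of Gaussian-blob "cells" over an
exponential autofluorescence background, emits the true centroids and
counts, and builds analytic bone-front geometries (prisms/wedges) whose
volumes have a closed form.

The exponential background is deliberate: the seed detector's Tukey
fence models the cell surround as an exponential intensity distribution,
so in synthetic data that model assumption holds exactly (a Gaussian
background option exists to probe robustness).  Two channel profiles
emulate the study's populations: ``EGFP_like`` cells are dim (peak
8-bit intensities 20-25, the "rigorous contrast enhancement" case) and
``TDTOMATO_like`` cells are bright (120-240).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .morphometry import VolumeReport
from .geometry import RegionGeometry, SliceFronts
from .stacks_io import ChannelRole, GroundTruth, ImageStack, MultiChannelStack

__all__ = [
    "SynthParams",
    "SynthScene",
    "PairedRegion",
    "CHANNEL_PROFILES",
    "generate_cell_stack",
    "generate_bone_geometry",
    "generate_paired_study",
]

#: Default desk-scale stack: 50 um depth at 1 um spacing, 256 x 256 raster.
DEFAULT_SHAPE = (50, 256, 256)
DEFAULT_VOXEL_SIZE = (1.0, 400.0 / 512, 400.0 / 512)

#: Peak 8-bit intensities and background scale of the emulated channels.
CHANNEL_PROFILES: dict[str, dict] = {
    "EGFP_like": {
        "intensity_range": (20.0, 25.0),
        "background_mean": 2.0,
        "role": ChannelRole.EGFP,
    },
    "TDTOMATO_like": {
        "intensity_range": (120.0, 240.0),
        "background_mean": 4.0,
        "role": ChannelRole.TDTOMATO,
    },
}

# Grid placement: spacing (z, y, x) guarantees that any two cells are
# separated, in at least one axis, by more than the default local-max
# kernel half-width, so well-separated synthetic cells never merge.
_GRID_SPACING = (14, 14, 12)
_GRID_MARGIN = (8, 7, 7)
_JITTER = 1.5


@dataclass(frozen=True)
class SynthParams:
    """Study conditions of one synthetic channel.

    ``n_cells`` may be an integer or an inclusive ``(lo, hi)`` range
    sampled per scene; ``radius_range`` is the lateral Gaussian sigma of
    a cell in pixels (axial sigma is 0.75 of it); intensities are blob
    peak amplitudes on the 8-bit scale.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    n_cells: int | tuple[int, int] = (150, 400)
    radius_range: tuple[float, float] = (1.6, 2.6)
    intensity_range: tuple[float, float] = (120.0, 240.0)
    background_mean: float = 4.0
    background_model: str = "exponential"  # or "gaussian"
    crosstalk_coefficient: float = 0.0
    crosstalk_background_mean: float = 12.0
    channel_profile: str = "TDTOMATO_like"
    rng_seed: int = 0
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if min(self.shape) < 1:
            raise ValueError("shape entries must be positive")
        if self.radius_range[0] < 0.5:
            raise ValueError("cell radius must be >= 0.5 px")
        if self.intensity_range[1] > 255:
            raise ValueError("peak intensity exceeds the 8-bit range")
        if self.background_model not in ("exponential", "gaussian"):
            raise ValueError("background_model must be 'exponential' or 'gaussian'")
        if self.channel_profile not in CHANNEL_PROFILES:
            raise ValueError(f"unknown channel profile {self.channel_profile!r}")

    @classmethod
    def for_profile(cls, profile: str, **overrides) -> "SynthParams":
        """Parameters of an emulated channel (``EGFP_like``/``TDTOMATO_like``)."""
        spec = CHANNEL_PROFILES[profile]
        base = cls(
            intensity_range=spec["intensity_range"],
            background_mean=spec["background_mean"],
            channel_profile=profile,
        )
        return replace(base, **overrides) if overrides else base

    @property
    def role(self) -> ChannelRole:
        return CHANNEL_PROFILES[self.channel_profile]["role"]


@dataclass
class SynthScene:
    """One synthetic region: stack, ground truth, geometry, analytic volumes.

    ``stack`` is ``None`` for unrendered scenes (ground truth only),
    used by the paired-study generator at desk scale.
    """

    stack: MultiChannelStack | None
    truth: dict[ChannelRole, GroundTruth]
    geometry: RegionGeometry
    analytic_volumes: VolumeReport
    osteocyte_truth: GroundTruth | None = None
    params: SynthParams | None = None


def _grid_sites(shape: tuple[int, int, int]) -> np.ndarray:
    axes = []
    for n, spacing, margin in zip(shape, _GRID_SPACING, _GRID_MARGIN):
        hi = n - 1 - margin
        if hi < margin:
            return np.empty((0, 3))
        axes.append(np.arange(margin, hi + 1e-9, spacing, dtype=float))
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)


def _place_centers(
    shape: tuple[int, int, int], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Jittered-grid placement: non-overlapping, well-separated centres."""
    sites = _grid_sites(shape)
    if n > len(sites):
        raise ValueError(
            f"infeasible packing: {n} cells requested, {len(sites)} sites available "
            f"in shape {shape}"
        )
    chosen = sites[rng.choice(len(sites), size=n, replace=False)]
    jitter = rng.uniform(-_JITTER, _JITTER, size=chosen.shape)
    return chosen + jitter

def _render_cells(
    canvas: np.ndarray,
    centers: np.ndarray,
    sigmas: np.ndarray,
    amps: np.ndarray,
) -> None:
    nz, ny, nx = canvas.shape
    for (cz, cy, cx), (sz, sy, sx), amp in zip(centers, sigmas, amps):
        rz, ry, rx = (int(np.ceil(3 * s)) for s in (sz, sy, sx))
        z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 2)
        y0, y1 = max(0, int(cy) - ry), min(ny, int(cy) + ry + 2)
        x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 2)
        zg = (np.arange(z0, z1) - cz) / sz
        yg = (np.arange(y0, y1) - cy) / sy
        xg = (np.arange(x0, x1) - cx) / sx
        blob = amp * np.exp(
            -0.5
            * (
                zg[:, None, None] ** 2
                + yg[None, :, None] ** 2
                + xg[None, None, :] ** 2
            )
        )
        canvas[z0:z1, y0:y1, x0:x1] += blob


def _sample_n_cells(params: SynthParams, rng: np.random.Generator) -> int:
    if isinstance(params.n_cells, (tuple, list)):
        lo, hi = params.n_cells
        return int(rng.integers(lo, hi + 1))
    return int(params.n_cells)


def _background(
    params: SynthParams, shape, rng: np.random.Generator
) -> np.ndarray:
    if params.background_mean <= 0:
        return np.zeros(shape, dtype=np.float64)
    if params.background_model == "exponential":
        return rng.exponential(params.background_mean, size=shape)
    return np.clip(
        rng.normal(params.background_mean, params.background_mean / 2, size=shape),
        0,
        None,
    )


def generate_cell_stack(params: SynthParams) -> SynthScene:
    """Render one synthetic channel with exact ground-truth centroids.

    Cells are anisotropic Gaussian blobs at jittered-grid centres
    (non-overlapping, separated beyond the default local-max kernel),
    added to an exponential background; the result is quantized to
    8-bit.  With ``crosstalk_coefficient > 0`` a companion calcein-blue
    channel is rendered and ``coefficient x companion`` leaks into the
    target channel.  Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    n = _sample_n_cells(params, rng)
    centers = _place_centers(params.shape, n, rng)
    sig_lat = rng.uniform(*params.radius_range, size=n)
    sigmas = np.stack([0.75 * sig_lat, sig_lat, sig_lat], axis=1)
    amps = rng.uniform(*params.intensity_range, size=n)

    canvas = _background(params, params.shape, rng)
    _render_cells(canvas, centers, sigmas, amps)

    channels: dict[ChannelRole, ImageStack] = {}
    if params.crosstalk_coefficient > 0:
        companion = rng.exponential(
            params.crosstalk_background_mean, size=params.shape
        )
        canvas += params.crosstalk_coefficient * companion
        channels[ChannelRole.CALCEIN_BLUE] = ImageStack(
            np.clip(np.rint(companion), 0, 255).astype(np.uint8),
            params.voxel_size,
            ChannelRole.CALCEIN_BLUE,
        )
    voxels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    role = params.role
    channels[role] = ImageStack(voxels, params.voxel_size, role)
    stack = MultiChannelStack(channels, timepoint=params.timepoint)

    geometry, volumes = generate_bone_geometry(
        params.shape, voxel_size=params.voxel_size
    )
    truth = {
        role: GroundTruth(centers, channel=role, stack_shape=params.shape)
    }
    return SynthScene(
        stack=stack,
        truth=truth,
        geometry=geometry,
        analytic_volumes=volumes,
        params=params,
    )


# ---------------------------------------------------------------------------
# Analytic bone-front geometry


def _gap_profile(profile, n_slices: int) -> np.ndarray:
    if np.isscalar(profile):
        return np.full(n_slices, float(profile))
    lo, hi = profile
    if n_slices == 1:
        return np.array([float(lo)])
    return np.linspace(float(lo), float(hi), n_slices)


def default_old_offset(nx: int) -> float:
    """Default old-front offset: a quarter of the frame width per side."""
    return round(0.25 * nx)


def generate_bone_geometry(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    old_offset_px: float | None = None,
    new_offset_profile=10.0,
    parietal_offset_profile=None,
    frame_height_px: float | None = None,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    n_slices: int | None = None,
) -> tuple[RegionGeometry, VolumeReport]:
    """Straight/wedge bone fronts with closed-form volumes.

    The frontal bone's old front is a vertical line at
    ``x = old_offset_px``; its new front sits ``gap(z)`` pixels toward
    the suture, where the gap is a constant or a ``(start, end)``
    linearly varying profile over z (a prism or a wedge).  The parietal
    side mirrors this from the right edge.  The suture boundary is the
    rectangle between the two new fronts.  Returns the geometry and the
    analytic :class:`VolumeReport` (exact for these polygonal fronts).
    """
    nz, ny, nx = shape
    if old_offset_px is None:
        old_offset_px = default_old_offset(nx)
    n_slices = nz if n_slices is None else n_slices
    H = float(ny if frame_height_px is None else frame_height_px)
    dz, dy, dx = voxel_size
    gaps_f = _gap_profile(new_offset_profile, n_slices)
    gaps_p = _gap_profile(
        new_offset_profile if parietal_offset_profile is None else parietal_offset_profile,
        n_slices,
    )
    xf = float(old_offset_px)
    xp = float(nx - 1 - old_offset_px)
    if np.any(xf + gaps_f >= xp - gaps_p):
        raise ValueError("crossing profile: new fronts meet inside the suture")

    slices = []
    for i in range(n_slices):
        gf, gp = gaps_f[i], gaps_p[i]
        fronts = {
            "old_front_frontal": [[0.0, xf], [H, xf]],
            "new_front_frontal": [[0.0, xf + gf], [H, xf + gf]],
            "old_front_parietal": [[0.0, xp], [H, xp]],
            "new_front_parietal": [[0.0, xp - gp], [H, xp - gp]],
            "suture_boundary": [
                [0.0, xf + gf],
                [H, xf + gf],
                [H, xp - gp],
                [0.0, xp - gp],
            ],
        }
        slices.append(SliceFronts(i, fronts))
    geometry = RegionGeometry(slices, voxel_size)

    um3 = 1e-9  # mm^3 per um^3
    area_scale = H * dy * dx
    v_f = float(gaps_f.sum()) * area_scale * dz * um3
    v_p = float(gaps_p.sum()) * area_scale * dz * um3
    v_s = float(((xp - gaps_p) - (xf + gaps_f)).sum()) * area_scale * dz * um3
    volumes = VolumeReport(
        new_bone_frontal=v_f,
        new_bone_parietal=v_p,
        suture_volume=v_s,
        n_slices=n_slices,
        depth_um=n_slices * dz,
    )
    return geometry, volumes


# ---------------------------------------------------------------------------
# Paired D0/D28 study generator


@dataclass
class PairedRegion:
    """Ground-truth-linked Day-0 / Day-28 scenes of one region."""

    region_id: str
    d0: SynthScene
    d28: SynthScene
    realized: dict = field(default_factory=dict)  # per-region realized effects

    @property
    def d0_count(self) -> int:
        return next(iter(self.d0.truth.values())).count

    @property
    def d28_count(self) -> int:
        return next(iter(self.d28.truth.values())).count

    @property
    def osteocyte_count(self) -> int:
        return self.d28.osteocyte_truth.count if self.d28.osteocyte_truth else 0


def _place_in_new_bone(
    geometry_gaps: tuple[float, float, float],  # (xf, gap, H)
    n: int,
    nz: int,
    rng: np.random.Generator,
) -> np.ndarray:
    xf, gap, H = geometry_gaps
    z = rng.uniform(0, nz - 1, size=n)
    y = rng.uniform(0, H, size=n)
    x = rng.uniform(xf, xf + gap, size=n)
    return np.stack([z, y, x], axis=1)


def generate_paired_study(
    effects: dict | None = None,
    n_regions: int = 8,
    rng_seed: int = 0,
    noise_sd_pct: float = 10.0,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    profile: str = "TDTOMATO_like",
    n_cells_baseline: tuple[int, int] = (80, 160),
    render: bool = False,
    place_cells: bool = True,
) -> list[PairedRegion]:
    """Paired D0/D28 scenes realizing requested effects in expectation.

    ``effects`` may contain (all in percent, defaults 0):

    * ``bone_growth_pct`` — D28 new-bone volume relative to the region's
      D0 baseline volume;
    * ``expansion_pct`` — growth of the labelled cell population;
    * ``incorporation_pct`` — osteocytes at D28 as a fraction of the
      D0 cell count.

    Region-level gaussian noise of ``noise_sd_pct`` percentage points is
    added to each effect independently per region.  With
    ``render=False`` (the default) scenes carry ground truth and
    geometry but no voxel data, which keeps whole-study simulations at
    desk scale; ``render=True`` additionally renders the image stacks.
    """
    effects = dict(effects or {})
    unknown = set(effects) - {"bone_growth_pct", "expansion_pct", "incorporation_pct"}
    if unknown:
        raise ValueError(f"unknown effects: {sorted(unknown)}")
    growth = float(effects.get("bone_growth_pct", 0.0))
    expansion = float(effects.get("expansion_pct", 0.0))
    incorporation = float(effects.get("incorporation_pct", 0.0))
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")

    rng = np.random.default_rng(rng_seed)
    role = CHANNEL_PROFILES[profile]["role"]
    nz, ny, nx = shape
    regions: list[PairedRegion] = []
    for i in range(n_regions):
        g0 = float(rng.uniform(8.0, 14.0))
        eps = rng.normal(0.0, noise_sd_pct, size=3) if noise_sd_pct > 0 else np.zeros(3)
        growth_i = growth + eps[0]
        expansion_i = expansion + eps[1]
        incorporation_i = max(0.0, incorporation + eps[2] * (incorporation > 0))
        g28 = g0 * (1.0 + growth_i / 100.0)
        if g28 <= 0:
            raise ValueError("inconsistent effects: negative D28 bone volume")

        n0 = int(rng.integers(*n_cells_baseline))
        n28 = max(0, int(round(n0 * (1.0 + expansion_i / 100.0))))
        n_osteo = int(round(n0 * incorporation_i / 100.0))

        scenes = {}
        for tp, gap, n_cells in (("D0", g0, n0), ("D28", g28, n28)):
            geometry, volumes = generate_bone_geometry(
                shape, new_offset_profile=gap, voxel_size=DEFAULT_VOXEL_SIZE
            )
            params = SynthParams.for_profile(
                profile,
                shape=shape,
                n_cells=n_cells,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                timepoint=tp,
            )
            if render:
                scene = generate_cell_stack(params)
                scene.geometry, scene.analytic_volumes = geometry, volumes
            else:
                if place_cells:
                    centers = _place_centers(shape, n_cells, np.random.default_rng(params.rng_seed))
                    truth = {role: GroundTruth(centers, channel=role, stack_shape=shape)}
                else:
                    truth = {role: GroundTruth(np.empty((0, 3)), channel=role)}
                scene = SynthScene(
                    stack=None,
                    truth=truth,
                    geometry=geometry,
                    analytic_volumes=volumes,
                    params=params,
                )
            scenes[tp] = scene

        if n_osteo > 0:
            xf = default_old_offset(nx)
            centers = _place_in_new_bone((xf, g28, float(ny)), n_osteo, nz, rng)
            scenes["D28"].osteocyte_truth = GroundTruth(
                centers, channel=role, stack_shape=shape
            )
        regions.append(
            PairedRegion(
                region_id=f"region_{i:02d}",
                d0=scenes["D0"],
                d28=scenes["D28"],
                realized={
                    "bone_growth_pct": growth_i,
                    "expansion_pct": expansion_i if n0 else 0.0,
                    "incorporation_pct": incorporation_i,
                },
            )
        )
    return regions
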