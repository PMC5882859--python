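"""Automatic 3D seed detection and cell counting.

Each cell is reduced to a single "seed": the 3D point at the centre of
its fluorescence peak.  Detection is a two-step process on a
standardized stack:

1. the stack is segmented (moment threshold), contrast-enhanced to a
   fixed saturated fraction, smoothed with a 3D mean filter, and local
   maxima are located with an anisotropic maximum filter sized to the
   expected cell extent;
2. local-maxima clusters are labelled (26-connectivity) and kept only if
   their peak enhanced intensity exceeds an outlier threshold ``T``
   derived from the intensity statistics of the cell surroundings via a
   Tukey fence, ``T = Q3 + 1.5 (Q3 - Q1)``, with the quartiles taken
   from an exponential model of the background: a surround with mean
   intensity ``x`` has ``Q1 = x ln(4/3)`` and ``Q3 = x ln 4``, so
   ``T = x (ln 4 + 1.5 ln 3)``.

The surround histogram is gated from below ("step background gating"):
the cutoff is the background mode of the raw stack plus an offset that
steps up with the stack's signal level, so heavily enhanced dim stacks
do not drag excessive background noise into the surround statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import (
    BinaryMask,
    DEFAULT_SATURATED_FRACTION,
    apply_contrast,
    contrast_bounds,
    moment_threshold,
)
from .stacks_io import ChannelRole, ImageStack, MultiChannelStack

__all__ = [
    "Seed",
    "SeedSet",
    "DetectionParams",
    "StepGating",
    "TukeyThreshold",
    "TUKEY_FENCE_FACTOR",
    "mean_filter_3d",
    "local_maxima_3d",
    "background_mode",
    "step_gate_cutoff",
    "surround_mean",
    "tukey_threshold",
    "detect_seeds",
    "count_cells",
    "read_seeds",
    "write_seeds",
]

#: T / x for an exponential surround: ln 4 + 1.5 ln 3.
TUKEY_FENCE_FACTOR = math.log(4.0) + 1.5 * math.log(3.0)


@dataclass(frozen=True)
class StepGating:
    """Signal-level-dependent offsets above the background mode.

    ``steps`` is an ordered list of ``(signal_level_upper_bound,
    offset_above_mode)``; the first step whose upper bound covers the
    stack's signal level supplies the offset.
    """

    steps: tuple[tuple[float, float], ...] = ((64, 2), (128, 4), (255, 8))

    def __post_init__(self) -> None:
        steps = tuple((float(b), float(o)) for b, o in self.steps)
        bounds = [b for b, _ in steps]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("step upper bounds must be strictly increasing")
        if any(o < 0 for _, o in steps):
            raise ValueError("step offsets must be >= 0")
        object.__setattr__(self, "steps", steps)


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the seed detector.

    ``localmax_kernel`` is ``(kx, ky, kz)`` half-widths in pixels of the
    local-maximum neighbourhood and should match the expected cell
    extent per axis (the default mirrors a ~10 um cell at ~0.78 um/px
    laterally and 1 um axially).
    """

    mean_kernel: int = 1
    localmax_kernel: tuple[int, int, int] = (6, 8, 10)  # (kx, ky, kz)
    saturated_fraction: float = DEFAULT_SATURATED_FRACTION
    surround_radius: int = 3
    gating_steps: StepGating = field(default_factory=StepGating)

    def __post_init__(self) -> None:
        if self.mean_kernel < 1:
            raise ValueError("kernel must be >= 1")
        if len(self.localmax_kernel) != 3 or any(k < 1 for k in self.localmax_kernel):
            raise ValueError("localmax_kernel entries must be >= 1")
        if self.surround_radius < 1:
            raise ValueError("surround_radius must be >= 1")


@dataclass(frozen=True)
class TukeyThreshold:
    """Exponential-model quartiles and the resulting outlier fence."""

    x: float
    q1: float
    q3: float
    threshold: float


@dataclass(frozen=True)
class Seed:
    """One detected cell centre (fractional voxel coordinates)."""

    position: tuple[float, float, float]  # (z, y, x)
    peak_intensity: float


@dataclass
class SeedSet:
    """Detected seeds of one channel, with detection provenance."""

    seeds: list[Seed]
    channel: ChannelRole | None = None
    params: DetectionParams | None = None

    @property
    def count(self) -> int:
        return len(self.seeds)

    def positions(self) -> np.ndarray:
        """(n, 3) array of (z, y, x) seed positions."""
        if not self.seeds:
            return np.empty((0, 3))
        return np.array([s.position for s in self.seeds], dtype=float)

    @classmethod
    def concat(cls, *sets: "SeedSet") -> "SeedSet":
        seeds = [s for ss in sets for s in ss.seeds]
        channel = sets[0].channel if sets else None
        return cls(seeds, channel=channel)


def mean_filter_3d(stack: ImageStack, kernel: int = 1) -> ImageStack:
    """3D mean filter over a ``(2*kernel + 1)**3`` box, edge-clamped.

    Returns a float32 stack (intensity scale preserved); the default
    1-pixel kernel averages the 27-voxel neighbourhood.
    """
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    out = ndimage.uniform_filter(
        stack.voxels.astype(np.float32), size=2 * kernel + 1, mode="nearest"
    )
    return ImageStack(out, stack.voxel_size, stack.channel, stack.bit_depth)


def local_maxima_3d(stack: ImageStack, kernel: tuple[int, int, int]) -> BinaryMask:
    """Mark voxels equal to the maximum over an anisotropic neighbourhood.

    ``kernel`` is ``(kx, ky, kz)`` half-widths; a voxel is marked iff its
    value equals the neighbourhood maximum and is > 0.  Plateaus produce
    connected marked clusters (merged later by 26-connected labelling).
    """
    kx, ky, kz = kernel
    if min(kx, ky, kz) < 1:
        raise ValueError("localmax kernel entries must be >= 1")
    size = (2 * kz + 1, 2 * ky + 1, 2 * kx + 1)
    v = stack.voxels
    mx = ndimage.maximum_filter(v, size=size, mode="nearest")
    return BinaryMask((v == mx) & (v > 0), stack.voxel_size)


def background_mode(raw: ImageStack) -> int:
    """Most frequent intensity of the raw stack (ties toward lower)."""
    v = raw.voxels
    if not np.issubdtype(v.dtype, np.integer):
        raise ValueError("background mode is defined on the raw integer stack")
    return int(np.bincount(v.ravel()).argmax())


def step_gate_cutoff(
    mode: float,
    signal_level: float,
    gating: StepGating,
    max_value: int = 255,
) -> float:
    """Gating cutoff = background mode + the step offset for this signal level.

    The first step whose upper bound covers ``signal_level`` supplies
    the offset; a signal beyond the last bound falls back to the last
    step's offset with a warning.  The cutoff is clamped to the dynamic
    range.
    """
    if not gating.steps:
        raise ValueError("empty step gating table")
    offset = None
    for bound, off in gating.steps:
        if signal_level <= bound:
            offset = off
            break
    if offset is None:
        warnings.warn(
            f"signal level {signal_level} exceeds the last gating bound; "
            "using the last step's offset",
            stacklevel=2,
        )
        offset = gating.steps[-1][1]
    return float(np.clip(mode + offset, 0, max_value))


def surround_mean(
    enhanced: ImageStack,
    cell_mask: BinaryMask,
    surround_radius: int = 3,
    cutoff: float = 0.0,
) -> float:
    """Mean intensity of the gated cell-surrounding shell.

    The surround is the euclidean dilation of the segmented cell areas
    by ``surround_radius`` pixels, minus the cell areas themselves.
    Only surround voxels with intensity >= ``cutoff`` enter the mean
    (step background gating); if the gate empties the shell, the ungated
    surround mean is returned.
    """
    if surround_radius < 1:
        raise ValueError("surround_radius must be >= 1")
    mask = cell_mask.voxels
    if not mask.any():
        raise ValueError("no cells segmented")
    r = int(surround_radius)
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    ball = (grid**2).sum(axis=0) <= r * r
    surround = ndimage.binary_dilation(mask, structure=ball) & ~mask
    vals = enhanced.voxels[surround].astype(np.float64)
    gated = vals[vals >= cutoff]
    chosen = gated if gated.size else vals
    return float(chosen.mean())


def tukey_threshold(x: float) -> TukeyThreshold:
    """Tukey outlier fence for an exponential surround with mean ``x``.

    ``Q1 = x ln(4/3)``, ``Q3 = x ln 4`` (exponential quartiles), and
    ``T = Q3 + 1.5 (Q3 - Q1) = x (ln 4 + 1.5 ln 3)``.  Homogeneous of
    degree 1 in ``x``.
    """
    if x < 0:
        raise ValueError("surround mean must be >= 0")
    q1 = x * math.log(4.0 / 3.0)
    q3 = x * math.log(4.0)
    t = q3 + 1.5 * (q3 - q1)
    return TukeyThreshold(x=float(x), q1=q1, q3=q3, threshold=t)


def detect_seeds(
    stack: MultiChannelStack | ImageStack,
    channel: ChannelRole | str | None = None,
    params: DetectionParams | None = None,
) -> SeedSet:
    """Run the full two-step seed detection on one channel.

    Pipeline: moment segmentation of cell areas -> standardized contrast
    enhancement -> 3D mean filter -> anisotropic local maxima ->
    26-connected component labelling -> Tukey-fence filter of components
    by peak enhanced intensity -> intensity-weighted centroid of each
    surviving component.  Deterministic for fixed input and parameters;
    an empty result (count 0) is valid.
    """
    if params is None:
        params = DetectionParams()
    if isinstance(stack, MultiChannelStack):
        if channel is None:
            raise ValueError("channel must be given for a multi-channel stack")
        role = ChannelRole.parse(channel)
        if role not in stack:
            raise KeyError(f"channel {role.value!r} not present in stack")
        raw = stack[role]
    else:
        raw = stack
        role = raw.channel

    if raw.voxels.min() == raw.voxels.max():  # constant stack: nothing to detect
        return SeedSet([], channel=role, params=params)
    _, cell_mask = moment_threshold(raw)
    lo, hi = contrast_bounds(raw, params.saturated_fraction)
    if hi <= lo:
        return SeedSet([], channel=role, params=params)
    enhanced = apply_contrast(raw, lo, hi)
    smoothed = mean_filter_3d(enhanced, params.mean_kernel)
    maxima = local_maxima_3d(smoothed, params.localmax_kernel)

    mode = background_mode(raw)
    signal_level = float(raw.voxels.max())
    cutoff_raw = step_gate_cutoff(
        mode, signal_level, params.gating_steps, raw.max_value
    )
    # Express the raw-scale cutoff on the enhanced scale.
    cutoff = float(np.clip((cutoff_raw - lo) * raw.max_value / (hi - lo), 0, raw.max_value))
    if cell_mask.voxels.any():
        x = surround_mean(enhanced, cell_mask, params.surround_radius, cutoff)
    else:
        x = float(enhanced.voxels.mean())
    fence_threshold = tukey_threshold(x).threshold

    labels, n = ndimage.label(maxima.voxels, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return SeedSet([], channel=role, params=params)
    # Representative intensity of a component: its peak in the smoothed
    # enhanced image (the image the maxima were found in).  Using the
    # unsmoothed peak instead admits single-voxel background outliers —
    # exactly the non-cell clusters the fence is meant to discard.
    idx = np.arange(1, n + 1)
    weights = smoothed.voxels.astype(np.float64)
    peaks = ndimage.maximum(weights, labels, idx)
    keep = np.flatnonzero(peaks > fence_threshold)
    if keep.size == 0:
        return SeedSet([], channel=role, params=params)
    centroids = ndimage.center_of_mass(weights, labels, idx[keep])
    seeds = [
        Seed(position=(float(cz), float(cy), float(cx)), peak_intensity=float(pk))
        for (cz, cy, cx), pk in zip(centroids, peaks[keep])
    ]
    seeds.sort(key=lambda s: s.position)
    return SeedSet(seeds, channel=role, params=params)


def count_cells(seeds: SeedSet) -> int:
    """Number of detected cells (the seed count)."""
    return seeds.count


def write_seeds(seeds: SeedSet, path) -> None:
    pos = seeds.positions()
    df = pd.DataFrame(
        {
            "z": pos[:, 0] if len(pos) else [],
            "y": pos[:, 1] if len(pos) else [],
            "x": pos[:, 2] if len(pos) else [],
            "peak_intensity": [s.peak_intensity for s in seeds.seeds],
        }
    )
    df.to_csv(path, index=False)


def read_seeds(path, channel: ChannelRole | str | None = None) -> SeedSet:
    df = pd.read_csv(path)
    missing = {"z", "y", "x"} - set(df.columns)
    if missing:
        raise ValueError(f"seeds CSV missing columns {sorted(missing)}")
    peaks = df["peak_intensity"] if "peak_intensity" in df else pd.Series([0.0] * len(df))
    seeds = [
        Seed((float(r.z), float(r.y), float(r.x)), float(p))
        for r, p in zip(df.itertuples(), peaks)
    ]
    return SeedSet(seeds, channel=ChannelRole.parse(channel) if channel else None)
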