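"""Containers and file IO for multi-channel two-photon z-stacks.

An :class:`ImageStack` is one channel's 3D voxel array in ``(z, y, x)``
order with a physical voxel size in micrometres; a
:class:`MultiChannelStack` groups the channels acquired from one region at
one imaging session.  Stacks are written as OME-TIFF (axes ``CZYX``,
physical sizes and channel names in the OME metadata) so any standard
viewer can open them, and read back bit-exactly.

Manually segmented bone-front geometry and ground-truth centroid tables
are inputs, not computed quantities; their readers live here too
(geometry IO is implemented in :mod:`ivmhisto.geometry` and re-exported).
"""

from __future__ import annotations

import enum
import xml.etree.ElementTree as _ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .geometry import RegionGeometry, read_geometry, write_geometry  # noqa: F401

__all__ = [
    "ChannelRole",
    "ImageStack",
    "MultiChannelStack",
    "GroundTruth",
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_VOXEL_SIZE_UM",
    "read_stack",
    "write_stack",
    "read_truth",
    "write_truth",
    "read_geometry",
    "write_geometry",
    "RegionGeometry",
]

#: Lateral pixel size assumed when a file carries no calibration: a
#: 400 x 400 um field of view rastered at 512 x 512 pixels.
DEFAULT_PIXEL_SIZE_UM = 400.0 / 512
#: (dz, dy, dx) in um: 1 um z-interval, default lateral calibration.
DEFAULT_VOXEL_SIZE_UM = (1.0, DEFAULT_PIXEL_SIZE_UM, DEFAULT_PIXEL_SIZE_UM)


class ChannelRole(enum.Enum):
    """Spectral role of an acquisition channel.

    SHG is the label-free collagen signal delineating mineralized bone;
    EGFP marks Prx1+ skeletal stem cells; tdTomato their lineage-traced
    progeny; calcein blue and tetracycline are the fluorochromes staining
    the old and new bone mineralization fronts.
    """

    SHG = "shg"
    EGFP = "egfp"
    TDTOMATO = "tdtomato"
    CALCEIN_BLUE = "calcein_blue"
    TETRACYCLINE = "tetracycline"

    @classmethod
    def parse(cls, value: "ChannelRole | str") -> "ChannelRole":
        if isinstance(value, ChannelRole):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown channel role {value!r}; expected one of "
                f"{[r.value for r in cls]}"
            ) from None


def _infer_bit_depth(dtype: np.dtype) -> int | None:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    return None


@dataclass
class ImageStack:
    """One channel's 3D intensity array with physical voxel size.

    Parameters
    ----------
    voxels:
        ``(z, y, x)`` array.  Stored stacks are ``uint8`` or ``uint16``;
        floating-point arrays are allowed for in-memory intermediates
        (e.g. the output of the 3D mean filter) and then carry the bit
        depth of their integer source.
    voxel_size:
        ``(dz, dy, dx)`` in micrometres, all strictly positive.
    channel:
        Optional :class:`ChannelRole` of the stack.
    bit_depth:
        8 or 16; inferred from the dtype when omitted.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    channel: ChannelRole | None = None
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a 3D (z, y, x) array with >= 1 slice")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (dz, dy, dx)")
        if self.bit_depth is None:
            self.bit_depth = _infer_bit_depth(self.voxels.dtype)
        if self.bit_depth not in (8, 16):
            raise ValueError(
                f"unsupported dtype/bit depth {self.voxels.dtype}/{self.bit_depth}; "
                "stacks are 8- or 16-bit"
            )
        if self.voxels.size and float(self.voxels.min()) < 0:
            raise ValueError("negative intensities are not allowed")
        if np.issubdtype(self.voxels.dtype, np.integer):
            if float(self.voxels.max(initial=0)) > self.max_value:
                raise ValueError("intensity exceeds the stack's bit depth")
        if self.channel is not None:
            self.channel = ChannelRole.parse(self.channel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Top of the dynamic range (255 for 8-bit, 65535 for 16-bit)."""
        return (1 << self.bit_depth) - 1  # type: ignore[operator]

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        """Same calibration/role/bit depth, new voxel data."""
        return ImageStack(voxels, self.voxel_size, self.channel, self.bit_depth)


@dataclass
class MultiChannelStack:
    """All channels acquired from one region at one timepoint.

    Member stacks must share shape and voxel size; there is at most one
    stack per :class:`ChannelRole` (enforced by the mapping key).
    """

    channels: dict[ChannelRole, ImageStack]
    region_id: str = ""
    timepoint: str | None = None  # "D0" or "D28"

    def __post_init__(self) -> None:
        self.channels = {ChannelRole.parse(k): v for k, v in self.channels.items()}
        if not self.channels:
            raise ValueError("empty channel mapping")
        shapes = {s.shape for s in self.channels.values()}
        sizes = {s.voxel_size for s in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel stacks differ in shape: {shapes}")
        if len(sizes) > 1:
            raise ValueError(f"channel stacks differ in voxel size: {sizes}")
        if self.timepoint is not None and self.timepoint not in ("D0", "D28"):
            raise ValueError("timepoint must be 'D0' or 'D28'")
        for role, stack in self.channels.items():
            stack.channel = role

    def __getitem__(self, role: ChannelRole | str) -> ImageStack:
        return self.channels[ChannelRole.parse(role)]

    def __contains__(self, role: ChannelRole | str) -> bool:
        return ChannelRole.parse(role) in self.channels

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).voxel_size


@dataclass
class GroundTruth:
    """True cell centroids for one channel of a synthetic (or annotated) stack."""

    centroids: np.ndarray  # (n, 3) float, (z, y, x) voxel coordinates
    channel: ChannelRole | None = None
    stack_shape: tuple[int, int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        if self.channel is not None:
            self.channel = ChannelRole.parse(self.channel)
        if self.stack_shape is not None:
            hi = np.asarray(self.stack_shape, dtype=float)
            if self.centroids.size and (
                (self.centroids < 0).any() or (self.centroids > hi - 1).any()
            ):
                raise ValueError("centroid outside stack bounds")

    @property
    def count(self) -> int:
        return int(self.centroids.shape[0])


# ---------------------------------------------------------------------------
# TIFF IO


def write_stack(stack: MultiChannelStack, path: str | Path) -> Path:
    """Write a multi-channel stack as OME-TIFF (lossless, metadata-complete).

    Channels are stored along the ``C`` axis in :class:`ChannelRole`
    declaration order; channel names and the physical voxel size go into
    the OME metadata so :func:`read_stack` (or any OME-aware tool)
    recovers them.
    """
    path = Path(path)
    roles = [r for r in ChannelRole if r in stack.channels]
    data = np.stack([stack.channels[r].voxels for r in roles])
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": [r.value for r in roles]},
        },
    )
    return path


def _parse_ome(xml: str) -> tuple[tuple[float, float, float] | None, list[str]]:
    """Extract (dz, dy, dx) and channel names from OME-XML, if present."""
    root = _ET.fromstring(xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pixels = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    voxel_size = None
    names: list[str] = []
    if pixels is not None:
        sx = pixels.get("PhysicalSizeX")
        sy = pixels.get("PhysicalSizeY")
        sz = pixels.get("PhysicalSizeZ")
        if sx and sy and sz:
            voxel_size = (float(sz), float(sy), float(sx))
        for ch in pixels.findall("ome:Channel" if ns else "Channel", ns):
            names.append(ch.get("Name") or "")
    return voxel_size, names


def read_stack(
    path: str | Path,
    channel_map: Mapping[int, ChannelRole | str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    region_id: str = "",
    timepoint: str | None = None,
) -> MultiChannelStack:
    """Read a multi-page TIFF / OME-TIFF into a :class:`MultiChannelStack`.

    Parameters
    ----------
    channel_map:
        For an OME-TIFF with a ``C`` axis, maps channel index -> role
        (defaults to the channel names stored in the file).  For a plain
        multi-page TIFF (pages = z-slices), maps page index -> role;
        pages sharing a role are stacked in order.
    voxel_size:
        ``(dz, dy, dx)`` override in um.  Required when the file carries
        no calibration.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        If no voxel size is available ("voxel size unknown"), pages have
        inconsistent shapes, or the channel map is incomplete.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_size, meta_names = (None, [])
        if tf.ome_metadata:
            meta_size, meta_names = _parse_ome(tf.ome_metadata)

    if voxel_size is None:
        voxel_size = meta_size
    if voxel_size is None:
        raise ValueError(f"voxel size unknown for {path}; pass voxel_size=")

    channels: dict[ChannelRole, np.ndarray] = {}
    if "C" in axes:
        # Normalize to (C, Z, Y, X).
        order = [axes.index(a) for a in "CZYX" if a in axes]
        data = np.transpose(data, order)
        if data.ndim == 3:  # single z-slice per channel
            data = data[:, None]
        if channel_map is None:
            if len(meta_names) != data.shape[0] or not all(meta_names):
                raise ValueError("no channel names in file; pass channel_map=")
            channel_map = {i: meta_names[i] for i in range(data.shape[0])}
        for idx, role in channel_map.items():
            channels[ChannelRole.parse(role)] = data[int(idx)]
    else:
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"cannot interpret TIFF axes {axes!r} as a z-stack")
        if channel_map is None:
            if len(meta_names) == 1 and meta_names[0]:
                channel_map = {i: meta_names[0] for i in range(data.shape[0])}
            else:
                raise ValueError("plain TIFF without channel names; pass channel_map=")
        by_role: dict[ChannelRole, list[int]] = {}
        for idx, role in channel_map.items():
            by_role.setdefault(ChannelRole.parse(role), []).append(int(idx))
        for role, pages in by_role.items():
            channels[role] = data[sorted(pages)]

    stacks = {
        role: ImageStack(arr, voxel_size, role) for role, arr in channels.items()
    }
    return MultiChannelStack(stacks, region_id=region_id, timepoint=timepoint)


# ---------------------------------------------------------------------------
# Ground-truth centroid tables


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(truth.centroids, columns=["z", "y", "x"])
    df.to_csv(path, index=False)
    return path


def read_truth(
    path: str | Path,
    channel: ChannelRole | str | None = None,
    stack_shape: tuple[int, int, int] | None = None,
) -> GroundTruth:
    df = pd.read_csv(path)
    missing = {"z", "y", "x"} - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth CSV missing columns {sorted(missing)}")
    return GroundTruth(
        df[["z", "y", "x"]].to_numpy(dtype=float),
        channel=ChannelRole.parse(channel) if channel is not None else None,
        stack_shape=stack_shape,
    )
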