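"""Calibrated multi-channel image stacks and physical-unit conversion.

A two-photon or confocal acquisition is represented as a
:class:`CalibratedStack`: one 3-D ``(z, y, x)`` intensity grid per channel,
plus the voxel dimensions in micrometres and a mapping from channel index to
its biological role (``glia``, ``vessel``, ``aqp4`` or ``nuclei``).
Intensities are kept in native integer units at load time — downstream
filters such as a minimum mean intensity are absolute levels, so no
normalisation is ever applied on read.

Calibration precedence is: explicit argument > OME metadata > error.  A stack
without known voxel size would silently corrupt every µm³ output, so it is
rejected.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("gliavasc")

VALID_ROLES = ("glia", "vessel", "aqp4", "nuclei")


class CalibrationError(ValueError):
    """No voxel calibration available for a stack that needs one."""


@dataclasses.dataclass(frozen=True)
class VoxelSize:
    """Voxel dimensions in µm: ``dx``/``dy`` per pixel, ``dz`` per z-step."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel dimensions must be > 0, got {self}")

    @property
    def volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dx * self.dy * self.dz

    @property
    def area_xy(self) -> float:
        """In-plane pixel area in µm²."""
        return self.dx * self.dy

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)


#: Two-photon intravital calibration used throughout as the default.
TWO_PHOTON_VOXEL = VoxelSize(0.144, 0.144, 0.988)


@dataclasses.dataclass
class CalibratedStack:
    """Multi-channel 3-D stack with voxel calibration.

    ``channels`` maps channel index -> ``(z, y, x)`` integer array; all
    channels share one shape.  ``channel_roles`` maps channel index ->
    role string.
    """

    channels: dict[int, np.ndarray]
    channel_roles: dict[int, str]
    voxel: VoxelSize
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a stack needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        for idx, role in self.channel_roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"unknown role {role!r} for channel {idx}")
            if idx not in self.channels:
                raise ValueError(f"role given for missing channel {idx}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def max_native(self) -> int:
        return (1 << self.bit_depth) - 1

    def channel_by_role(self, role: str) -> np.ndarray:
        """Return the first channel carrying ``role``."""
        for idx in sorted(self.channel_roles):
            if self.channel_roles[idx] == role:
                return self.channels[idx]
        raise KeyError(f"no channel with role {role!r}")

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles.values()


def volume_um3(voxel_count: int, voxel: VoxelSize) -> float:
    """Physical volume of ``voxel_count`` voxels, exactly count × dx·dy·dz."""
    if voxel_count < 0:
        raise ValueError("voxel_count must be non-negative")
    return voxel_count * voxel.volume


def voxels_for_volume(volume: float, voxel: VoxelSize) -> float:
    """Number of voxels (fractional) corresponding to a µm³ volume."""
    return volume / voxel.volume


def _dtype_for_depth(bit_depth: int):
    return np.uint8 if bit_depth == 8 else np.uint16


def write_stack(stack: CalibratedStack, path: str | Path) -> Path:
    """Write an OME-TIFF with voxel calibration and channel roles embedded.

    The round trip ``read_stack(write_stack(s))`` is bit-exact and preserves
    both calibration and the channel-role mapping (roles are stored as OME
    channel names).
    """
    path = Path(path)
    indices = sorted(stack.channels)
    dtype = _dtype_for_depth(stack.bit_depth)
    data = np.stack([stack.channels[i] for i in indices], axis=1).astype(dtype)
    names = [stack.channel_roles.get(i, f"channel{i}") for i in indices]
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": stack.voxel.dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.voxel.dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.voxel.dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )
    logger.info("write_stack: %s shape=%s channels=%d", path, stack.shape, len(indices))
    return path


def _voxel_from_ome(tif: tifffile.TiffFile) -> VoxelSize | None:
    meta = None
    if tif.ome_metadata:
        try:
            meta = tifffile.xml2dict(tif.ome_metadata)
        except Exception:  # pragma: no cover - malformed XML
            return None
    if meta is None:
        return None
    try:
        images = meta["OME"]["Image"]
        if isinstance(images, list):
            images = images[0]
        px = images["Pixels"]
        return VoxelSize(
            float(px["PhysicalSizeX"]),
            float(px["PhysicalSizeY"]),
            float(px["PhysicalSizeZ"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def _roles_from_ome(tif: tifffile.TiffFile) -> dict[int, str]:
    roles: dict[int, str] = {}
    if not tif.ome_metadata:
        return roles
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        images = meta["OME"]["Image"]
        if isinstance(images, list):
            images = images[0]
        chans = images["Pixels"]["Channel"]
        if isinstance(chans, dict):
            chans = [chans]
        for i, ch in enumerate(chans):
            name = ch.get("Name")
            if name in VALID_ROLES:
                roles[i] = name
    except (KeyError, TypeError):
        pass
    return roles


def read_stack(
    path: str | Path,
    voxel: VoxelSize | None = None,
    roles: Mapping[int, str] | None = None,
) -> CalibratedStack:
    """Read a TIFF / OME-TIFF as a calibrated stack.

    Parameters
    ----------
    path:
        TIFF file whose series is interpretable as ``(z, y, x)`` or
        ``(z, c, y, x)`` (any axis order reported by the file is normalised).
    voxel:
        Explicit calibration; overrides any OME metadata.  If neither is
        available, a sidecar YAML file ``<path>.voxel.yaml`` with keys
        ``dx, dy, dz`` (µm) is consulted before failing.
    roles:
        Channel-role override; otherwise roles stored as OME channel names
        are used.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        file_voxel = _voxel_from_ome(tif)
        file_roles = _roles_from_ome(tif)

    # Normalise to (z, c, y, x)
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if data.ndim == 2:
        data = data[np.newaxis, np.newaxis]
    elif data.ndim == 3:
        # plane-major pages map to z; a pure CYX series becomes one z-plane
        if axes.startswith("C") and "Z" not in axes:
            data = data[np.newaxis]
        else:
            data = data[:, np.newaxis]
    elif data.ndim == 4:
        order = [axes.index(a) for a in "ZCYX" if a in axes]
        if len(order) != 4:
            raise ValueError(f"cannot interpret axes {axes!r} as (z, c, y, x)")
        data = np.transpose(data, order)
    else:
        raise ValueError(f"cannot interpret {data.ndim}-D data as a stack")

    if voxel is None:
        voxel = file_voxel
    if voxel is None:
        sidecar = path.with_suffix(path.suffix + ".voxel.yaml")
        if sidecar.exists():
            d = yaml.safe_load(sidecar.read_text())
            voxel = VoxelSize(float(d["dx"]), float(d["dy"]), float(d["dz"]))
    if voxel is None:
        raise CalibrationError(
            f"{path} carries no calibration; pass voxel= or provide a sidecar"
        )

    if data.dtype == np.uint16 or data.max(initial=0) > 255:
        bit_depth = 16
    else:
        bit_depth = 8

    role_map = dict(file_roles)
    if roles:
        role_map.update({int(k): v for k, v in roles.items()})

    channels = {
        i: np.ascontiguousarray(data[:, i]).astype(_dtype_for_depth(bit_depth))
        for i in range(data.shape[1])
    }
    logger.info(
        "read_stack: %s shape=%s channels=%d voxel=%s",
        path, channels[0].shape, len(channels), voxel.as_tuple(),
    )
    return CalibratedStack(
        channels=channels, channel_roles=role_map, voxel=voxel, bit_depth=bit_depth
    )
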