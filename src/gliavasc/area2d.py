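"""Immunopositive area on maximum-intensity projections.

Microglial (Iba1) and astrocytic (GFAP) reactivity in sections is scored as
the thresholded area, in µm², of the marker's maximum-intensity projection.
The published pairing of thresholds — intermeans "default" for Iba1,
maximum entropy for GFAP — is the default here, selectable per marker.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import VoxelSize
from .thresholding import apply_threshold, compute_threshold

#: marker -> threshold method, as published
MARKER_METHODS = {"iba1": "default", "gfap": "max_entropy"}


@dataclasses.dataclass(frozen=True)
class AreaResult:
    area_um2: float
    positive_pixels: int
    threshold_bin: int
    method: str
    projection_depth: int


def max_projection(channel: np.ndarray) -> np.ndarray:
    """Pixelwise maximum over z."""
    channel = np.asarray(channel)
    if channel.ndim != 3 or channel.shape[0] == 0:
        raise ValueError("need a non-empty (z, y, x) stack")
    return channel.max(axis=0)


def immunopositive_area(
    projection: np.ndarray,
    method: str,
    voxel: VoxelSize,
    projection_depth: int = 1,
) -> AreaResult:
    """Threshold a 2-D projection and report the positive area in µm²."""
    projection = np.asarray(projection)
    level = compute_threshold(projection, method)
    positive = int(apply_threshold(projection, level).sum())
    return AreaResult(
        area_um2=positive * voxel.area_xy,
        positive_pixels=positive,
        threshold_bin=level.bin,
        method=method,
        projection_depth=projection_depth,
    )


def run_area_pipeline(
    channel: np.ndarray, voxel: VoxelSize, method: str = "default"
) -> AreaResult:
    """Project a stack and measure the immunopositive area."""
    proj = max_projection(channel)
    return immunopositive_area(proj, method, voxel, projection_depth=channel.shape[0])
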