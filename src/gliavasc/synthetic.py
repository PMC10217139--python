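"""Synthetic calibrated stacks with exact ground truth.

No imaging data accompany the quantification pipelines, so every stage is
validated against simulated volumes that carry their own truth: tubular
vessels (correlated random walks running roughly axially, like penetrating
cortical vessels), ellipsoidal glial somata with thin processes, optional
endfoot co-coverage of a stated fraction of vessel voxels, an optional
one-voxel perivascular AQP4 shell over a stated fraction of the vessel
surface, spectral crosstalk from the vessel channel into the glial channel,
and additive Gaussian noise.

Intensities are two-level (background / per-structure foreground) before
noise; SNR is defined as (foreground − background) / noise SD.  All
randomness flows from one seed; the same seed reproduces the stack
bit-exactly.  Stored truth values are recomputable from the stored masks
via the same definitions the measurement modules use.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .aqp4 import SurfaceParams, extract_surface, surface_contact_percent
from .contact import contact_ratio
from .core_io import TWO_PHOTON_VOXEL, CalibratedStack, VoxelSize, volume_um3

_FACE6 = ndimage.generate_binary_structure(3, 1)


@dataclasses.dataclass(frozen=True)
class SynthParams:
    """Generator knobs; defaults emulate the two-photon acquisitions."""

    shape: tuple[int, int, int] = (128, 256, 256)  # (z, y, x)
    voxel: VoxelSize = TWO_PHOTON_VOXEL
    n_vessels: int = 2
    vessel_radius_um: float = 3.0
    n_cells: int = 8
    soma_volume_range_um3: tuple[float, float] = (400.0, 1100.0)
    soma_axis_ratio_max: float = 1.4
    n_processes_per_cell: int = 3
    process_radius_um: float = 0.35
    process_length_um: tuple[float, float] = (8.0, 15.0)
    coverage_fraction: float = 0.0
    endfoot_sheath_px: float = 2.0
    aqp4_surface_fraction: float = 0.0
    aqp4_thickness_um: float = 0.5
    crosstalk: float = 0.15
    background: float = 10.0
    glia_level: float = 220.0
    vessel_level: float = 90.0
    aqp4_level: float = 230.0
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction in [0, 1]")
        if not 0.0 <= self.aqp4_surface_fraction <= 1.0:
            raise ValueError("aqp4_surface_fraction in [0, 1]")
        if not 0.0 <= self.crosstalk < 1.0:
            raise ValueError("crosstalk in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for level in (self.background, self.glia_level, self.vessel_level,
                      self.aqp4_level):
            if not 0 <= level <= 255:
                raise ValueError("intensity levels must lie in [0, 255]")


@dataclasses.dataclass
class GroundTruth:
    """True masks and the values derived from them."""

    vessel_mask: np.ndarray
    glia_mask: np.ndarray
    soma_labels: np.ndarray          # 0 background, 1..n_cells
    aqp4_mask: np.ndarray
    true_soma_volumes_um3: list[float]
    true_contact_ratio_percent: float
    true_surface_contact_percent: float
    voxel: VoxelSize


def _physical_grid_distance(points: np.ndarray, shape, voxel: VoxelSize) -> np.ndarray:
    """EDT (µm) from every voxel to a rasterised point set."""
    grid = np.zeros(shape, dtype=bool)
    grid[points[:, 0], points[:, 1], points[:, 2]] = True
    return ndimage.distance_transform_edt(
        ~grid, sampling=(voxel.dz, voxel.dy, voxel.dx)
    )


def _vessel_paths(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Centreline voxels of all vessels (correlated walks, roughly axial)."""
    nz, ny, nx = params.shape
    v = params.voxel
    extent = np.array([nz * v.dz, ny * v.dy, nx * v.dx])
    margin = params.vessel_radius_um
    step = 0.3  # µm between centreline samples
    pts: list[np.ndarray] = []
    for _ in range(params.n_vessels):
        pos = np.array([
            0.0,
            rng.uniform(margin, extent[1] - margin),
            rng.uniform(margin, extent[2] - margin),
        ])
        direction = np.array([1.0, rng.normal(0, 0.15), rng.normal(0, 0.15)])
        direction /= np.linalg.norm(direction)
        while 0 <= pos[0] < extent[0]:
            if margin <= pos[1] <= extent[1] - margin and \
               margin <= pos[2] <= extent[2] - margin:
                pts.append(pos.copy())
            # curvature-bounded heading update, re-biased towards +z
            direction = direction + rng.normal(0, 0.05, 3)
            direction[0] = max(direction[0], 0.3)
            direction /= np.linalg.norm(direction)
            pos = pos + step * direction
            pos[1] = np.clip(pos[1], margin, extent[1] - margin)
            pos[2] = np.clip(pos[2], margin, extent[2] - margin)
    if not pts:
        raise ValueError("volume too small to fit any vessel path")
    coords = np.array(pts) / np.array([v.dz, v.dy, v.dx])
    coords = np.round(coords).astype(int)
    coords[:, 0] = np.clip(coords[:, 0], 0, nz - 1)
    coords[:, 1] = np.clip(coords[:, 1], 0, ny - 1)
    coords[:, 2] = np.clip(coords[:, 2], 0, nx - 1)
    return np.unique(coords, axis=0)


def _render_somata(
    params: SynthParams,
    dist_to_vessel: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[float]]:
    """Place and rasterise ellipsoidal somata; returns label volume + volumes.

    Centres keep clear of vessels and of each other, and stay far enough
    from the stack border that no soma is clipped.
    """
    nz, ny, nx = params.shape
    v = params.voxel
    extent = np.array([nz * v.dz, ny * v.dy, nx * v.dx])
    labels = np.zeros(params.shape, dtype=np.int16)
    volumes: list[float] = []
    placed: list[tuple[np.ndarray, float]] = []
    vmin, vmax = params.soma_volume_range_um3
    for cell in range(1, params.n_cells + 1):
        target = rng.uniform(vmin, vmax)
        ratios = rng.uniform(1.0, params.soma_axis_ratio_max, 3)
        base = (3.0 * target / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
        semi = base * ratios  # (az, ay, ax) µm
        rmax = float(semi.max())
        ok = False
        for _ in range(300):
            c = np.array([
                rng.uniform(rmax + 0.5, extent[0] - rmax - 0.5),
                rng.uniform(rmax + 0.5, extent[1] - rmax - 0.5),
                rng.uniform(rmax + 0.5, extent[2] - rmax - 0.5),
            ])
            cz, cy, cx = np.round(c / [v.dz, v.dy, v.dx]).astype(int)
            if dist_to_vessel[cz, cy, cx] < rmax + params.vessel_radius_um + 1.0:
                continue
            if any(np.linalg.norm(c - pc) < rmax + pr + 1.0 for pc, pr in placed):
                continue
            ok = True
            break
        if not ok:
            raise ValueError(
                f"could not place soma {cell}: volume too small or crowded"
            )
        placed.append((c, rmax))
        # rasterise within the bounding box only
        lo = np.floor((c - semi) / [v.dz, v.dy, v.dx]).astype(int)
        hi = np.ceil((c + semi) / [v.dz, v.dy, v.dx]).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, params.shape)
        zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        u = (
            ((zz * v.dz - c[0]) / semi[0]) ** 2
            + ((yy * v.dy - c[1]) / semi[1]) ** 2
            + ((xx * v.dx - c[2]) / semi[2]) ** 2
        )
        inside = u <= 1.0
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = cell
        volumes.append(volume_um3(int(inside.sum()), v))
    return labels, volumes


def _render_processes(
    params: SynthParams,
    soma_labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thin straight processes radiating from each soma centre."""
    mask = np.zeros(params.shape, dtype=bool)
    if params.n_processes_per_cell == 0 or params.n_cells == 0:
        return mask
    v = params.voxel
    scale = np.array([v.dz, v.dy, v.dx])
    r = params.process_radius_um
    centers = ndimage.center_of_mass(
        soma_labels > 0, soma_labels, np.arange(1, int(soma_labels.max()) + 1)
    )
    for c_vox in centers:
        c = np.array(c_vox) * scale
        for _ in range(params.n_processes_per_cell):
            d = rng.normal(0, 1, 3)
            d /= np.linalg.norm(d)
            length = rng.uniform(*params.process_length_um)
            ts = np.arange(0.0, length, 0.15)
            pts = c[None, :] + ts[:, None] * d[None, :]
            vox = np.round(pts / scale).astype(int)
            keep = np.all((vox >= 0) & (vox < np.array(params.shape)), axis=1)
            vox = vox[keep]
            if len(vox) == 0:
                continue
            lo = np.maximum(vox.min(axis=0) - np.ceil(r / scale).astype(int) - 1, 0)
            hi = np.minimum(
                vox.max(axis=0) + np.ceil(r / scale).astype(int) + 2, params.shape
            )
            local = np.zeros(tuple(hi - lo), dtype=bool)
            local[tuple((vox - lo).T)] = True
            d_loc = ndimage.distance_transform_edt(~local, sampling=tuple(scale))
            mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d_loc <= r
    return mask


def _z_band_selection(
    coords: np.ndarray, k: int, nz: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick ``k`` of the given voxels forming a contiguous (wrapping) z-band."""
    z0 = rng.integers(0, nz)
    key = (coords[:, 0] - z0) % nz
    order = np.lexsort((coords[:, 2], coords[:, 1], key))
    return coords[order[:k]]


def _endfoot_regions(
    params: SynthParams,
    vessel_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Glial endfoot mask: a z-band of vessel voxels plus an outer sheath."""
    coords = np.argwhere(vessel_mask)
    k = int(round(params.coverage_fraction * len(coords)))
    if k == 0:
        return np.zeros(params.shape, dtype=bool)
    chosen = _z_band_selection(coords, k, params.shape[0], rng)
    covered = np.zeros(params.shape, dtype=bool)
    covered[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    if params.endfoot_sheath_px > 0:
        v = params.voxel
        aspect = v.dz / v.dx
        d = ndimage.distance_transform_edt(
            ~covered, sampling=(aspect, 1.0, 1.0)
        )
        sheath = (d <= params.endfoot_sheath_px) & ~vessel_mask
        return covered | sheath
    return covered


def _aqp4_shell(
    params: SynthParams,
    vessel_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perivascular shell outside the vessel over a z-band of its surface.

    The shell is one voxel deep axially (the z step already exceeds the
    physical layer thickness) and ``aqp4_thickness_um`` deep laterally —
    a strictly one-lateral-voxel sheet would be ~0.14 µm thick, far below
    a real perivascular AQP4 layer, and its smoothed brightness would
    split into dim lateral walls versus bright axial caps.

    Surface voxels on the axial stack borders are never selected: wall
    created by clipping a vessel at the field of view is an acquisition
    artifact, and a shell painted there would have to sit outside the
    volume.
    """
    surface = extract_surface(vessel_mask)
    surface[0] = False
    surface[-1] = False
    coords = np.argwhere(surface)
    k = int(round(params.aqp4_surface_fraction * len(coords)))
    if k == 0:
        return np.zeros(params.shape, dtype=bool)
    chosen = _z_band_selection(coords, k, params.shape[0], rng)
    sel = np.zeros(params.shape, dtype=bool)
    sel[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    shell = ndimage.binary_dilation(sel, structure=_FACE6) & ~vessel_mask
    r = int(round(params.aqp4_thickness_um / params.voxel.dx)) - 1
    if r > 0:
        y, x = np.mgrid[-r : r + 1, -r : r + 1]
        disk = (y**2 + x**2 <= r**2)[np.newaxis]  # in-plane thickening only
        shell = ndimage.binary_dilation(shell, structure=disk) & ~vessel_mask
    return shell


def truth_from_masks(
    vessel_mask: np.ndarray,
    glia_mask: np.ndarray,
    aqp4_mask: np.ndarray,
    voxel: VoxelSize,
) -> tuple[float, float]:
    """(contact ratio %, surface-contact %) via the measurement definitions."""
    if vessel_mask.any() and glia_mask.any():
        contact = contact_ratio(glia_mask, vessel_mask).contact_ratio_percent
    elif vessel_mask.any():
        contact = 0.0
    else:
        contact = float("nan")
    if vessel_mask.any():
        surf = surface_contact_percent(
            vessel_mask, aqp4_mask, voxel, SurfaceParams()
        ).contact_percent
    else:
        surf = float("nan")
    return contact, surf


def generate_stack(params: SynthParams) -> tuple[CalibratedStack, GroundTruth]:
    """Render a two- or three-channel stack with its ground truth."""
    rng = np.random.default_rng(params.seed)
    v = params.voxel

    path_voxels = _vessel_paths(params, rng)
    dist = _physical_grid_distance(path_voxels, params.shape, v)
    vessel_mask = dist <= params.vessel_radius_um

    if params.n_cells > 0:
        soma_labels, soma_volumes = _render_somata(params, dist, rng)
        processes = _render_processes(params, soma_labels, rng)
    else:
        soma_labels = np.zeros(params.shape, dtype=np.int16)
        soma_volumes = []
        processes = np.zeros(params.shape, dtype=bool)

    endfeet = _endfoot_regions(params, vessel_mask, rng)
    glia_mask = (soma_labels > 0) | processes | endfeet
    aqp4_mask = _aqp4_shell(params, vessel_mask, rng)

    bg = params.background
    glia = np.full(params.shape, bg, dtype=np.float64)
    glia[glia_mask] = params.glia_level
    glia += params.crosstalk * (params.vessel_level - bg) * vessel_mask
    vessel = np.full(params.shape, bg, dtype=np.float64)
    vessel[vessel_mask] = params.vessel_level

    channels: dict[int, np.ndarray] = {}
    roles: dict[int, str] = {0: "glia", 1: "vessel"}
    planes = [glia, vessel]
    if params.aqp4_surface_fraction > 0 or aqp4_mask.any():
        aqp4 = np.full(params.shape, bg, dtype=np.float64)
        aqp4[aqp4_mask] = params.aqp4_level
        planes.append(aqp4)
        roles[2] = "aqp4"
    for i, plane in enumerate(planes):
        if params.noise_sd > 0:
            plane = plane + rng.normal(0.0, params.noise_sd, params.shape)
        channels[i] = np.clip(np.round(plane), 0, 255).astype(np.uint8)

    contact, surf = truth_from_masks(vessel_mask, glia_mask, aqp4_mask, v)
    stack = CalibratedStack(
        channels=channels, channel_roles=roles, voxel=v, bit_depth=8
    )
    truth = GroundTruth(
        vessel_mask=vessel_mask,
        glia_mask=glia_mask,
        soma_labels=soma_labels,
        aqp4_mask=aqp4_mask,
        true_soma_volumes_um3=soma_volumes,
        true_contact_ratio_percent=contact,
        true_surface_contact_percent=surf,
        voxel=v,
    )
    return stack, truth
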