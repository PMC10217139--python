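import numpy as np
import pytest
from scipy import ndimage

from gliavasc.core_io import VoxelSize
from gliavasc.soma import (
    ObjectRecord,
    ObjectTable,
    SomaParams,
    ellipsoid_element,
    filter_objects,
    mean_soma_volume,
    measure_objects,
    open_ellipsoid,
    run_soma_pipeline,
    segment_soma_mask,
    split_touching,
)

ISO = VoxelSize(1.0, 1.0, 1.0)


def ball(radius, shape=None, center=None):
    shape = shape or (2 * radius + 3,) * 3
    center = center or tuple(s // 2 for s in shape)
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    ) <= radius**2


# ----------------------------------------------------------------- opening

def test_opening_matches_structuring_element_oracle(rng):
    """EDT-based opening equals scipy's opening with the explicit element."""
    radii = (2.5, 2.5, 1.5)
    se = ellipsoid_element(radii)
    for _ in range(5):
        mask = ndimage.binary_dilation(
            rng.random((24, 24, 24)) > 0.98, iterations=2
        )
        expected = ndimage.binary_opening(mask, structure=se)
        np.testing.assert_array_equal(open_ellipsoid(mask, radii), expected)


def test_opening_identity_on_own_element():
    radii = (3.5, 3.5, 2.0)
    se = ellipsoid_element(radii)
    pad = np.pad(se, 2)
    np.testing.assert_array_equal(open_ellipsoid(pad, radii), pad)


def test_opening_removes_thin_tube_keeps_sphere():
    mask = ball(9, shape=(32, 48, 48), center=(16, 24, 24))
    tube = np.zeros_like(mask)
    tube[16, 24, :] = True  # 1-px tube through the sphere
    opened = open_ellipsoid(mask | tube, (5.5, 5.5, 2.0))
    assert not opened[16, 24, 2]          # tube gone outside the sphere
    assert opened[16, 24, 24]             # sphere centre retained
    # anti-extensive and nearly volume-preserving on the smooth sphere
    assert opened.sum() <= (mask | tube).sum()
    assert opened.sum() >= 0.85 * mask.sum()


def test_opening_anti_extensive_and_idempotent(rng):
    mask = ndimage.binary_dilation(rng.random((20, 30, 30)) > 0.97, iterations=3)
    radii = (2.5, 2.5, 1.5)
    once = open_ellipsoid(mask, radii)
    assert not (once & ~mask).any()
    np.testing.assert_array_equal(open_ellipsoid(once, radii), once)


def test_opening_empty_mask():
    assert open_ellipsoid(np.zeros((4, 4, 4), bool), (2, 2, 1)).sum() == 0


# --------------------------------------------------------------- watershed

def test_split_disjoint_spheres_two_labels():
    m = np.zeros((24, 24, 60), bool)
    m |= ball(7, shape=m.shape, center=(12, 12, 14))
    m |= ball(7, shape=m.shape, center=(12, 12, 45))
    labels = split_touching(m, h=1.0)
    assert labels.max() == 2
    counts = np.bincount(labels.ravel())[1:]
    assert counts[0] == counts[1] == ball(7).sum()


def test_split_touching_spheres_conserves_and_halves():
    m = np.zeros((30, 30, 48), bool)
    m |= ball(8, shape=m.shape, center=(15, 15, 16))
    m |= ball(8, shape=m.shape, center=(15, 15, 28))  # overlap 4 px
    labels = split_touching(m, h=1.0)
    np.testing.assert_array_equal(labels > 0, m)  # voxel-set conservation
    assert labels.max() == 2
    one_sphere = ball(8).sum()
    for lab in (1, 2):
        assert (labels == lab).sum() == pytest.approx(one_sphere, rel=0.10)


def test_split_empty_mask():
    assert split_touching(np.zeros((4, 4, 4), bool)).max() == 0


# ------------------------------------------------------------- measurement

def test_measure_single_voxel_volume(two_photon_voxel):
    labels = np.zeros((3, 3, 3), np.int32)
    labels[1, 1, 1] = 1
    table = measure_objects(labels, np.full(labels.shape, 50, np.uint8),
                            two_photon_voxel)
    assert table.records[0].volume_um3 == pytest.approx(0.020487168)
    assert table.records[0].mean_intensity == 50
    assert table.records[0].flatness >= 1.0


def test_measure_digital_ball_round_and_right_volume():
    m = ball(6)
    table = measure_objects(m.astype(np.int32), (m * 100).astype(np.uint8), ISO)
    rec = table.records[0]
    assert 1.0 <= rec.flatness <= 1.1
    assert rec.volume_um3 == pytest.approx(4 / 3 * np.pi * 6**3, rel=0.10)


def test_measure_prolate_ellipsoid_flatness():
    # semi-axes (12, 4, 1.0) µm rendered at 0.25 µm voxels: flatness ~ 4 / 1.0
    v = VoxelSize(0.25, 0.25, 0.25)
    z, y, x = np.ogrid[:37, :101, :13]
    m = (
        ((x - 6) * 0.25 / 1.0) ** 2
        + ((y - 50) * 0.25 / 12.0) ** 2
        + ((z - 18) * 0.25 / 4.0) ** 2
    ) <= 1
    table = measure_objects(m.astype(np.int32), (m * 90).astype(np.uint8), v)
    assert table.records[0].flatness == pytest.approx(4.0, rel=0.10)


def test_measure_shape_mismatch():
    with pytest.raises(ValueError):
        measure_objects(np.zeros((2, 2, 2), np.int32), np.zeros((2, 2, 3)), ISO)


# --------------------------------------------------------------- filtering

def fake_record(label, volume, intensity, flatness):
    return ObjectRecord(label, 1, volume, intensity, flatness, (0.0, 0.0, 0.0))


def test_filter_boundaries_inclusive_on_kept_side():
    params = SomaParams()
    table = ObjectTable(
        [
            fake_record(1, 199.9, 200, 1.2),   # volume just below the cut
            fake_record(2, 200.0, 60.0, 3.5),  # exactly at every boundary
            fake_record(3, 500.0, 59.9, 1.0),  # intensity below
            fake_record(4, 500.0, 100, 3.6),   # too flat
        ],
        ISO,
    )
    kept = filter_objects(table, params)
    assert [r.label for r in kept.records] == [2]


def test_filter_equals_predicate_scan_and_is_idempotent(rng):
    params = SomaParams()
    records = [
        fake_record(
            i,
            float(rng.uniform(0, 1500)),
            float(rng.uniform(0, 255)),
            float(rng.uniform(1, 6)),
        )
        for i in range(100)
    ]
    table = ObjectTable(records, ISO)
    kept = filter_objects(table, params)
    oracle = [
        r
        for r in records
        if r.volume_um3 >= 200 and r.mean_intensity >= 60 and r.flatness <= 3.5
    ]
    assert kept.records == oracle
    assert filter_objects(kept, params).records == kept.records


def test_filter_monotone_in_min_volume(rng):
    records = [
        fake_record(i, float(rng.uniform(0, 1500)), 200.0, 1.0) for i in range(60)
    ]
    table = ObjectTable(records, ISO)
    sizes = [
        len(filter_objects(table, SomaParams(min_volume_um3=v)))
        for v in (0, 100, 200, 400, 800)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_mean_soma_volume():
    table = ObjectTable([fake_record(1, 100, 99, 1), fake_record(2, 300, 99, 1)], ISO)
    assert mean_soma_volume(table) == 200
    assert mean_soma_volume(ObjectTable([fake_record(1, 42, 99, 1)], ISO)) == 42
    with pytest.raises(ValueError):
        mean_soma_volume(ObjectTable([], ISO))


# ---------------------------------------------------------------- pipeline

def test_segment_clean_ellipsoids_exact(two_photon_voxel):
    z, y, x = np.ogrid[:24, :48, :48]
    m = (((x - 24) / 10) ** 2 + ((y - 24) / 10) ** 2 + ((z - 12) / 4) ** 2) <= 1
    img = np.where(m, 200, 10).astype(np.uint8)
    for method in ("renyi", "otsu"):
        np.testing.assert_array_equal(segment_soma_mask(img, method), m)


def test_segment_constant_image_raises():
    with pytest.raises(ValueError):
        segment_soma_mask(np.full((4, 8, 8), 7, np.uint8))


def test_pipeline_recovers_mean_volume(soma_stack):
    stack, truth = soma_stack
    table, labels = run_soma_pipeline(stack.channel_by_role("glia"), stack.voxel)
    assert len(table) == len(truth.true_soma_volumes_um3)
    est = mean_soma_volume(table)
    true = float(np.mean(truth.true_soma_volumes_um3))
    assert est == pytest.approx(true, rel=0.10)
    assert labels.max() == len(table)
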