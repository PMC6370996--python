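"""Geometry operations: rasterization, expansion, subtraction, distances, cones."""

import numpy as np
import pytest

import geodvh as gd
from geodvh.geometry import GeometryError

from conftest import brute_force_signed_distance, random_mask


def grid_iso(n=20, spacing=1.0):
    return gd.VoxelGrid((n, n, n), (spacing,) * 3)


# ---------------------------------------------------------------------------
# rasterize_structure
# ---------------------------------------------------------------------------

def square_contour(z, lo=-0.5, hi=9.5):
    return np.array([[lo, lo, z], [hi, lo, z], [hi, hi, z], [lo, hi, z]])


def test_rasterize_axis_aligned_square():
    g = grid_iso(20)
    contours = [square_contour(z) for z in range(20)]
    mask = gd.rasterize_structure(contours, g, "sq")
    assert mask.voxel_count == 10 * 10 * 20
    assert mask.inside[:10, :10, :].all()


def test_rasterize_empty_contour_set():
    mask = gd.rasterize_structure([], grid_iso(8), "empty")
    assert mask.volume_mL == 0.0


def test_rasterize_out_of_grid_contour_warns():
    g = grid_iso(8)
    with pytest.warns(UserWarning, match="outside grid"):
        mask = gd.rasterize_structure([square_contour(z=50.0, hi=5.5)], g)
    assert mask.is_empty()


def test_rasterize_self_intersecting_rejected():
    bowtie = np.array([[0, 0, 2], [4, 4, 2], [4, 0, 2], [0, 4, 2]], dtype=float)
    with pytest.raises(GeometryError, match="[Ss]elf-intersecting"):
        gd.rasterize_structure([bowtie], grid_iso(8))


def _even_odd_inside(point, poly):
    """Crossing-number point-in-polygon oracle."""
    x, y = point
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_rasterize_matches_even_odd_oracle(seed):
    rng = np.random.default_rng(seed)
    g = gd.VoxelGrid((15, 15, 3), (1.3, 0.9, 2.0))
    # random convex polygon (hull of random points), placed on slice 1
    angles = np.sort(rng.uniform(0, 2 * np.pi, 8))
    radii = rng.uniform(3, 8, 8)
    poly = np.column_stack([
        7 + radii * np.cos(angles) + rng.normal(0, 1e-3, 8),
        6 + radii * np.sin(angles) + rng.normal(0, 1e-3, 8),
    ])
    contour = np.column_stack([poly, np.full(8, g.spacing[2])])
    mask = gd.rasterize_structure([contour], g)
    xs, ys, _ = g.voxel_centers()
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            assert mask.inside[i, j, 1] == _even_odd_inside((x, y), poly)
    assert not mask.inside[:, :, 0].any() and not mask.inside[:, :, 2].any()


# ---------------------------------------------------------------------------
# expand_mask
# ---------------------------------------------------------------------------

def test_expand_zero_margin_is_identity():
    rng = np.random.default_rng(0)
    m = random_mask(grid_iso(12), rng)
    out = gd.expand_mask(m, gd.Margins.isotropic(0))
    assert np.array_equal(out.inside, m.inside)


def test_expand_sphere_matches_brute_force():
    g = grid_iso(25)
    inside = np.zeros(g.dims, dtype=bool)
    inside[12, 12, 12] = True
    out = gd.expand_mask(gd.StructureMask(g, inside, "pt"), gd.Margins.isotropic(10))
    centers = np.argwhere(np.ones(g.dims, dtype=bool)) - 12
    expect = (centers**2).sum(axis=1) <= 100 + 1e-12
    assert np.array_equal(out.inside.ravel(), expect)


def test_expand_posterior_margin_larger():
    """10-mm isotropic with 15 mm posterior: asymmetric A-P extents."""
    g = gd.VoxelGrid((40, 40, 40), (1, 1, 1))
    inside = np.zeros(g.dims, dtype=bool)
    inside[20, 20, 20] = True
    m = gd.Margins(left=10, right=10, anterior=10, posterior=15, superior=10, inferior=10)
    out = gd.expand_mask(gd.StructureMask(g, inside, "pt"), m)
    ys = np.flatnonzero(out.inside[20, :, 20])
    assert ys.min() == 20 - 10  # anterior (-y) reach 10 voxels
    assert ys.max() == 20 + 15  # posterior (+y) reach 15 voxels


def test_expand_monotone_and_extensive():
    import warnings

    rng = np.random.default_rng(3)
    g = gd.VoxelGrid((14, 14, 14), (1.5, 1.5, 2.0))
    a = random_mask(g, rng, 0.05)
    b = gd.StructureMask(g, a.inside | (rng.random(g.dims) < 0.05), "b")
    margins = gd.Margins.isotropic(4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # masks reach the border
        ea, eb = gd.expand_mask(a, margins), gd.expand_mask(b, margins)
    assert (a.inside <= ea.inside).all()  # extensive
    assert (ea.inside <= eb.inside).all()  # monotone


def test_expand_clip_warns():
    g = grid_iso(8)
    inside = np.zeros(g.dims, dtype=bool)
    inside[4, 4, 4] = True
    with pytest.warns(UserWarning, match="clipped"):
        gd.expand_mask(gd.StructureMask(g, inside, "pt"), gd.Margins.isotropic(6))


# ---------------------------------------------------------------------------
# subtract_overlap
# ---------------------------------------------------------------------------

def test_subtract_disjoint_and_covering():
    g = grid_iso(10)
    ptv = np.zeros(g.dims, bool)
    ptv[2:5, 2:5, 2:5] = True
    far = np.zeros(g.dims, bool)
    far[7:9, 7:9, 7:9] = True
    p = gd.StructureMask(g, ptv, "PTV")
    assert np.array_equal(
        gd.subtract_overlap(p, [gd.StructureMask(g, far, "o")]).inside, ptv
    )
    total = gd.StructureMask(g, np.ones(g.dims, bool), "all")
    assert gd.subtract_overlap(p, [total]).is_empty()


def test_subtract_volume_arithmetic():
    rng = np.random.default_rng(5)
    g = grid_iso(12)
    ptv = random_mask(g, rng, 0.3)
    oars = [random_mask(g, rng, 0.15) for _ in range(3)]
    out = gd.subtract_overlap(ptv, oars)
    union = np.logical_or.reduce([o.inside for o in oars])
    assert out.voxel_count == ptv.voxel_count - np.sum(ptv.inside & union)
    assert (out.inside <= ptv.inside).all()


def test_subtract_incompatible_grid_rejected():
    g1, g2 = grid_iso(10), grid_iso(10, spacing=2.0)
    p = gd.StructureMask(g1, np.ones(g1.dims, bool), "p")
    o = gd.StructureMask(g2, np.ones(g2.dims, bool), "o")
    with pytest.raises(GeometryError, match="incompatible"):
        gd.subtract_overlap(p, [o])


# ---------------------------------------------------------------------------
# signed_distance_map
# ---------------------------------------------------------------------------

def test_signed_distance_axis_aligned():
    g = gd.VoxelGrid((10, 10, 10), (2.0, 2.0, 2.5))
    tgt = np.zeros(g.dims, bool)
    tgt[4:6, 4:6, 2:4] = True
    oar = np.zeros(g.dims, bool)
    oar[4, 4, 6] = True  # 3 voxels straight superior of the target face
    dm = gd.signed_distance_map(
        gd.StructureMask(g, oar, "o"), gd.StructureMask(g, tgt, "t")
    )
    assert dm.distances == pytest.approx([7.5])


def test_signed_distance_sign_convention():
    g = grid_iso(12)
    tgt = np.zeros(g.dims, bool)
    tgt[3:9, 3:9, 3:9] = True
    oar = np.zeros(g.dims, bool)
    oar[5, 5, 5] = True  # deep inside
    dm = gd.signed_distance_map(
        gd.StructureMask(g, oar, "o"), gd.StructureMask(g, tgt, "t")
    )
    assert dm.distances[0] < 0


def test_signed_distance_empty_target_rejected():
    g = grid_iso(6)
    empty = gd.StructureMask(g, np.zeros(g.dims, bool), "t")
    oar = gd.StructureMask(g, np.ones(g.dims, bool), "o")
    with pytest.raises(GeometryError, match="nonempty target"):
        gd.signed_distance_map(oar, empty)


@pytest.mark.parametrize("seed", [10, 11, 12, 13])
def test_signed_distance_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    g = gd.VoxelGrid((16, 16, 16), (1.1, 0.8, 1.9))
    target = random_mask(g, rng, 0.1)
    if target.is_empty():
        pytest.skip("degenerate draw")
    oar = random_mask(g, rng, 0.1)
    dm = gd.signed_distance_map(oar, target)
    expect = brute_force_signed_distance(oar, target)
    assert np.allclose(dm.distances, expect, atol=1e-9)


# ---------------------------------------------------------------------------
# partition_field
# ---------------------------------------------------------------------------

def _cube_target(g, lo=8, hi=12):
    t = np.zeros(g.dims, bool)
    t[lo:hi, lo:hi, lo:hi] = True
    return gd.StructureMask(g, t, "t")


def test_partition_axis_voxel_outfield_and_midplane_infield():
    g = grid_iso(40)
    target = _cube_target(g, 18, 22)
    oar = np.zeros(g.dims, bool)
    oar[19, 19, 39] = True  # on the SI axis, far above the superior apex
    oar[2, 2, 19] = True  # same SI level as the target: between apices
    fmap = gd.partition_field(gd.StructureMask(g, oar, "o"), target, 0)
    # voxel order is C order: (2,2,19) first, (19,19,39) second
    assert fmap.infield[0] and not fmap.infield[1]


def test_partition_boundary_angle_is_infield():
    g = gd.VoxelGrid((41, 41, 41), (1, 1, 1))
    t = np.zeros(g.dims, bool)
    t[20, 20, 20] = True  # single-voxel target: apexes at its center (interval 0)
    target = gd.StructureMask(g, t, "t")
    tan30 = np.tan(np.radians(30))
    oar = np.zeros(g.dims, bool)
    # pick lateral offset 10 -> dz exactly tan(30)*10 is not integer; use the
    # angle oracle over a shell of voxels instead
    oar[18:23, 18:23, :] = True
    oar[:, :, 18:23] = True
    fmap = gd.partition_field(gd.StructureMask(g, oar, "o"), target, 0)
    idx = np.argwhere(oar)
    for k, vox in enumerate(idx):
        dx, dy, dz = vox - 20
        lateral = np.hypot(dx, dy)
        expected_outfield = abs(dz) > tan30 * lateral and dz != 0
        assert fmap.infield[k] == (not expected_outfield), vox


@pytest.mark.parametrize("seed", [21, 22])
def test_partition_matches_angle_oracle(seed):
    rng = np.random.default_rng(seed)
    g = gd.VoxelGrid((20, 20, 24), (2.0, 2.0, 2.5))
    t = np.zeros(g.dims, bool)
    t[8:12, 9:13, 10:14] = True
    target = gd.StructureMask(g, t, "t")
    oar = random_mask(g, rng, 0.15)
    for interval in (0, 5, 10):
        fmap = gd.partition_field(oar, target, interval)
        xs, ys, zs = g.voxel_centers()
        idx = np.argwhere(t)
        zmax, zmin = idx[:, 2].max(), idx[:, 2].min()
        sup = idx[idx[:, 2] == zmax]
        inf = idx[idx[:, 2] == zmin]
        apex_s = np.array([xs[sup[:, 0]].mean(), ys[sup[:, 1]].mean(), zs[zmax] + interval])
        apex_i = np.array([xs[inf[:, 0]].mean(), ys[inf[:, 1]].mean(), zs[zmin] - interval])
        tan30 = np.tan(np.radians(30))
        for k, vox in enumerate(np.argwhere(oar.inside)):
            v = np.array([xs[vox[0]], ys[vox[1]], zs[vox[2]]])
            outf = False
            if v[2] > apex_s[2]:
                outf = v[2] - apex_s[2] > tan30 * np.hypot(*(v[:2] - apex_s[:2]))
            elif v[2] < apex_i[2]:
                outf = apex_i[2] - v[2] > tan30 * np.hypot(*(v[:2] - apex_i[:2]))
            assert fmap.infield[k] == (not outf)


def test_partition_interval_monotone_and_conserving():
    rng = np.random.default_rng(30)
    g = gd.VoxelGrid((24, 24, 28), (2.0, 2.0, 2.5))
    t = np.zeros(g.dims, bool)
    t[10:14, 10:14, 12:16] = True
    target = gd.StructureMask(g, t, "t")
    oar = random_mask(g, rng, 0.3)
    outs = {}
    for interval in (0, 5, 10):
        fmap = gd.partition_field(oar, target, interval)
        outs[interval] = ~fmap.infield
        # partition never drops voxels
        assert fmap.infield.sum() + (~fmap.infield).sum() == oar.voxel_count
    assert (outs[5] <= outs[0]).all() and (outs[10] <= outs[5]).all()


def test_single_field_all_infield():
    g = grid_iso(8)
    oar = gd.StructureMask(g, np.ones(g.dims, bool), "o")
    assert gd.single_field(oar).infield.all()
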