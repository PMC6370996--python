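"""Voxel-grid structure handling for radiotherapy plan geometry.

Masks and dose grids live on a shared anisotropic voxel grid in patient (LPS)
millimetre coordinates: axis 0 is left–right (+x left), axis 1 is
anterior–posterior (+y posterior), axis 2 is superior–inferior (+z superior).
All distances are in mm, volumes in mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Invalid geometric input (incompatible grids, empty targets, ...)."""


@dataclass(frozen=True)
class VoxelGrid:
    """Anisotropic 3-D raster in patient mm coordinates.

    ``dims`` are voxel counts along (L-R, A-P, S-I); ``spacing`` the voxel
    pitch in mm; ``origin`` the mm coordinate of the center of voxel
    (0, 0, 0).  Index axis 2 increases toward superior.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise GeometryError(f"grid dims must be positive triple, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"grid spacing must be positive triple, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in mL (mm^3 / 1000)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def diagonal_mm(self) -> float:
        return float(np.linalg.norm([(d - 1) * s for d, s in zip(self.dims, self.spacing)]))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid-free center coordinates: three 1-D arrays (x, y, z)."""
        return self.axis_coords(0), self.axis_coords(1), self.axis_coords(2)

    def compatible(self, other: "VoxelGrid") -> bool:
        return (
            self.dims == other.dims
            and self.spacing == other.spacing
            and np.allclose(self.origin, other.origin)
        )


def _require_compatible(*grids: VoxelGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.compatible(g):
            raise GeometryError(f"incompatible grids: {ref} vs {g}")


@dataclass
class StructureMask:
    """Boolean occupancy of one anatomic structure on a grid."""

    grid: VoxelGrid
    inside: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.dims:
            raise GeometryError(
                f"mask shape {self.inside.shape} does not match grid dims {self.grid.dims}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.inside.sum())

    @property
    def volume_mL(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mL

    def is_empty(self) -> bool:
        return not self.inside.any()


@dataclass(frozen=True)
class Margins:
    """Per-direction expansion distances in mm (all >= 0)."""

    left: float = 0.0
    right: float = 0.0
    anterior: float = 0.0
    posterior: float = 0.0
    superior: float = 0.0
    inferior: float = 0.0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.as_tuple()):
            raise GeometryError(f"margins must be >= 0, got {self}")

    @classmethod
    def isotropic(cls, mm: float) -> "Margins":
        return cls(mm, mm, mm, mm, mm, mm)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.left, self.right, self.anterior, self.posterior, self.superior, self.inferior)

    def per_axis(self) -> tuple[tuple[float, float], ...]:
        """((neg, pos) margin per index axis): axis 0 -x=right/+x=left, axis 1
        -y=anterior/+y=posterior, axis 2 -z=inferior/+z=superior."""
        return ((self.right, self.left), (self.anterior, self.posterior), (self.inferior, self.superior))


@dataclass
class DistanceMap:
    """Signed distance (mm) from each OAR voxel to the target boundary.

    Negative inside the target, positive outside; voxel-center-to-voxel-center
    semantics.  ``distances`` is a flat array aligned with ``voxel_indices``
    (the OAR voxels in C order).
    """

    oar_label: str
    target_label: str
    grid: VoxelGrid
    voxel_indices: np.ndarray  # (n, 3) int
    distances: np.ndarray  # (n,) float, mm

    @property
    def n_voxels(self) -> int:
        return len(self.distances)


@dataclass
class FieldLabelMap:
    """Infield/outfield membership of each OAR voxel (aligned with a DistanceMap)."""

    oar_label: str
    apex_interval_mm: float
    infield: np.ndarray  # (n,) bool; True = infield

    @property
    def n_voxels(self) -> int:
        return len(self.infield)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _polygon_self_intersects(xy: np.ndarray) -> bool:
    from shapely.geometry import Polygon
    from shapely.validation import explain_validity

    poly = Polygon(xy)
    if poly.is_valid:
        return False
    return "Self-intersection" in explain_validity(poly)


def rasterize_structure(contour_set, grid: VoxelGrid, label: str = "") -> StructureMask:
    """Rasterize planar closed contours (patient mm) onto a voxel grid.

    ``contour_set`` is an iterable of (n, 3) arrays; each contour must be
    planar in z.  A voxel is inside iff its center lies inside the contour
    polygon of its slice (even–odd rule; multiple contours on one slice XOR,
    which carves holes).  Contours whose z falls outside the grid are ignored
    with a warning; self-intersecting polygons are rejected.
    """
    from matplotlib.path import Path

    inside = np.zeros(grid.dims, dtype=bool)
    xs, ys, zs = grid.voxel_centers()
    pts = np.column_stack([m.ravel() for m in np.meshgrid(xs, ys, indexing="ij")])

    for contour in contour_set:
        contour = np.asarray(contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 3 or len(contour) < 3:
            raise GeometryError("contour must be an (n>=3, 3) array of mm points")
        z = contour[0, 2]
        if not np.allclose(contour[:, 2], z, atol=1e-6):
            raise GeometryError("contour is not planar in z")
        if _polygon_self_intersects(contour[:, :2]):
            raise GeometryError("self-intersecting contour polygon rejected")
        k = (z - grid.origin[2]) / grid.spacing[2]
        ki = int(round(k))
        if ki < 0 or ki >= grid.dims[2] or abs(k - ki) > 0.5 + 1e-9:
            warnings.warn(f"contour at z={z:.2f} mm outside grid; ignored", stacklevel=2)
            continue
        # explicit closing vertex: matplotlib treats the last point of a
        # closed Path as the (ignored) CLOSEPOLY dummy
        path = Path(np.vstack([contour[:, :2], contour[:1, :2]]), closed=True)
        hit = path.contains_points(pts).reshape(grid.dims[0], grid.dims[1])
        inside[:, :, ki] ^= hit  # even-odd across multiple contours per slice

    return StructureMask(grid, inside, label)


# ---------------------------------------------------------------------------
# Margin expansion and boolean structure arithmetic
# ---------------------------------------------------------------------------

def _margin_structuring_element(margins: Margins, spacing) -> np.ndarray:
    """Ellipsoidal-per-octant structuring element in voxel offsets.

    A displacement (dx, dy, dz) in mm is admissible iff
    sum((d_i / m_i)^2) <= 1, where m_i is the margin for d_i's sign on that
    axis; a zero margin admits only zero displacement along that axis.
    """
    per_axis = margins.per_axis()
    # symmetric footprint (binary_dilation anchors at the element center);
    # inadmissible octants are simply left False
    radii = [
        int(np.floor(max(neg, pos) / s + 1e-9))
        for (neg, pos), s in zip(per_axis, spacing)
    ]
    offs = [np.arange(-r, r + 1) for r in radii]
    ox, oy, oz = np.meshgrid(*offs, indexing="ij")
    total = np.zeros(ox.shape, dtype=float)
    for off, (neg, pos), s in zip((ox, oy, oz), per_axis, spacing):
        d = off * s
        m = np.where(off >= 0, pos, neg)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(d == 0, 0.0, (d / m) ** 2)
        term = np.where((d != 0) & (m == 0), np.inf, term)
        total += term
    return total <= 1.0 + 1e-12


def expand_mask(mask: StructureMask, margins: Margins) -> StructureMask:
    """Anisotropic margin expansion of a structure mask.

    The result contains exactly the voxels whose center lies within the
    per-octant ellipsoidal margin distance of some source voxel center; it is
    clipped at the grid bounds (with a warning when clipping occurs).
    """
    if mask.is_empty():
        raise GeometryError("cannot expand an empty mask")
    selem = _margin_structuring_element(margins, mask.grid.spacing)
    out = ndimage.binary_dilation(mask.inside, structure=selem)
    faces = (
        out[0].any() or out[-1].any()
        or out[:, 0].any() or out[:, -1].any()
        or out[:, :, 0].any() or out[:, :, -1].any()
    )
    if faces and any(m > 0 for m in margins.as_tuple()):
        warnings.warn(
            f"expansion of '{mask.label}' reaches the grid boundary; clipped", stacklevel=2
        )
    return StructureMask(mask.grid, out, mask.label)


def subtract_overlap(ptv: StructureMask, gi_oars: list[StructureMask]) -> StructureMask:
    """PTV minus the union of GI-OAR masks (may be empty)."""
    _require_compatible(ptv.grid, *[m.grid for m in gi_oars])
    union = np.zeros(ptv.grid.dims, dtype=bool)
    for m in gi_oars:
        union |= m.inside
    return StructureMask(ptv.grid, ptv.inside & ~union, ptv.label)


# ---------------------------------------------------------------------------
# Signed distance and field partition
# ---------------------------------------------------------------------------

def signed_distance_field(target: StructureMask) -> np.ndarray:
    """Grid-wide signed distance (mm) to the target, voxel-center semantics.

    Outside voxels: + distance to the nearest target voxel center; inside
    voxels: − distance to the nearest non-target voxel center.
    """
    if target.is_empty():
        raise GeometryError("signed distance requires a nonempty target")
    sp = target.grid.spacing
    t = target.inside
    d_out = ndimage.distance_transform_edt(~t, sampling=sp)
    if t.all():
        d_in = np.zeros(t.shape)  # degenerate: target fills the grid
    else:
        d_in = ndimage.distance_transform_edt(t, sampling=sp)
    return np.where(t, -d_in, d_out)


def signed_distance_map(oar: StructureMask, target: StructureMask) -> DistanceMap:
    """Signed minimal Euclidean distance of each OAR voxel to the target boundary."""
    _require_compatible(oar.grid, target.grid)
    if target.is_empty():
        raise GeometryError("signed distance requires a nonempty target")
    sdf = signed_distance_field(target)
    idx = np.argwhere(oar.inside)
    return DistanceMap(
        oar_label=oar.label,
        target_label=target.label,
        grid=oar.grid,
        voxel_indices=idx,
        distances=sdf[oar.inside.nonzero()] if idx.size else np.empty(0),
    )


# Noncoplanar SBRT beams stay within +-30 deg of the axial plane, so voxels a
# beam plane through the cone apex cannot reach have elevation > 30 deg.
CONE_HALF_ANGLE_DEG = 30.0
_TAN30 = np.tan(np.radians(CONE_HALF_ANGLE_DEG))


def _cone_apexes(target: StructureMask, interval_mm: float):
    """Superior/inferior double-cone apexes: (x, y) centroid of the extreme
    target slice, pushed ``interval_mm`` beyond the target along z."""
    idx = np.argwhere(target.inside)
    zmax, zmin = idx[:, 2].max(), idx[:, 2].min()
    xs, ys, zs = target.grid.voxel_centers()

    def slice_centroid(k):
        sl = idx[idx[:, 2] == k]
        return xs[sl[:, 0]].mean(), ys[sl[:, 1]].mean()

    cx_s, cy_s = slice_centroid(zmax)
    cx_i, cy_i = slice_centroid(zmin)
    apex_sup = np.array([cx_s, cy_s, zs[zmax] + interval_mm])
    apex_inf = np.array([cx_i, cy_i, zs[zmin] - interval_mm])
    return apex_sup, apex_inf


def outfield_mask(target: StructureMask, interval_mm: float) -> np.ndarray:
    """Grid-wide boolean array: True where a voxel center is outfield.

    Outfield is the double cone along the superior–inferior axis: a voxel is
    outfield iff it lies beyond an apex along z and its elevation angle from
    the axial plane, measured from the nearer apex, strictly exceeds 30 deg.
    Boundary voxels (exactly 30 deg) are infield.
    """
    if interval_mm not in (0, 5, 10):
        raise GeometryError(f"apex interval must be 0, 5 or 10 mm, got {interval_mm}")
    if target.is_empty():
        raise GeometryError("field partition requires a nonempty target")
    apex_sup, apex_inf = _cone_apexes(target, interval_mm)
    xs, ys, zs = target.grid.voxel_centers()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    out = np.zeros(target.grid.dims, dtype=bool)
    for apex, above in ((apex_sup, True), (apex_inf, False)):
        lateral = np.hypot(gx - apex[0], gy - apex[1])  # (nx, ny)
        dz = zs - apex[2]  # (nz,)
        dz = dz if above else -dz
        beyond = dz > 0
        # |dz| > tan(30) * lateral, only beyond the apex
        cone = dz[None, None, :] > (_TAN30 * lateral)[:, :, None]
        out |= cone & beyond[None, None, :]
    return out


def partition_field(
    oar: StructureMask, target: StructureMask, interval_mm: float = 0
) -> FieldLabelMap:
    """Label each OAR voxel infield/outfield under the double-cone beam model."""
    _require_compatible(oar.grid, target.grid)
    out = outfield_mask(target, interval_mm)
    infield = ~out[oar.inside.nonzero()] if oar.voxel_count else np.empty(0, dtype=bool)
    return FieldLabelMap(oar_label=oar.label, apex_interval_mm=float(interval_mm), infield=infield)


def single_field(oar: StructureMask) -> FieldLabelMap:
    """Degenerate partition: every voxel infield (partition mode 'single')."""
    return FieldLabelMap(
        oar_label=oar.label,
        apex_interval_mm=float("nan"),
        infield=np.ones(oar.voxel_count, dtype=bool),
    )
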