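"""Voxel phantoms, HU calibration, Siddon raytracing and grid resampling.

Conventions (fixed to avoid half-voxel drift): right-handed coordinates in
mm, 0-based voxel indices, half-open voxel extents ``[lower, upper)``, and
the grid ``origin`` at the *corner* of voxel (0, 0, 0).  The centre of voxel
``(i, j, k)`` is therefore ``origin + (i + 0.5) * spacing`` per axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .database import DEFAULT_HU_CALIBRATION
from .errors import GeometryError, ValidationError


@dataclass
class VoxelGrid:
    """A rectilinear voxel lattice of HU or relative-stopping-power values."""

    values: np.ndarray            # (nx, ny, nz)
    spacing: tuple                # mm per axis
    origin: tuple = (0.0, 0.0, 0.0)
    value_kind: str = "RSP"       # "HU" or "RSP"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive on all axes")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if self.value_kind not in ("HU", "RSP"):
            raise ValidationError("value_kind must be 'HU' or 'RSP'")
        if self.value_kind == "RSP" and np.any(self.values < 0):
            raise ValidationError("RSP values must be >= 0")

    @property
    def shape(self):
        return self.values.shape

    @property
    def extent(self):
        """Upper corner of the grid in mm."""
        return tuple(o + n * s for o, n, s in
                     zip(self.origin, self.shape, self.spacing))

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_mesh(self):
        """Voxel-centre coordinate arrays (broadcastable 3-D)."""
        cx = self.axis_centers(0)[:, None, None]
        cy = self.axis_centers(1)[None, :, None]
        cz = self.axis_centers(2)[None, None, :]
        return cx, cy, cz

    def like(self, values) -> "VoxelGrid":
        return VoxelGrid(values, self.spacing, self.origin, self.value_kind)

    # -- text I/O: JSON header + CSV of flattened values --------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        header = {"shape": list(self.shape), "spacing": list(self.spacing),
                  "origin": list(self.origin), "value_kind": self.value_kind}
        (path / "header.json").write_text(json.dumps(header))
        np.savetxt(path / "values.csv", self.values.ravel(order="C"),
                   fmt="%.17g")

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        path = Path(path)
        header = json.loads((path / "header.json").read_text())
        vals = np.loadtxt(path / "values.csv").reshape(header["shape"],
                                                       order="C")
        return cls(vals, header["spacing"], header["origin"],
                   header["value_kind"])


@dataclass
class ROIMask:
    """Named binary mask on a stated grid."""

    name: str
    mask: np.ndarray
    grid: VoxelGrid = field(repr=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValidationError(
                f"ROI {self.name!r}: mask shape {self.mask.shape} != grid "
                f"shape {self.grid.shape}")

    @property
    def volume_cm3(self) -> float:
        return float(self.mask.sum()) * self.grid.voxel_volume / 1000.0

    def to_json(self) -> str:
        """Run-length encoding of the C-order flattened mask."""
        flat = self.mask.ravel(order="C")
        changes = np.nonzero(np.diff(flat))[0] + 1
        bounds = np.concatenate(([0], changes, [flat.size]))
        runs = np.diff(bounds).tolist()
        return json.dumps({"name": self.name, "shape": list(self.mask.shape),
                           "first": bool(flat[0]), "runs": runs})

    @classmethod
    def from_json(cls, text: str, grid: VoxelGrid) -> "ROIMask":
        obj = json.loads(text)
        flat = np.zeros(int(np.prod(obj["shape"])), dtype=bool)
        val = obj["first"]
        pos = 0
        for run in obj["runs"]:
            flat[pos:pos + run] = val
            pos += run
            val = not val
        return cls(obj["name"], flat.reshape(obj["shape"], order="C"), grid)


@dataclass
class Ray:
    source: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise GeometryError("ray direction must be nonzero")
        if abs(n - 1.0) > 1e-12:
            self.direction = self.direction / n


def hu_to_rsp(grid: VoxelGrid, calibration=None) -> VoxelGrid:
    """Piecewise-linear HU -> relative stopping power, clamped at the ends.

    The default node list anchors air near 0, water at exactly (0 HU, 1.0)
    and compact bone around 1.6; out-of-range HU clamp to the end nodes.
    """
    if grid.value_kind != "HU":
        raise ValidationError("hu_to_rsp expects an HU grid")
    nodes = calibration if calibration is not None else DEFAULT_HU_CALIBRATION
    hu = np.asarray([n[0] for n in nodes], dtype=float)
    rsp = np.asarray([n[1] for n in nodes], dtype=float)
    if np.any(np.diff(hu) <= 0):
        raise ValidationError("calibration nodes must be strictly increasing")
    if hu[0] > -1024 or hu[-1] < 3000:
        raise ValidationError("calibration must cover [-1024, 3000] HU")
    out = np.interp(grid.values, hu, rsp)
    return VoxelGrid(out, grid.spacing, grid.origin, "RSP")


# ---------------------------------------------------------------------------
# raytracing
# ---------------------------------------------------------------------------

def _grid_entry_exit(grid: VoxelGrid, ray: Ray):
    """Slab intersection of the ray with the grid box; None if it misses."""
    lo = np.asarray(grid.origin)
    hi = np.asarray(grid.extent)
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        d = ray.direction[ax]
        s = ray.source[ax]
        if abs(d) < 1e-15:
            if s < lo[ax] or s >= hi[ax]:
                return None
            continue
        ta = (lo[ax] - s) / d
        tb = (hi[ax] - s) / d
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if t1 <= t0:
        return None
    return t0, t1


def raytrace_wepl(grid: VoxelGrid, ray: Ray):
    """Exact Siddon-style traversal of the grid along the ray.

    Returns ``(indices, lengths, cum_wepl)`` where ``indices`` is (M, 3) of
    traversed voxels, ``lengths`` the geometric chord per voxel (mm) and
    ``cum_wepl`` the water-equivalent prefix sums (mm).  Voxel membership
    follows the half-open convention via segment midpoints, so a ray running
    exactly along a voxel boundary books its length to one column only.
    """
    if grid.value_kind != "RSP":
        raise ValidationError("raytrace_wepl expects an RSP grid")
    hit = _grid_entry_exit(grid, ray)
    empty = (np.zeros((0, 3), dtype=int), np.zeros(0), np.zeros(0))
    if hit is None:
        return empty
    t0, t1 = hit
    ts = [np.array([t0, t1])]
    lo = np.asarray(grid.origin)
    for ax in range(3):
        d = ray.direction[ax]
        if abs(d) < 1e-15:
            continue
        s = ray.source[ax]
        h = grid.spacing[ax]
        # plane indices whose crossing parameter lies in (t0, t1)
        a = (min(t0, t1) * d + s - lo[ax]) / h
        b = (max(t0, t1) * d + s - lo[ax]) / h
        if d < 0:
            a, b = b, a
        k = np.arange(np.ceil(min(a, b) - 1e-12),
                      np.floor(max(a, b) + 1e-12) + 1)
        ts.append((lo[ax] + k * h - s) / d)
    t = np.unique(np.concatenate(ts))
    t = t[(t >= t0 - 1e-12) & (t <= t1 + 1e-12)]
    if t.size < 2:
        return empty
    mids = 0.5 * (t[:-1] + t[1:])
    pts = ray.source[None, :] + mids[:, None] * ray.direction[None, :]
    idx = np.floor((pts - lo[None, :]) / np.asarray(grid.spacing)[None, :])
    idx = idx.astype(int)
    shape = np.asarray(grid.shape)
    keep = np.all((idx >= 0) & (idx < shape[None, :]), axis=1)
    lengths = np.diff(t)
    keep &= lengths > 1e-12
    idx = idx[keep]
    lengths = lengths[keep]
    rsp = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    cum = np.cumsum(lengths * rsp)
    return idx, lengths, cum


def wepl_profile(grid: VoxelGrid, point, direction):
    """Piecewise-linear WEPL vs distance along a ray through the grid.

    Returns ``(s_knots, wepl_knots)``: distances measured from the ray's
    entry into the grid and the cumulative WEPL at each segment end, with a
    leading (0, 0) knot.  Empty arrays if the ray misses the grid.
    """
    ray = Ray(np.asarray(point, dtype=float), np.asarray(direction, float))
    hit = _grid_entry_exit(grid, ray)
    if hit is None:
        return np.zeros(1), np.zeros(1), 0.0
    _, lengths, cum = raytrace_wepl(grid, ray)
    if lengths.size == 0:
        return np.zeros(1), np.zeros(1), hit[0]
    s = np.concatenate(([0.0], np.cumsum(lengths)))
    w = np.concatenate(([0.0], cum))
    return s, w, hit[0]


# ---------------------------------------------------------------------------
# dose-grid resampling
# ---------------------------------------------------------------------------

def _overlap_matrix(n_src: int, s_src: float, n_dst: int, s_dst: float):
    """(n_dst, n_src) box-overlap lengths between 1-D cell partitions."""
    src_lo = np.arange(n_src) * s_src
    src_hi = src_lo + s_src
    dst_lo = np.arange(n_dst) * s_dst
    dst_hi = dst_lo + s_dst
    ov = (np.minimum(dst_hi[:, None], src_hi[None, :])
          - np.maximum(dst_lo[:, None], src_lo[None, :]))
    return np.clip(ov, 0.0, None)


def resample_to_dose_grid(grid: VoxelGrid, dose_spacing) -> VoxelGrid:
    """Volume-weighted box average of a CT-resolution map onto a coarser grid.

    The dose grid shares the source origin; its last voxel may only partially
    overlap the source extent, in which case the value is the mean over the
    overlapping part (exact box overlap, not nearest neighbour).
    """
    dose_spacing = tuple(float(s) for s in np.broadcast_to(
        np.asarray(dose_spacing, dtype=float), (3,)))
    for a in range(3):
        if dose_spacing[a] < grid.spacing[a] - 1e-12:
            raise ValidationError(
                "dose spacing must be >= CT spacing on every axis")
    mats = []
    shape_out = []
    for a in range(3):
        n_src = grid.shape[a]
        extent = n_src * grid.spacing[a]
        n_dst = int(np.ceil(extent / dose_spacing[a] - 1e-9))
        m = _overlap_matrix(n_src, grid.spacing[a], n_dst, dose_spacing[a])
        norm = m.sum(axis=1, keepdims=True)
        mats.append(m / norm)
        shape_out.append(n_dst)
    out = np.einsum("ai,ijk->ajk", mats[0], grid.values)
    out = np.einsum("bj,ajk->abk", mats[1], out)
    out = np.einsum("ck,abk->abc", mats[2], out)
    return VoxelGrid(out, dose_spacing, grid.origin, grid.value_kind)


# ---------------------------------------------------------------------------
# phantom builders
# ---------------------------------------------------------------------------

def _cube_mask(grid: VoxelGrid, center, side):
    # half-open box [c - s/2, c + s/2) to match the voxel convention
    cx, cy, cz = grid.center_mesh()
    half = np.broadcast_to(np.asarray(side, dtype=float) / 2.0, (3,))
    c = np.asarray(center, dtype=float)
    return ((cx >= c[0] - half[0]) & (cx < c[0] + half[0])
            & (cy >= c[1] - half[1]) & (cy < c[1] + half[1])
            & (cz >= c[2] - half[2]) & (cz < c[2] + half[2]))


def make_phantom(kind: str, **params):
    """Build a named test phantom.

    ``water_tank``: uniform RSP-1 grid with a cubic target ROI whose proximal
    face sits at ``target_depth`` mm along +z (the beam axis).
    ``slab_with_insert``: HU water block with adjacent bone-like and air-like
    lateral inserts.
    ``head_like``: ellipsoidal soft-tissue body in air with a bone shell and
    an air cavity, plus PTV/OAR box masks.

    Returns ``(VoxelGrid, dict_of_ROIMask)``.
    """
    if kind == "water_tank":
        return _water_tank(**params)
    if kind == "slab_with_insert":
        return _slab_with_insert(**params)
    if kind == "head_like":
        return _head_like(**params)
    raise ValidationError(f"unknown phantom kind {kind!r}")


def _water_tank(size=(100.0, 100.0, 200.0), spacing=(2.0, 2.0, 2.0),
                target_side=30.0, target_depth=120.0):
    size = np.asarray(size, dtype=float)
    spacing = tuple(float(s) for s in spacing)
    shape = tuple(int(round(size[a] / spacing[a])) for a in range(3))
    if target_depth + target_side > size[2]:
        raise ValidationError(
            f"target (depth {target_depth} + side {target_side} mm) deeper "
            f"than the {size[2]} mm grid")
    grid = VoxelGrid(np.ones(shape), spacing, (0.0, 0.0, 0.0), "RSP")
    center = (size[0] / 2, size[1] / 2, target_depth + target_side / 2)
    mask = _cube_mask(grid, center, (target_side,) * 3)
    return grid, {"target": ROIMask("target", mask, grid)}


def _slab_with_insert(size=(100.0, 100.0, 120.0), spacing=(2.0, 2.0, 2.0),
                      insert_depth=30.0, insert_thickness=20.0,
                      bone_hu=700.0, air_hu=-1000.0):
    size = np.asarray(size, dtype=float)
    spacing = tuple(float(s) for s in spacing)
    shape = tuple(int(round(size[a] / spacing[a])) for a in range(3))
    vals = np.zeros(shape)   # water = 0 HU
    grid = VoxelGrid(vals, spacing, (0.0, 0.0, 0.0), "HU")
    cx, cy, cz = grid.center_mesh()
    band = (cz >= insert_depth) & (cz < insert_depth + insert_thickness)
    bone = band & (cx < size[0] / 3)
    air = band & (cx >= 2 * size[0] / 3)
    vals[np.broadcast_to(bone, shape)] = bone_hu
    vals[np.broadcast_to(air, shape)] = air_hu
    grid = VoxelGrid(vals, spacing, (0.0, 0.0, 0.0), "HU")
    rois = {
        "bone_insert": ROIMask("bone_insert", np.broadcast_to(bone, shape), grid),
        "air_insert": ROIMask("air_insert", np.broadcast_to(air, shape), grid),
    }
    return grid, rois


def _head_like(size=(160.0, 160.0, 160.0), spacing=(2.0, 2.0, 2.0),
               soft_hu=40.0, bone_hu=700.0, air_hu=-1000.0,
               shell_thickness=6.0):
    size = np.asarray(size, dtype=float)
    spacing = tuple(float(s) for s in spacing)
    shape = tuple(int(round(size[a] / spacing[a])) for a in range(3))
    vals = np.full(shape, air_hu)
    grid = VoxelGrid(vals, spacing, (0.0, 0.0, 0.0), "HU")
    cx, cy, cz = grid.center_mesh()
    c = size / 2
    ax = size / 2 - 10.0
    rr = (((cx - c[0]) / ax[0]) ** 2 + ((cy - c[1]) / ax[1]) ** 2
          + ((cz - c[2]) / ax[2]) ** 2)
    axi = (size / 2 - 10.0 - shell_thickness)
    rr_in = (((cx - c[0]) / axi[0]) ** 2 + ((cy - c[1]) / axi[1]) ** 2
             + ((cz - c[2]) / axi[2]) ** 2)
    body = np.broadcast_to(rr <= 1.0, shape)
    inner = np.broadcast_to(rr_in <= 1.0, shape)
    vals[body] = bone_hu
    vals[inner] = soft_hu
    cavity = _cube_mask(grid, (c[0], c[1] - 25.0, c[2] - 30.0),
                        (24.0, 24.0, 24.0))
    cavity = np.broadcast_to(cavity, shape) & inner
    vals[cavity] = air_hu
    grid = VoxelGrid(vals, spacing, (0.0, 0.0, 0.0), "HU")
    ptv = _cube_mask(grid, (c[0], c[1], c[2]), (30.0, 30.0, 30.0))
    oar = _cube_mask(grid, (c[0] + 30.0, c[1], c[2]), (20.0, 20.0, 20.0))
    rois = {
        "ptv": ROIMask("ptv", np.broadcast_to(ptv, shape) & inner, grid),
        "oar": ROIMask("oar", np.broadcast_to(oar, shape) & inner, grid),
    }
    return grid, rois
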