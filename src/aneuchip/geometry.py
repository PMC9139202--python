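"""Synthetic vessel/aneurysm geometries and STL voxelization.

Geometries are represented as binary indicator fields ("masks") on a
uniform Cartesian grid, the native format of the volume-penalization
flow solver.

Indicator convention
--------------------
``indicator == 1`` marks SOLID (penalized) cells, ``indicator == 0``
marks fluid.  This matches the support of the Brinkman penalization term
-(chi/eta) u and is the OPPOSITE of the "occupancy = material of
interest" convention used by many voxelization tools — check twice when
interfacing with other software.

Coordinates are 0-based cell indices; the physical position of a cell
center is ``origin + (index + 1/2) * spacing``.  All dimensional
quantities are SI (meters).

The parametric generators produce a 2-D channel section (the default
pipeline geometry) or a coarse 3-D cylinder; the sidewall-aneurysm
generator is 2-D.  Patient-specific surfaces can be supplied as
watertight STL meshes and voxelized onto the same grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage

from .errors import GeometryError, MeshFormatError, ResolutionError, UsageError

__all__ = [
    "AneurysmParams",
    "VoxelMask",
    "make_straight_vessel",
    "make_sidewall_aneurysm",
    "voxelize_stl",
    "refine_mask",
    "smooth_mask",
    "save_mask",
    "load_mask",
]

#: minimum number of cells across the vessel diameter
MIN_CELLS_ACROSS = 8

#: minimum number of solid padding layers on non-inlet/outlet faces, so
#: penalization handles every wall uniformly
MIN_PADDING_CELLS = 2


@dataclass(frozen=True)
class AneurysmParams:
    """Parametric description of a straight supply vessel with an
    optional sidewall sac.

    Defaults describe a 4 mm supplying vessel (the length scale of the
    Re = 250 flow conditions) carrying a 1.6 mm-radius sac with a
    1.28 mm neck — plausible for a small sidewall aneurysm; the actual
    patient dimensions are not published, so these are surrogates, not
    patient-matched values.
    """

    vessel_diameter: float = 4.0e-3
    vessel_length: float = 16.0e-3
    sac_radius: float = 1.6e-3
    neck_width: float = 1.28e-3
    sac_side: str = "top"
    sac_center_offset: float = 8.0e-3

    def __post_init__(self) -> None:
        if self.vessel_diameter <= 0:
            raise UsageError("vessel_diameter must be positive")
        if self.vessel_length <= 0:
            raise UsageError("vessel_length must be positive")
        if self.sac_radius <= 0:
            raise UsageError("sac_radius must be positive")
        if self.neck_width < 0:
            raise UsageError("neck_width must be non-negative")
        if self.neck_width > 2.0 * self.sac_radius:
            raise UsageError(
                f"neck_width ({self.neck_width}) cannot exceed the sac "
                f"diameter ({2.0 * self.sac_radius})"
            )
        if self.sac_side not in ("top", "bottom"):
            raise UsageError("sac_side must be 'top' or 'bottom'")


@dataclass
class VoxelMask:
    """Binary fluid/solid field on a uniform, isotropic Cartesian grid.

    Attributes
    ----------
    indicator:
        uint8 array, shape ``(nx, ny)`` or ``(nx, ny, nz)``; 1 = solid.
    spacing:
        Cell size in meters (uniform and isotropic).
    origin:
        Physical coordinates of the low corner of cell (0, 0[, 0]).
    flow_axis:
        Axis along which flow enters and leaves the domain.
    inlet_faces, outlet_faces:
        ``(n, ndim)`` integer index arrays of the boundary fluid cells
        whose domain faces act as inlet (low end of ``flow_axis``) and
        outlet (high end).
    """

    indicator: np.ndarray
    spacing: float
    origin: tuple
    flow_axis: int = 0
    inlet_faces: np.ndarray = field(default=None, repr=False)
    outlet_faces: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.indicator = np.ascontiguousarray(self.indicator, dtype=np.uint8)
        self.origin = tuple(float(o) for o in self.origin)
        if self.inlet_faces is None:
            self.inlet_faces = _boundary_fluid_cells(self.indicator, self.flow_axis, 0)
        if self.outlet_faces is None:
            self.outlet_faces = _boundary_fluid_cells(self.indicator, self.flow_axis, -1)

    # -- basic queries -------------------------------------------------
    @property
    def ndim(self) -> int:
        return self.indicator.ndim

    @property
    def shape(self) -> tuple:
        return self.indicator.shape

    @property
    def fluid(self) -> np.ndarray:
        """Boolean fluid array (True = fluid)."""
        return self.indicator == 0

    @property
    def fluid_fraction(self) -> float:
        return float(np.mean(self.indicator == 0))

    def fluid_volume(self) -> float:
        """Total fluid volume (3-D) or area (2-D), SI units."""
        return float(np.sum(self.indicator == 0)) * self.spacing**self.ndim

    def cell_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical positions of cell centers for an ``(n, ndim)`` index
        array."""
        idx = np.atleast_2d(np.asarray(indices))
        return np.asarray(self.origin) + (idx + 0.5) * self.spacing

    def inlet_width(self) -> float:
        """Width (meters) of the largest contiguous fluid opening on the
        inlet boundary layer — the solver's default length scale."""
        run = largest_inlet_run(self)
        return len(run) * self.spacing

    # -- validation ----------------------------------------------------
    def validate(self, require_ports: bool = True) -> None:
        """Check every mask invariant; raise :class:`GeometryError` or
        :class:`UsageError` on violation."""
        ind = self.indicator
        if not np.isin(ind, (0, 1)).all():
            raise GeometryError("indicator must be exactly 0 or 1 everywhere")
        if self.spacing <= 0:
            raise UsageError("spacing must be positive")
        if require_ports:
            if self.inlet_faces.size == 0 or self.outlet_faces.size == 0:
                raise GeometryError("inlet and outlet faces must be non-empty")
            key_in = {tuple(r) for r in self.inlet_faces}
            key_out = {tuple(r) for r in self.outlet_faces}
            if key_in & key_out:
                raise GeometryError("inlet and outlet faces must be disjoint")
            for faces, end in ((self.inlet_faces, 0), (self.outlet_faces, -1)):
                layer = 0 if end == 0 else ind.shape[self.flow_axis] - 1
                if not (faces[:, self.flow_axis] == layer).all():
                    raise GeometryError("port faces must lie on the domain boundary")
                if ind[tuple(faces.T)].any():
                    raise GeometryError("port faces must be adjacent to fluid cells")
            self._check_connected()

    def _check_connected(self) -> None:
        fluid = self.indicator == 0
        structure = ndimage.generate_binary_structure(self.ndim, 1)
        labels, nlab = ndimage.label(fluid, structure=structure)
        if nlab == 0:
            raise GeometryError("mask contains no fluid cells")
        seed_label = labels[tuple(self.inlet_faces[0])]
        if seed_label == 0:
            raise GeometryError("inlet is not adjacent to fluid")
        if nlab > 1:
            sizes = ndimage.sum_labels(fluid, labels, index=range(1, nlab + 1))
            raise GeometryError(
                f"fluid region has {nlab} connected components "
                f"(sizes {sizes.astype(int).tolist()}); flood fill from the "
                "inlet does not reach every fluid cell"
            )


def _boundary_fluid_cells(indicator: np.ndarray, axis: int, end: int) -> np.ndarray:
    """Index array of fluid cells in the first/last layer along ``axis``."""
    layer = 0 if end == 0 else indicator.shape[axis] - 1
    sl = [slice(None)] * indicator.ndim
    sl[axis] = layer
    fluid = indicator[tuple(sl)] == 0
    other = np.argwhere(fluid)
    if other.size == 0:
        return np.empty((0, indicator.ndim), dtype=np.intp)
    out = np.empty((other.shape[0], indicator.ndim), dtype=np.intp)
    cols = [a for a in range(indicator.ndim) if a != axis]
    out[:, axis] = layer
    for k, a in enumerate(cols):
        out[:, a] = other[:, k]
    return out


def largest_inlet_run(mask: VoxelMask) -> np.ndarray:
    """Row indices of the largest contiguous fluid run on the inlet
    layer (2-D), or flat indices of the largest fluid component of the
    inlet cross-section (3-D)."""
    sl = [slice(None)] * mask.ndim
    sl[mask.flow_axis] = 0
    fluid_layer = mask.indicator[tuple(sl)] == 0
    if fluid_layer.ndim == 1:
        runs, nlab = ndimage.label(fluid_layer)
    else:
        runs, nlab = ndimage.label(fluid_layer)
    if nlab == 0:
        raise GeometryError("no fluid on the inlet boundary")
    sizes = ndimage.sum_labels(fluid_layer, runs, index=range(1, nlab + 1))
    best = int(np.argmax(sizes)) + 1
    return np.flatnonzero(runs.ravel() == best)


# ---------------------------------------------------------------------
# parametric generators
# ---------------------------------------------------------------------

def _check_resolution(diameter: float, spacing: float) -> None:
    n_across = diameter / spacing
    if n_across < MIN_CELLS_ACROSS:
        raise ResolutionError(
            f"spacing {spacing:g} m gives only {n_across:.1f} cells across the "
            f"{diameter:g} m diameter; at least {MIN_CELLS_ACROSS} are required"
        )


def make_straight_vessel(
    params: AneurysmParams,
    spacing: float,
    *,
    dim: int = 2,
    domain_height: float | None = None,
    wall_offset: float | None = None,
) -> VoxelMask:
    """Straight channel (2-D) or circular cylinder (3-D) of the vessel
    diameter, with inlet/outlet on the two axial domain faces.

    ``wall_offset`` (2-D) places the lower channel wall at a given
    height above the domain floor; by default the channel is centered.
    """
    d, length = params.vessel_diameter, params.vessel_length
    _check_resolution(d, spacing)
    if dim not in (2, 3):
        raise UsageError("dim must be 2 or 3")
    nx = int(round(length / spacing))

    if dim == 2:
        if domain_height is None:
            domain_height = 2.0 * d if wall_offset is None else d + 2.0 * wall_offset
        if wall_offset is None:
            wall_offset = 0.5 * (domain_height - d)
        ny = int(round(domain_height / spacing))
        if wall_offset < MIN_PADDING_CELLS * spacing or (
            domain_height - wall_offset - d
        ) < MIN_PADDING_CELLS * spacing - 1e-12:
            raise GeometryError(
                "vessel does not leave >= 2 solid padding layers on the "
                "transverse domain faces"
            )
        y = (np.arange(ny) + 0.5) * spacing
        fluid_row = (y > wall_offset) & (y < wall_offset + d)
        indicator = np.ones((nx, ny), dtype=np.uint8)
        indicator[:, fluid_row] = 0
    else:
        cross = 2.0 * d if domain_height is None else domain_height
        nyz = int(round(cross / spacing))
        yz = (np.arange(nyz) + 0.5) * spacing - 0.5 * cross
        yy, zz = np.meshgrid(yz, yz, indexing="ij")
        disk = yy**2 + zz**2 < (0.5 * d) ** 2
        if (cross - d) / 2.0 < MIN_PADDING_CELLS * spacing - 1e-12:
            raise GeometryError("cylinder does not leave 2 solid padding layers")
        indicator = np.ones((nx, nyz, nyz), dtype=np.uint8)
        indicator[:, disk] = 0

    mask = VoxelMask(indicator, spacing, (0.0,) * dim)
    mask.validate()
    return mask


def make_sidewall_aneurysm(
    params: AneurysmParams,
    spacing: float,
    *,
    domain_height: float | None = None,
    wall_offset: float | None = None,
) -> VoxelMask:
    """2-D channel with a circular sidewall sac connected through a neck.

    The sac disk is centered a distance ``sqrt(r^2 - (neck/2)^2)`` beyond
    the vessel wall so that the opening chord in the wall line has
    exactly the requested neck width.  The fluid region must come out as
    a single connected component (flood fill from the inlet), otherwise
    a :class:`GeometryError` is raised — e.g. for a zero or sub-cell
    neck width.
    """
    d, r, neck = params.vessel_diameter, params.sac_radius, params.neck_width
    _check_resolution(d, spacing)
    if neck <= 0:
        raise GeometryError("neck_width must be positive: a zero-width neck "
                            "disconnects the sac from the vessel")
    bulge = float(np.sqrt(r**2 - (0.5 * neck) ** 2))  # wall -> sac center

    if wall_offset is None:
        wall_offset = max(0.15 * d, (MIN_PADDING_CELLS + 1) * spacing)
    pad_top = max(0.08 * d, (MIN_PADDING_CELLS + 1) * spacing)
    if domain_height is None:
        domain_height = wall_offset + d + bulge + r + pad_top

    length = params.vessel_length
    nx = int(round(length / spacing))
    ny = int(round(domain_height / spacing))

    y0 = wall_offset
    y1 = wall_offset + d  # wall carrying the sac (sac_side == 'top')
    sac_y = y1 + bulge
    sac_x = params.sac_center_offset
    if sac_y + r > domain_height - MIN_PADDING_CELLS * spacing + 1e-12:
        raise GeometryError("sac dome does not fit inside the domain box")
    if not (0 < sac_x - neck / 2 and sac_x + neck / 2 < length):
        raise GeometryError("neck opening extends beyond the vessel length")

    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    xx, yy = np.meshgrid(x, y, indexing="ij")
    channel = (yy > y0) & (yy < y1)
    sac = (xx - sac_x) ** 2 + (yy - sac_y) ** 2 < r**2
    fluid = channel | sac
    if params.sac_side == "bottom":
        fluid = fluid[:, ::-1]

    indicator = np.where(fluid, 0, 1).astype(np.uint8)
    mask = VoxelMask(indicator, spacing, (0.0, 0.0))
    mask.validate()  # raises GeometryError if the sac is pinched off
    return mask


# ---------------------------------------------------------------------
# STL voxelization
# ---------------------------------------------------------------------

def voxelize_stl(
    surface: "trimesh.Trimesh | str",
    spacing: float,
    *,
    padding_cells: int = MIN_PADDING_CELLS,
    flow_axis: int | None = None,
) -> VoxelMask:
    """Voxelize a watertight triangulated surface onto the solver grid.

    A cell is fluid iff its center lies inside the surface, decided by
    even-odd ray-crossing parity along the z axis.  Cell-center (x, y)
    coordinates carry a fixed sub-nanometer perturbation so rays never
    hit triangle edges exactly; the result is reproducible across runs.

    ``flow_axis`` labels inlet/outlet faces on the two domain boundaries
    along that axis (for surfaces whose openings were capped at the
    domain box); leave ``None`` for closed objects.
    """
    if isinstance(surface, (str, bytes)) or hasattr(surface, "__fspath__"):
        mesh = trimesh.load_mesh(str(surface))
    else:
        mesh = surface
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshFormatError("input does not contain a triangulated surface")
    if not mesh.is_watertight:
        edges = np.sort(mesh.edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int(np.sum(counts != 2))
        raise MeshFormatError(
            f"surface is not watertight: {n_open} open (non-manifold) edges"
        )

    lo = mesh.bounds[0] - padding_cells * spacing
    hi = mesh.bounds[1] + padding_cells * spacing
    shape = np.ceil((hi - lo) / spacing).astype(int)
    nx, ny, nz = (int(s) for s in shape)

    # fixed deterministic perturbation of the ray grid (fractions of a cell)
    eps = spacing * np.array([0.5e-6, 1.3e-6])
    xc = lo[0] + (np.arange(nx) + 0.5) * spacing + eps[0]
    yc = lo[1] + (np.arange(ny) + 0.5) * spacing + eps[1]
    zc = lo[2] + (np.arange(nz) + 0.5) * spacing

    crossings = np.zeros((nx, ny, nz), dtype=np.int32)
    tri = mesh.triangles  # (ntri, 3, 3)
    for v0, v1, v2 in tri:
        # candidate ray columns under the triangle's xy bounding box
        txmin, txmax = min(v0[0], v1[0], v2[0]), max(v0[0], v1[0], v2[0])
        tymin, tymax = min(v0[1], v1[1], v2[1]), max(v0[1], v1[1], v2[1])
        i0, i1 = np.searchsorted(xc, (txmin, txmax))
        j0, j1 = np.searchsorted(yc, (tymin, tymax))
        if i0 == i1 or j0 == j1:
            continue
        px = xc[i0:i1, None] - v0[0]
        py = yc[None, j0:j1] - v0[1]
        e1x, e1y = v1[0] - v0[0], v1[1] - v0[1]
        e2x, e2y = v2[0] - v0[0], v2[1] - v0[1]
        det = e1x * e2y - e1y * e2x
        if det == 0.0:  # triangle vertical in z: never crossed transversally
            continue
        a = (px * e2y - py * e2x) / det
        b = (e1x * py - e1y * px) / det
        hit = (a >= 0) & (b >= 0) & (a + b <= 1)
        if not hit.any():
            continue
        zhit = v0[2] + a * (v1[2] - v0[2]) + b * (v2[2] - v0[2])
        ii, jj = np.nonzero(hit)
        above = zc[None, :] > zhit[ii, jj][:, None]  # (nhit, nz)
        np.add.at(crossings, (ii + i0, jj + j0), above.astype(np.int32))

    inside = (crossings % 2) == 1
    indicator = np.where(inside, 0, 1).astype(np.uint8)
    mask = VoxelMask(indicator, spacing, tuple(lo), flow_axis=flow_axis or 0)
    if flow_axis is not None:
        mask.validate()
    else:
        mask.validate(require_ports=False)
    return mask


# ---------------------------------------------------------------------
# refinement and smoothing
# ---------------------------------------------------------------------

def refine_mask(mask: VoxelMask, factor: int) -> VoxelMask:
    """Uniformly refine: each cell becomes ``factor**ndim`` cells of the
    same value; spacing is divided by ``factor``.  Port labels are
    recomputed on the refined grid (block replication keeps the fluid
    openings identical, so labels propagate consistently).

    The volume fraction is preserved exactly, and refinement composes:
    ``refine(m, a*b) == refine(refine(m, a), b)``.
    """
    if int(factor) != factor or factor < 1:
        raise UsageError("refinement factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return replace(mask, indicator=mask.indicator.copy(),
                       inlet_faces=mask.inlet_faces.copy(),
                       outlet_faces=mask.outlet_faces.copy())
    ind = mask.indicator
    for axis in range(ind.ndim):
        ind = np.repeat(ind, factor, axis=axis)
    return VoxelMask(ind, mask.spacing / factor, mask.origin,
                     flow_axis=mask.flow_axis)


def smooth_mask(mask: VoxelMask, radius: int) -> VoxelMask:
    """Morphological closing then opening of the solid indicator with a
    ball (disk in 2-D) structuring element.

    Closing fills fluid pits in the solid of size <= radius; the
    subsequent opening removes solid specks of the same scale — the
    voxel analogue of the surface smoothing applied to segmented
    imagery before simulation.  The domain border is treated as solid so
    the padding layers are never eroded.  Raises
    :class:`GeometryError` if smoothing disconnects the fluid path.
    """
    if radius < 0:
        raise UsageError("radius must be >= 0")
    if radius == 0:
        return replace(mask, indicator=mask.indicator.copy(),
                       inlet_faces=mask.inlet_faces.copy(),
                       outlet_faces=mask.outlet_faces.copy())
    from skimage.morphology import ball, disk

    selem = disk(radius) if mask.ndim == 2 else ball(radius)
    # pad by 3r with edge replication: the morphology treats beyond-array
    # as background, so border erosion must never reach the real domain
    pad = 3 * radius
    solid = np.pad(mask.indicator.astype(bool), pad, mode="edge")
    solid = ndimage.binary_closing(solid, structure=selem)
    solid = ndimage.binary_opening(solid, structure=selem)
    core = tuple(slice(pad, -pad) for _ in range(mask.ndim))
    out = VoxelMask(solid[core].astype(np.uint8), mask.spacing, mask.origin,
                    flow_axis=mask.flow_axis)
    out.validate()
    return out


# ---------------------------------------------------------------------
# persistence: compressed arrays with a JSON sidecar
# ---------------------------------------------------------------------

def save_mask(mask: VoxelMask, path: str) -> None:
    """Write the indicator as an .npz array plus a .json sidecar holding
    spacing, origin and the port labels."""
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    np.savez_compressed(base + ".npz", indicator=mask.indicator)
    sidecar = {
        "spacing": mask.spacing,
        "origin": list(mask.origin),
        "flow_axis": mask.flow_axis,
        "inlet_faces": mask.inlet_faces.tolist(),
        "outlet_faces": mask.outlet_faces.tolist(),
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_mask(path: str) -> VoxelMask:
    path = str(path)
    base = path[:-4] if path.endswith((".npz", ".json")) else path
    with np.load(base + ".npz") as data:
        indicator = data["indicator"]
    with open(base + ".json") as fh:
        meta = json.load(fh)
    return VoxelMask(
        indicator,
        float(meta["spacing"]),
        tuple(meta["origin"]),
        flow_axis=int(meta["flow_axis"]),
        inlet_faces=np.asarray(meta["inlet_faces"], dtype=np.intp).reshape(-1, indicator.ndim),
        outlet_faces=np.asarray(meta["outlet_faces"], dtype=np.intp).reshape(-1, indicator.ndim),
    )
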