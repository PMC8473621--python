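"""Scaffold and defect geometry.

The titanium layer of the osteochondral scaffold is a truncated cone
(8.0 mm top / 5.9 mm bottom diameter by default) filled with a log-pile
lattice of cylindrical beams: each sublayer holds parallel beams of
0.5 mm diameter on a regular pitch, and successive sublayers are rotated
90 degrees.  The surgical defect that receives it is a slightly larger
truncated cone; the 0.1 mm annular gap left at the top rim vents air
while bone marrow is injected through the lateral and bottom faces.

All lengths in this module are millimetres.  The z axis points upward
from the defect bottom; the cone axis is x = y = 0.

Morphometrics (porosity, surface area) are computed on voxelizations of
the implicit solid; the flow solver instead uses :class:`SectionGeometry`,
a planar mid-plane cut of the same construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# cell/face label codes shared with the flow solver
FLUID = 0
SCAFFOLD = 1
EXTERIOR = 2

FACE_INTERIOR = 0
FACE_WALL = 1
FACE_INLET_SIDE = 2
FACE_INLET_BOTTOM = 3
FACE_OUTLET = 4

FACE_TAGS = {
    FACE_WALL: "wall",
    FACE_INLET_SIDE: "inlet_side",
    FACE_INLET_BOTTOM: "inlet_bottom",
    FACE_OUTLET: "outlet_gap",
}


@dataclass(frozen=True)
class ScaffoldSpec:
    """Parametric description of the titanium lattice layer.

    ``pore_pitch`` is the clear opening between neighbouring beams, so
    the beam centre-to-centre spacing is ``pore_pitch + beam_diameter``
    (1.5 mm by default, giving the nominal 1 x 1 mm pores).
    """

    top_diameter: float = 8.0
    bottom_diameter: float = 5.9
    height: float = 6.9
    beam_diameter: float = 0.5
    pore_pitch: float = 1.0
    n_sublayers: int = 11
    alternate_orientation: bool = True

    def __post_init__(self) -> None:
        for name in ("top_diameter", "bottom_diameter", "height",
                     "beam_diameter", "pore_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.bottom_diameter > self.top_diameter:
            raise ValueError("bottom_diameter must not exceed top_diameter")
        if self.n_sublayers < 0:
            raise ValueError("n_sublayers must be >= 0")

    @property
    def beam_spacing(self) -> float:
        return self.pore_pitch + self.beam_diameter

    @property
    def layer_pitch(self) -> float:
        return self.height / max(self.n_sublayers, 1)

    def radius_at(self, z):
        """Local cone radius, linear from bottom to top."""
        rb = self.bottom_diameter / 2.0
        rt = self.top_diameter / 2.0
        return rb + (rt - rb) * np.clip(np.asarray(z, float) / self.height, 0.0, 1.0)


@dataclass(frozen=True)
class DefectSpec:
    """The truncated-cone osteochondral defect hosting the scaffold."""

    top_diameter: float = 8.2
    bottom_diameter: float = 5.88
    depth: float = 6.9
    outlet_gap: float = 0.1

    def __post_init__(self) -> None:
        for name in ("top_diameter", "bottom_diameter", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.outlet_gap < 0:
            raise ValueError("outlet_gap must be >= 0")

    def radius_at(self, z):
        rb = self.bottom_diameter / 2.0
        rt = self.top_diameter / 2.0
        return rb + (rt - rb) * np.clip(np.asarray(z, float) / self.depth, 0.0, 1.0)


class LatticeModel:
    """Implicit solid: union of cylindrical beams clipped to the cone.

    Sublayer ``i`` sits at height ``(i + 0.5) * layer_pitch`` with beams
    along x for even ``i`` and along y for odd ``i`` (when alternating).
    Membership is evaluated pointwise, which keeps voxelization exact
    and deterministic.
    """

    def __init__(self, spec: ScaffoldSpec):
        if spec.beam_diameter >= spec.bottom_diameter:
            raise ValueError("beam_diameter must be smaller than the cone "
                             "bottom diameter")
        self.spec = spec

    @property
    def bounds(self):
        r = self.spec.top_diameter / 2.0
        return (-r, -r, 0.0), (r, r, self.spec.height)

    def _beam_dist2(self, x, y, z):
        """Squared distance to the nearest beam axis (ignoring the cone)."""
        s = self.spec
        h = s.layer_pitch
        pitch = s.beam_spacing
        layer = np.clip(np.floor(z / h).astype(int), 0, max(s.n_sublayers - 1, 0))
        zc = (layer + 0.5) * h
        along_x = (layer % 2 == 0) | (not s.alternate_orientation)
        t = np.where(along_x, y, x)
        dt = t - np.round(t / pitch) * pitch
        return dt * dt + (z - zc) ** 2

    def contains(self, points) -> np.ndarray:
        """Boolean membership for an (N, 3) array of points (mm)."""
        p = np.asarray(points, float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        s = self.spec
        if s.n_sublayers == 0:
            return np.zeros(x.shape, bool)
        in_cone = ((z >= 0.0) & (z <= s.height)
                   & (x * x + y * y <= s.radius_at(z) ** 2))
        r = s.beam_diameter / 2.0
        return in_cone & (self._beam_dist2(x, y, z) <= r * r)

    def field(self, points) -> np.ndarray:
        """Smooth inside-positive field (mm) for surface extraction.

        Exact signed distance near the beam surfaces; the cone clip uses
        the slope-uncorrected radial margin, which preserves the zero
        level set location.
        """
        p = np.asarray(points, float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        s = self.spec
        if s.n_sublayers == 0:
            return np.full(x.shape, -1.0)
        beam = s.beam_diameter / 2.0 - np.sqrt(self._beam_dist2(x, y, z))
        rho = np.sqrt(x * x + y * y)
        cone = np.minimum(np.minimum(s.radius_at(z) - rho, z), s.height - z)
        return np.minimum(beam, cone)


@dataclass
class VoxelDomain:
    """Voxelized occupancy with optional boundary-face labels.

    ``occupancy`` holds cell labels (FLUID / SCAFFOLD / EXTERIOR) on a
    regular grid; ``origin`` is the corner of voxel (0, 0, 0) and
    ``spacing`` the cubic voxel edge, both mm.  ``frustum`` remembers the
    scaffold cone so porosity can be restricted to it.  ``face_labels``
    (one uint8 array per axis, staggered shape) is populated by
    :func:`build_defect_domain`.
    """

    spacing: float
    origin: np.ndarray
    occupancy: np.ndarray
    frustum: ScaffoldSpec | None = None
    face_labels: tuple | None = None
    solid_fn: object = None

    @property
    def shape(self):
        return self.occupancy.shape

    def centers(self):
        """Voxel-centre coordinate axes (mm)."""
        return tuple(self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing
                     for a in range(3))

    def solid_fraction(self) -> float:
        return float(np.mean(self.occupancy == SCAFFOLD))

    def face_counts(self) -> dict:
        """Number of labeled boundary faces per tag."""
        out = {tag: 0 for tag in FACE_TAGS.values()}
        if self.face_labels is None:
            return out
        for arr in self.face_labels:
            for code, tag in FACE_TAGS.items():
                out[tag] += int(np.sum(arr == code))
        return out


def build_titanium_lattice(spec: ScaffoldSpec) -> LatticeModel:
    """Construct the implicit beam-lattice solid for ``spec``."""
    return LatticeModel(spec)


def voxelize(lattice: LatticeModel, spacing: float) -> VoxelDomain:
    """Sample lattice membership at voxel centres on a cubic grid.

    The grid covers the lattice bounding box; a voxel is solid iff its
    centre lies inside the implicit solid (no fractional occupancy).
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    lo, hi = lattice.bounds
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    xs, ys, zs = (lo[a] + (np.arange(shape[a]) + 0.5) * spacing for a in range(3))
    occ = np.full(tuple(shape), FLUID, np.uint8)
    # slab-by-slab keeps peak memory at one z-plane of points
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.empty(X.shape + (3,))
    pts[..., 0], pts[..., 1] = X, Y
    for k, z in enumerate(zs):
        pts[..., 2] = z
        occ[:, :, k] = np.where(lattice.contains(pts), SCAFFOLD, FLUID)
    return VoxelDomain(spacing=spacing, origin=lo, occupancy=occ,
                       frustum=getattr(lattice, "spec", None),
                       solid_fn=lattice.contains)


def porosity(domain: VoxelDomain) -> float:
    """Void fraction inside the scaffold's bounding frustum.

    Counts void voxels among voxels whose centres fall inside the
    truncated cone; if the domain carries no frustum the whole grid is
    used.
    """
    occ = domain.occupancy
    if domain.frustum is not None:
        xs, ys, zs = domain.centers()
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        rho2 = (X * X + Y * Y)[:, :, None]
        R = domain.frustum.radius_at(zs)[None, None, :]
        inside = (rho2 <= R * R) & (zs[None, None, :] >= 0) \
            & (zs[None, None, :] <= domain.frustum.height)
    else:
        inside = np.ones(occ.shape, bool)
    n = int(inside.sum())
    if n == 0:
        raise ValueError("empty frustum: no voxel centres inside the cone")
    return 1.0 - float(np.sum((occ == SCAFFOLD) & inside)) / n


def surface_area(solid, spacing: float) -> float:
    """Surface area (mm^2) of an implicit solid by marching cubes.

    ``solid`` needs ``bounds`` and a ``field(points)`` inside-positive
    function (``LatticeModel`` qualifies).  The field is sampled on a
    grid padded by one layer so the surface closes at the bounds.
    """
    from skimage import measure

    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    lo, hi = solid.bounds
    lo = np.asarray(lo, float) - 2 * spacing
    hi = np.asarray(hi, float) + 2 * spacing
    axes = [np.arange(lo[a], hi[a] + spacing / 2, spacing) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    vol = solid.field(np.stack([X, Y, Z], axis=-1))
    if vol.max() <= 0:
        return 0.0
    verts, faces, _, _ = measure.marching_cubes(
        vol, level=0.0, spacing=(spacing,) * 3)
    return float(measure.mesh_surface_area(verts, faces))


def build_defect_domain(scaffold: VoxelDomain, defect: DefectSpec) -> VoxelDomain:
    """Embed the voxelized scaffold into the defect cone and label faces.

    Void space is the defect frustum minus the scaffold solid; everything
    outside the frustum (host bone) is EXTERIOR.  Boundary faces of the
    void are tagged: lateral frustum surface -> inlet_side, bottom disc
    -> inlet_bottom, the top annulus of width ``outlet_gap`` -> the air
    vent, the rest of the top -> wall (the dense PLA cap).  Faces against
    the scaffold solid are walls.
    """
    spec = scaffold.frustum
    if spec is None:
        raise ValueError("scaffold domain must carry its frustum spec")
    if spec.height > defect.depth + 1e-9:
        raise ValueError("scaffold protrudes beyond the defect depth")
    if spec.top_diameter > defect.top_diameter + 1e-9:
        raise ValueError("scaffold top wider than the defect")
    sp = scaffold.spacing
    rt = defect.top_diameter / 2.0
    lo = np.array([-rt, -rt, 0.0])
    hi = np.array([rt, rt, defect.depth])
    shape = np.maximum(np.ceil((hi - lo) / sp).astype(int), 1)
    xs, ys, zs = (lo[a] + (np.arange(shape[a]) + 0.5) * sp for a in range(3))
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rho2 = (X * X + Y * Y)[:, :, None]
    Rd = defect.radius_at(zs)[None, None, :]
    in_defect = rho2 <= Rd * Rd
    occ = np.where(in_defect, FLUID, EXTERIOR).astype(np.uint8)
    if scaffold.solid_fn is not None:
        pts = np.empty(X.shape + (3,))
        pts[..., 0], pts[..., 1] = X, Y
        for k, z in enumerate(zs):
            pts[..., 2] = z
            occ[:, :, k][scaffold.solid_fn(pts) & in_defect[:, :, k]] = SCAFFOLD

    face_labels = _label_faces_3d(occ, xs, ys, zs, defect)
    dom = VoxelDomain(spacing=sp, origin=lo, occupancy=occ, frustum=spec,
                      face_labels=face_labels, solid_fn=scaffold.solid_fn)
    return dom


def _label_faces_3d(occ, xs, ys, zs, defect: DefectSpec):
    """Tag every boundary face of the void region exactly once."""
    nx, ny, nz = occ.shape
    fluid = occ == FLUID
    fx = np.zeros((nx + 1, ny, nz), np.uint8)
    fy = np.zeros((nx, ny + 1, nz), np.uint8)
    fz = np.zeros((nx, ny, nz + 1), np.uint8)

    # interior faces between fluid and non-fluid
    for arr, axis in ((fx, 0), (fy, 1), (fz, 2)):
        a = fluid[tuple(slice(None, -1) if ax == axis else slice(None)
                        for ax in range(3))]
        b = fluid[tuple(slice(1, None) if ax == axis else slice(None)
                        for ax in range(3))]
        boundary = a ^ b
        nbr_solid = np.where(a, ~b, ~a)  # the non-fluid side
        occ_a = occ[tuple(slice(None, -1) if ax == axis else slice(None)
                          for ax in range(3))]
        occ_b = occ[tuple(slice(1, None) if ax == axis else slice(None)
                          for ax in range(3))]
        nbr = np.where(a, occ_b, occ_a)
        inner = tuple(slice(1, -1) if ax == axis else slice(None)
                      for ax in range(3))
        code = np.where(nbr == EXTERIOR, FACE_INLET_SIDE, FACE_WALL)
        arr[inner] = np.where(boundary & nbr_solid, code, 0)

    # domain-boundary faces of fluid cells
    fx[0, :, :][fluid[0, :, :]] = FACE_INLET_SIDE
    fx[-1, :, :][fluid[-1, :, :]] = FACE_INLET_SIDE
    fy[:, 0, :][fluid[:, 0, :]] = FACE_INLET_SIDE
    fy[:, -1, :][fluid[:, -1, :]] = FACE_INLET_SIDE
    fz[:, :, 0][fluid[:, :, 0]] = FACE_INLET_BOTTOM
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rho = np.sqrt(X * X + Y * Y)
    top_outlet = rho >= (defect.top_diameter / 2.0 - defect.outlet_gap)
    top = fluid[:, :, -1]
    fz[:, :, -1][top & top_outlet] = FACE_OUTLET
    fz[:, :, -1][top & ~top_outlet] = FACE_WALL
    return fx, fy, fz


# ---------------------------------------------------------------------------
# planar mid-plane section used by the reduced-scale flow model
# ---------------------------------------------------------------------------

@dataclass
class SectionGeometry:
    """Analytic mid-plane (x-z) cut of scaffold + defect, in metres.

    Every lattice sublayer appears as a row of circular beam sections of
    the beam diameter on the beam spacing; successive rows are staggered
    by half a spacing to stand in for the alternating beam orientation
    of the 3D log-pile.  Beam sections are clipped to the scaffold cone.
    The surrounding defect walls are the slanted frustum sides, the
    bottom disc and the capped top with the air-vent spans at its rim.
    """

    scaffold: ScaffoldSpec
    defect: DefectSpec
    beam_centers: np.ndarray = field(init=False)  # (M, 2) metres
    beam_layers: np.ndarray = field(init=False)
    beam_radius: float = field(init=False)

    def __post_init__(self) -> None:
        s = self.scaffold
        r = s.beam_diameter / 2.0
        pitch = s.beam_spacing
        centers, layers = [], []
        jmax = int(np.ceil((s.top_diameter / 2.0) / pitch)) + 1
        for i in range(s.n_sublayers):
            zc = (i + 0.5) * s.layer_pitch
            off = 0.0 if i % 2 == 0 or not s.alternate_orientation else pitch / 2.0
            for j in range(-jmax, jmax + 1):
                xc = j * pitch + off
                # keep a beam only if some of its section lies in the cone
                if abs(xc) - r < float(s.radius_at(zc)):
                    centers.append((xc * 1e-3, zc * 1e-3))
                    layers.append(i)
        self.beam_centers = (np.asarray(centers, float).reshape(-1, 2)
                             if centers else np.zeros((0, 2)))
        self.beam_layers = np.asarray(layers, int)
        self.beam_radius = r * 1e-3

    @property
    def depth(self) -> float:
        return self.defect.depth * 1e-3

    @property
    def half_width(self) -> float:
        return self.defect.top_diameter / 2.0 * 1e-3

    def defect_radius_at(self, z):
        return np.asarray(self.defect.radius_at(np.asarray(z) * 1e3)) * 1e-3

    def scaffold_radius_at(self, z):
        return np.asarray(self.scaffold.radius_at(np.asarray(z) * 1e3)) * 1e-3

    def in_scaffold(self, x, z):
        """Beam-section membership for metre coordinates (vectorized)."""
        x = np.atleast_1d(np.asarray(x, float))
        z = np.atleast_1d(np.asarray(z, float))
        if len(self.beam_centers) == 0:
            return np.zeros(x.shape, bool)
        d2 = ((x[:, None] - self.beam_centers[None, :, 0]) ** 2
              + (z[:, None] - self.beam_centers[None, :, 1]) ** 2)
        in_beam = (d2 <= self.beam_radius**2).any(axis=1)
        in_cone = ((z >= 0) & (z <= self.scaffold.height * 1e-3)
                   & (np.abs(x) <= self.scaffold_radius_at(z)))
        return in_beam & in_cone

    def in_defect(self, x, z):
        x = np.asarray(x, float)
        z = np.asarray(z, float)
        return (z >= 0) & (z <= self.depth) & (np.abs(x) <= self.defect_radius_at(z))

    def nearest_beam(self, pts):
        """(distance to beam surface, beam index) for (N, 2) metre points."""
        if len(self.beam_centers) == 0:
            n = np.atleast_2d(pts).shape[0]
            return np.full(n, np.inf), np.full(n, -1)
        p = np.atleast_2d(pts)
        c = self.beam_centers
        c2 = getattr(self, "_c2", None)
        if c2 is None:
            c2 = (c * c).sum(1)
            self._c2 = c2
        # |p - c|^2 = |p|^2 - 2 p.c + |c|^2, evaluated as one GEMM
        d2 = (p * p).sum(1)[:, None] - 2.0 * (p @ c.T) + c2[None, :]
        idx = np.argmin(d2, axis=1)
        d = np.sqrt(np.maximum(d2[np.arange(len(p)), idx], 0.0))
        return d - self.beam_radius, idx

    def wall_distance(self, pts):
        """Distance and outward-into-fluid normal of the defect walls.

        Returns (dist, normal (N,2), kind) where kind is 'bottom',
        'side', 'top'.  Distances are positive inside the defect.
        """
        p = np.atleast_2d(pts)
        x, z = p[:, 0], p[:, 1]
        # bottom
        d_bot = z
        # slanted sides: line through (r_b, 0) and (r_t, depth)
        rb = self.defect.bottom_diameter / 2.0 * 1e-3
        rt = self.defect.top_diameter / 2.0 * 1e-3
        slope = (rt - rb) / self.depth
        denom = np.sqrt(1.0 + slope * slope)
        d_side = (rb + slope * z - np.abs(x)) / denom
        d_top = self.depth - z
        dists = np.stack([d_bot, d_side, d_top], axis=1)
        kind_idx = np.argmin(dists, axis=1)
        dist = dists[np.arange(len(p)), kind_idx]
        normals = np.zeros((len(p), 2))
        normals[kind_idx == 0] = (0.0, 1.0)
        normals[kind_idx == 2] = (0.0, -1.0)
        side = kind_idx == 1
        # into-fluid normal of the slanted wall points toward the axis
        normals[side] = np.stack([-np.sign(x[side]) / denom,
                                  np.full(side.sum(), slope / denom)], axis=1)
        kinds = np.array(["bottom", "side", "top"])[kind_idx]
        return dist, normals, kinds

    def radial_band(self, x, n_bands: int = 5):
        """1-based band index across the scaffold top diameter."""
        half = self.scaffold.top_diameter / 2.0 * 1e-3
        t = (np.asarray(x, float) + half) / (2 * half)
        return np.clip((t * n_bands).astype(int), 0, n_bands - 1) + 1


@dataclass
class SectionDomain:
    """Cartesian MAC discretization of a :class:`SectionGeometry`.

    ``cell_type`` is (nx, nz) with FLUID/SCAFFOLD/EXTERIOR codes;
    ``fx``/``fz`` are staggered face-label arrays ((nx+1, nz) and
    (nx, nz+1)).  Coordinates are metres; x spans the defect top
    diameter, z the depth.
    """

    geometry: SectionGeometry
    nx: int
    nz: int
    dx: float = field(init=False)
    dz: float = field(init=False)
    x0: float = field(init=False)
    cell_type: np.ndarray = field(init=False)
    fx: np.ndarray = field(init=False)
    fz: np.ndarray = field(init=False)
    outlet_span: float = field(init=False)

    def __post_init__(self) -> None:
        g = self.geometry
        self.x0 = -g.half_width
        self.dx = 2 * g.half_width / self.nx
        self.dz = g.depth / self.nz
        xc = self.x0 + (np.arange(self.nx) + 0.5) * self.dx
        zc = (np.arange(self.nz) + 0.5) * self.dz
        X, Z = np.meshgrid(xc, zc, indexing="ij")
        in_def = g.in_defect(X.ravel(), Z.ravel()).reshape(X.shape)
        in_sc = g.in_scaffold(X.ravel(), Z.ravel()).reshape(X.shape)
        ct = np.where(in_def, FLUID, EXTERIOR).astype(np.uint8)
        ct[in_sc & in_def] = SCAFFOLD
        self.cell_type = ct
        # vent span: the physical 0.1 mm rim gap, but at least one cell
        self.outlet_span = max(g.defect.outlet_gap * 1e-3, self.dx)
        self._label_faces(xc)

    def _label_faces(self, xc) -> None:
        ct = self.cell_type
        fluid = ct == FLUID
        nx, nz = self.nx, self.nz
        fx = np.zeros((nx + 1, nz), np.uint8)
        fz = np.zeros((nx, nz + 1), np.uint8)
        # vertical faces between columns
        a, b = fluid[:-1, :], fluid[1:, :]
        nbr = np.where(a, ct[1:, :], ct[:-1, :])
        code = np.where(nbr == EXTERIOR, FACE_INLET_SIDE, FACE_WALL)
        fx[1:-1, :] = np.where((a ^ b), code, 0)
        fx[0, :][fluid[0, :]] = FACE_INLET_SIDE
        fx[-1, :][fluid[-1, :]] = FACE_INLET_SIDE
        # horizontal faces between rows
        a, b = fluid[:, :-1], fluid[:, 1:]
        nbr = np.where(a, ct[:, 1:], ct[:, :-1])
        code = np.where(nbr == EXTERIOR, FACE_INLET_SIDE, FACE_WALL)
        fz[:, 1:-1] = np.where((a ^ b), code, 0)
        fz[:, 0][fluid[:, 0]] = FACE_INLET_BOTTOM
        rim = self.geometry.defect_radius_at(self.geometry.depth)
        vent = np.abs(xc) >= rim - self.outlet_span
        top = fluid[:, -1]
        if self.geometry.defect.outlet_gap > 0:
            fz[:, -1][top & vent] = FACE_OUTLET
        fz[:, -1][top & ~vent] = FACE_WALL
        if self.geometry.defect.outlet_gap <= 0:
            fz[:, -1][top & vent] = FACE_WALL
        self.fx, self.fz = fx, fz

    @property
    def cell_area(self) -> float:
        """Section cell area (m^2); the section carries unit depth."""
        return self.dx * self.dz

    def face_counts(self) -> dict:
        out = {tag: 0 for tag in FACE_TAGS.values()}
        for arr in (self.fx, self.fz):
            for code, tag in FACE_TAGS.items():
                out[tag] += int(np.sum(arr == code))
        return out

    def cell_centers(self):
        xc = self.x0 + (np.arange(self.nx) + 0.5) * self.dx
        zc = (np.arange(self.nz) + 0.5) * self.dz
        return xc, zc

    def cell_of(self, pts):
        """Cell indices for (N, 2) metre points (clipped to the grid)."""
        p = np.atleast_2d(pts)
        i = np.clip(((p[:, 0] - self.x0) / self.dx).astype(int), 0, self.nx - 1)
        k = np.clip((p[:, 1] / self.dz).astype(int), 0, self.nz - 1)
        return i, k


def build_section_domain(scaffold: ScaffoldSpec | None = None,
                         defect: DefectSpec | None = None,
                         nx: int = 64, nz: int = 96) -> SectionDomain:
    """Convenience builder for the default reduced-scale flow domain."""
    geo = SectionGeometry(scaffold or ScaffoldSpec(), defect or DefectSpec())
    return SectionDomain(geo, nx, nz)
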