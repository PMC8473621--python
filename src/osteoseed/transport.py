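"""Lagrangian tracking of BMSC particles in the resolved flow.

Cells are non-rotating rigid spheres (25 um, 1000 kg/m^3) carried
one-way by the marrow: each step integrates the force balance

    m_p dv/dt = F_drag + (rho_p - rho_f) V_p g

with Stokes drag corrected by the Schiller-Naumann factor
(1 + 0.15 Re_p^0.687), semi-implicitly so the stiff drag relaxation
(tau ~ 3.5 us at defaults) is unconditionally stable.  Fluid velocity
and mixture properties are interpolated bilinearly from the staggered
grid to the particle position.

Impingement against the scaffold beams and the defect walls is detected
with the analytic section geometry: an event fires when a particle's
surface (centre within d/2 of a wall) reaches a surface while moving
toward it.  What happens next (stick / rebound / spread) is decided by
the adhesion module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SectionDomain

SUSPENDED, STUCK, SPREAD, ESCAPED = 0, 1, 2, 3
STATUS_NAMES = {SUSPENDED: "suspended", STUCK: "stuck", SPREAD: "spread",
                ESCAPED: "escaped"}


@dataclass
class CellPhase:
    """Growable ensemble of cell particles (SI units, 2D positions)."""

    diameter: float = 25e-6
    density: float = 1000.0
    surface_tension: float = 0.03
    capacity: int = 1024
    n: int = 0
    pos: np.ndarray = field(default=None)
    vel: np.ndarray = field(default=None)
    status: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("diameter and density must be > 0")
        if self.pos is None:
            self.pos = np.zeros((self.capacity, 2))
            self.vel = np.zeros((self.capacity, 2))
            self.status = np.zeros(self.capacity, np.int8)

    @property
    def mass(self) -> float:
        """Mass of one cell, kg."""
        return self.density * np.pi / 6.0 * self.diameter**3

    def _grow(self, need: int):
        cap = len(self.status)
        if self.n + need <= cap:
            return
        new_cap = max(2 * cap, self.n + need)
        for name in ("pos", "vel"):
            arr = np.zeros((new_cap, 2))
            arr[:self.n] = getattr(self, name)[:self.n]
            setattr(self, name, arr)
        status = np.zeros(new_cap, np.int8)
        status[:self.n] = self.status[:self.n]
        self.status = status

    def add(self, pos, vel):
        pos = np.atleast_2d(pos)
        self._grow(len(pos))
        sl = slice(self.n, self.n + len(pos))
        self.pos[sl] = pos
        self.vel[sl] = np.atleast_2d(vel)
        self.status[sl] = SUSPENDED
        self.n += len(pos)

    def counts(self) -> dict:
        s = self.status[:self.n]
        return {name: int(np.sum(s == code))
                for code, name in STATUS_NAMES.items()}

    def suspended_idx(self) -> np.ndarray:
        return np.nonzero(self.status[:self.n] == SUSPENDED)[0]


@dataclass
class InjectionSchedule:
    """When, where, and how many cells enter the defect.

    Cells are released uniformly over the inlet faces throughout the
    window; cumulative counts follow round(n_cells * elapsed fraction)
    so the window delivers exactly ``n_cells``.  In the
    ``continued_injection`` scenario the same number rate carries on
    after the window at ``post_fill_speed``.
    """

    n_cells: int = 50_000
    window: tuple = (0.0, 2.5)
    speed: float = 1e-3
    post_fill_mode: str = "continued_injection"
    post_fill_speed: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.window[1] <= self.window[0]:
            raise ValueError("window must have positive length")
        if self.post_fill_mode not in ("no_injection", "continued_injection"):
            raise ValueError("unknown post_fill_mode")

    def cumulative(self, t: float) -> int:
        """Target number of cells injected by time t."""
        t0, t1 = self.window
        rate = self.n_cells / (t1 - t0)
        if t <= t0:
            return 0
        if t <= t1 or self.post_fill_mode == "continued_injection":
            return int(round(rate * (min(t, t1) - t0)
                             + (rate * (t - t1)
                                if t > t1 and
                                self.post_fill_mode == "continued_injection"
                                else 0.0)))
        return self.n_cells


class _InletFaces:
    """Flattened inlet-face geometry for uniform sampling."""

    def __init__(self, domain: SectionDomain):
        d = domain
        xs, zs, nx_, nz_, lengths = [], [], [], [], []
        xc = d.x0 + (np.arange(d.nx) + 0.5) * d.dx
        zc = (np.arange(d.nz) + 0.5) * d.dz
        from .geometry import FACE_INLET_BOTTOM, FACE_INLET_SIDE, FLUID
        inlet_x = np.isin(d.fx, (FACE_INLET_SIDE, FACE_INLET_BOTTOM))
        for i, k in zip(*np.nonzero(inlet_x)):
            sign = 1.0 if i < d.nx and d.cell_type[i, k] == FLUID else -1.0
            xs.append(d.x0 + i * d.dx)
            zs.append(zc[k])
            nx_.append(sign)
            nz_.append(0.0)
            lengths.append(d.dz)
        inlet_z = np.isin(d.fz, (FACE_INLET_SIDE, FACE_INLET_BOTTOM))
        for i, k in zip(*np.nonzero(inlet_z)):
            sign = 1.0 if k < d.nz and d.cell_type[i, k] == FLUID else -1.0
            xs.append(xc[i])
            zs.append(k * d.dz)
            nx_.append(0.0)
            nz_.append(sign)
            lengths.append(d.dx)
        self.center = np.stack([xs, zs], axis=1) if xs else np.zeros((0, 2))
        self.normal = np.stack([nx_, nz_], axis=1) if xs else np.zeros((0, 2))
        self.length = np.asarray(lengths)
        self.prob = self.length / self.length.sum() if xs else None
        self.dx, self.dz = d.dx, d.dz


def inject(schedule: InjectionSchedule, domain: SectionDomain, cells: CellPhase,
           t: float, dt: float, rng: np.random.Generator,
           injected_so_far: int | None = None) -> int:
    """Release the cells due in (t, t+dt]; returns how many were added.

    Particles appear uniformly over the inlet faces (weighted by face
    length), half a cell inside the fluid, moving inward at the
    injection speed.
    """
    done = cells.n if injected_so_far is None else injected_so_far
    due = schedule.cumulative(t + dt) - done
    if due <= 0:
        return 0
    faces = getattr(domain, "_inlet_faces", None)
    if faces is None:
        faces = _InletFaces(domain)
        domain._inlet_faces = faces
    if faces.prob is None:
        return 0
    idx = rng.choice(len(faces.prob), size=due, p=faces.prob)
    frac = rng.uniform(-0.5, 0.5, size=due)
    tang = np.stack([faces.normal[idx, 1], faces.normal[idx, 0]], axis=1)
    offset = 0.5 * np.where(faces.normal[idx] != 0,
                            [faces.dx, faces.dz], 0.0).sum(axis=1)
    pos = (faces.center[idx]
           + tang * (frac * faces.length[idx])[:, None]
           + faces.normal[idx] * offset[:, None])
    geo = getattr(domain, "geometry", None)
    if geo is not None:
        # staircase inlet faces can overhang the analytic frustum; push
        # any such release point back inside with a one-diameter margin
        clear = cells.diameter
        d, nvec, _ = geo.wall_distance(pos)
        short = d < clear
        pos[short] += nvec[short] * (clear - d[short])[:, None]
    speed = (schedule.post_fill_speed if t >= schedule.window[1]
             else schedule.speed)
    vel = faces.normal[idx] * speed
    cells.add(pos, vel)
    return due


def _sample_mac(arr, gx, gz):
    """Bilinear sample of a 2D array at fractional grid coordinates."""
    m, n = arr.shape
    gx = np.clip(gx, 0.0, m - 1.0)
    gz = np.clip(gz, 0.0, n - 1.0)
    i0 = np.minimum(gx.astype(int), m - 2) if m > 1 else np.zeros_like(gx, int)
    k0 = np.minimum(gz.astype(int), n - 2) if n > 1 else np.zeros_like(gz, int)
    fx = gx - i0
    fz = gz - k0
    i1 = np.minimum(i0 + 1, m - 1)
    k1 = np.minimum(k0 + 1, n - 1)
    return ((1 - fx) * (1 - fz) * arr[i0, k0] + fx * (1 - fz) * arr[i1, k0]
            + (1 - fx) * fz * arr[i0, k1] + fx * fz * arr[i1, k1])


def fluid_velocity_at(state, domain, pts) -> np.ndarray:
    """Bilinear MAC interpolation of (u, w) at (N, 2) positions."""
    p = np.atleast_2d(pts)
    gx = (p[:, 0] - domain.x0) / domain.dx
    gz = p[:, 1] / domain.dz
    u = _sample_mac(state.u, gx, gz - 0.5)
    w = _sample_mac(state.w, gx - 0.5, gz)
    return np.stack([u, w], axis=1)


def advance(cells: CellPhase, state, domain, rheo, dt: float,
            gravity=(0.0, -9.81), mu_field=None) -> None:
    """Semi-implicit drag + buoyancy update of suspended particles."""
    idx = cells.suspended_idx()
    if len(idx) == 0:
        return
    p = cells.pos[idx]
    v = cells.vel[idx]
    uf = fluid_velocity_at(state, domain, p)
    gx = (p[:, 0] - domain.x0) / domain.dx - 0.5
    gz = p[:, 1] / domain.dz - 0.5
    if mu_field is None:
        solver = getattr(state, "solver", None)
        if solver is not None:
            _, mu_field = solver.mixture(state)
    if mu_field is not None:
        mu = _sample_mac(mu_field, gx, gz)
        rho_f = _sample_mac(state.alpha, gx, gz) * rheo.rho
    else:
        mu = np.full(len(idx), rheo.eta_max)
        rho_f = np.full(len(idx), rheo.rho)
    d = cells.diameter
    rho_p = cells.density
    rel = uf - v
    rel_mag = np.sqrt((rel**2).sum(1))
    re_p = rho_f * rel_mag * d / np.maximum(mu, 1e-12)
    f_corr = 1.0 + 0.15 * re_p**0.687
    tau = rho_p * d * d / (18.0 * np.maximum(mu, 1e-12)) / f_corr
    g = np.asarray(gravity)
    g_eff = (1.0 - rho_f / rho_p)[:, None] * g[None, :]
    a = dt / tau
    v_new = (v + a[:, None] * uf + dt * g_eff) / (1.0 + a[:, None])
    cells.vel[idx] = v_new
    cells.pos[idx] = p + dt * v_new


@dataclass
class ImpingementEvents:
    """Vectorized record of one step's wall/beam contacts."""

    index: np.ndarray       # particle indices
    kind: np.ndarray        # 'beam' | 'boundary' | 'cap' | 'outlet'
    beam_id: np.ndarray     # -1 for non-beam surfaces
    normal: np.ndarray      # (N, 2) into-fluid unit normals
    v_normal: np.ndarray    # approach speed along -normal, >= 0
    point: np.ndarray       # (N, 2) contact position

    def __len__(self):
        return len(self.index)


def detect_impingement(cells: CellPhase, domain: SectionDomain,
                       dt: float) -> ImpingementEvents:
    """Find suspended particles touching a surface while approaching it.

    A contact means the particle centre is within d/2 of the nearest
    beam section or defect wall (or past it) with velocity directed into
    the surface.  Particles reaching the top rim inside the vent span
    are marked for escape.
    """
    geo = domain.geometry
    idx = cells.suspended_idx()
    empty = ImpingementEvents(np.zeros(0, int), np.zeros(0, object),
                              np.zeros(0, int), np.zeros((0, 2)),
                              np.zeros(0), np.zeros((0, 2)))
    if len(idx) == 0:
        return empty
    p = cells.pos[idx]
    v = cells.vel[idx]
    r = cells.diameter / 2.0
    d_beam, beam_id = geo.nearest_beam(p)
    d_wall, n_wall, kind_wall = geo.wall_distance(p)
    use_beam = d_beam < d_wall
    dist = np.where(use_beam, d_beam, d_wall)
    touching = dist <= r
    if not touching.any():
        return empty
    sel = np.nonzero(touching)[0]
    normals = np.empty((len(sel), 2))
    kinds = np.empty(len(sel), object)
    bids = np.full(len(sel), -1)
    rim = geo.defect_radius_at(geo.depth)
    span = getattr(domain, "outlet_span", geo.defect.outlet_gap * 1e-3)
    ub = use_beam[sel]
    if ub.any():
        bsel = sel[ub]
        nvec = p[bsel] - geo.beam_centers[beam_id[bsel]]
        nn = np.sqrt((nvec**2).sum(1))
        nvec = np.where(nn[:, None] > 0, nvec / np.maximum(nn, 1e-300)[:, None],
                        (0.0, 1.0))
        normals[ub] = nvec
        kinds[ub] = "beam"
        bids[ub] = beam_id[bsel]
    if (~ub).any():
        wsel = sel[~ub]
        normals[~ub] = n_wall[wsel]
        kw = kind_wall[wsel]
        at_vent = ((np.abs(p[wsel, 0]) >= rim - span)
                   & (geo.defect.outlet_gap > 0))
        wk = np.where(kw == "top", np.where(at_vent, "outlet", "cap"),
                      "boundary")
        kinds[~ub] = wk
    vn = -(v[sel] * normals).sum(axis=1)
    approaching = vn > 0
    # particles already overlapping are events regardless of velocity
    overlap = dist[sel] < r * 0.999
    keep = approaching | overlap
    sel = sel[keep]
    if len(sel) == 0:
        return empty
    normals = normals[keep]
    kinds = kinds[keep]
    bids = bids[keep]
    vn = np.maximum(vn[keep], 0.0)
    contact = p[sel] - normals * (dist[sel] - r)[:, None]
    return ImpingementEvents(index=idx[sel], kind=kinds, beam_id=bids,
                             normal=normals, v_normal=vn, point=contact)
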