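"""Two-phase marrow/air flow on the defect section.

Reduced-scale incompressible solver for the marrow-filling stage: a
planar mid-plane cut of the defect + scaffold is discretized on a
staggered (MAC) grid, the marrow volume fraction ``alpha`` is captured
with a conservative donor-cell VOF scheme, and the marrow viscosity is
the clamped power law evaluated from the local shear rate every step.

Time stepping per step:

1. mixture properties ``rho = a*rho_m + (1-a)*rho_air`` (same for mu,
   with the power-law viscosity for the marrow part),
2. explicit advection (hybrid central/upwind) + gravity,
3. variable-viscosity diffusion, explicit but subcycled to a Gershgorin
   stability bound, with harmonic viscosity averaging at faces/corners
   so phase and wall contrasts stay non-stiff,
4. variable-density pressure projection: matrix-free preconditioned CG
   with a cached direct factorization as preconditioner, iterated until
   the post-correction divergence is below tolerance,
5. donor-cell VOF transport with inlet/outlet fluxes and flux
   bookkeeping for the mass-conservation audit.

Velocities are m/s, lengths m, pressures Pa.  The 2D section carries
unit depth, so "volumes" are areas times 1 m.  Walls and scaffold beams
are no-slip with zero roughness; marrow is injected with fixed normal
speed on the lateral/bottom inlet faces while injection is active; the
top vent is a zero-pressure outlet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (FACE_INLET_BOTTOM, FACE_INLET_SIDE, FACE_OUTLET,
                       FACE_WALL, FLUID, FACE_TAGS)
from .rheology import MarrowRheology, apparent_viscosity


@dataclass(frozen=True)
class FlowConfig:
    """Run parameters for the filling simulation (SI units)."""

    inlet_speed: float = 1e-3        # marrow injection speed, m/s
    fill_duration: float = 2.5       # marrow/cell injection window, s
    total_duration: float = 5.0      # simulated time, s
    dt: float | None = None          # fixed step; None = adaptive
    dt_max: float = 2e-3
    gravity: tuple = (0.0, -9.81)
    air_density: float = 1.2
    air_viscosity: float = 1.8e-5
    cfl_limit: float = 0.4
    divergence_tol: float = 1e-6     # max |div u| allowed, 1/s
    post_fill_inflow: bool = False   # continued-injection scenario

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.fill_duration > self.total_duration:
            raise ValueError("fill_duration must not exceed total_duration")
        if not 0 < self.cfl_limit < 1:
            raise ValueError("cfl_limit must be in (0, 1)")


@dataclass
class FlowState:
    """Staggered velocity, pressure, and marrow-fraction fields."""

    u: np.ndarray                 # (nx+1, nz) x-face velocities
    w: np.ndarray                 # (nx, nz+1) z-face velocities
    p: np.ndarray                 # (nx, nz) cell pressures
    alpha: np.ndarray             # (nx, nz) marrow volume fraction
    time: float = 0.0
    influx: float = 0.0           # cumulative marrow volume in, m^3
    outflux: float = 0.0          # cumulative marrow volume out, m^3
    clip_residual: float = 0.0    # |alpha| clipped outside [0,1]
    max_divergence: float = 0.0
    mu_field: np.ndarray | None = None   # last mixture viscosity
    solver: object = None


class BoxDomain:
    """Plain rectangular fluid box for fixtures and benchmarks.

    All-fluid interior with no-slip walls; ``lid`` names a side carrying
    a tangential velocity (for the driven-cavity benchmark) and
    ``outlet_top`` opens the whole top as a pressure outlet.
    """

    def __init__(self, nx, nz, lx=1.0, lz=1.0, lid=None, lid_speed=0.0,
                 outlet_top=False, inlet_bottom=False):
        self.nx, self.nz = nx, nz
        self.dx, self.dz = lx / nx, lz / nz
        self.x0 = 0.0
        self.cell_type = np.full((nx, nz), FLUID, np.uint8)
        self.fx = np.zeros((nx + 1, nz), np.uint8)
        self.fz = np.zeros((nx, nz + 1), np.uint8)
        self.fx[0, :] = self.fx[-1, :] = FACE_WALL
        self.fz[:, 0] = FACE_INLET_BOTTOM if inlet_bottom else FACE_WALL
        self.fz[:, -1] = FACE_OUTLET if outlet_top else FACE_WALL
        self.lid = lid
        self.lid_speed = lid_speed

    def face_counts(self):
        out = {tag: 0 for tag in FACE_TAGS.values()}
        for arr in (self.fx, self.fz):
            for code, tag in FACE_TAGS.items():
                out[tag] += int(np.sum(arr == code))
        return out


class _Stencil5:
    """Fixed-pattern 5-point sparse operator on an (m, n) grid.

    The sparsity pattern (diag + existing E/W/N/S neighbours) is built
    once; per-step only the coefficient data changes, which keeps the
    repeated factorizations cheap.
    """

    def __init__(self, m, n):
        self.m, self.n = m, n
        N = m * n
        ids = np.arange(N).reshape(m, n)
        rows, cols, self.slots = [], [], {}
        order = [("C", ids, ids)]
        east = (ids[:-1, :], ids[1:, :])
        west = (ids[1:, :], ids[:-1, :])
        north = (ids[:, :-1], ids[:, 1:])
        south = (ids[:, 1:], ids[:, :-1])
        for name, (r, c) in [("E", east), ("W", west), ("N", north),
                             ("S", south)]:
            order.append((name, r, c))
        pos = 0
        for name, r, c in order:
            r, c = np.ravel(r), np.ravel(c)
            rows.append(r)
            cols.append(c)
            self.slots[name] = (pos, len(r), r)
            pos += len(r)
        self._rows = np.concatenate(rows)
        self._cols = np.concatenate(cols)
        self._data = np.zeros(pos)
        coo = sp.coo_matrix((np.ones(pos), (self._rows, self._cols)),
                            shape=(N, N))
        csc = coo.tocsc()
        self._csc_template = csc
        # map from our entry order into the CSC data layout
        perm = sp.coo_matrix((np.arange(pos) + 1.0,
                              (self._rows, self._cols)), shape=(N, N)).tocsc()
        self._perm = (perm.data - 1.0).astype(np.int64)

    def set(self, name, values):
        """Assign coefficients for one stencil leg.

        ``values`` must have the natural shape of that leg: (m, n) for
        the diagonal, (m-1, n) for E/W, (m, n-1) for N/S.
        """
        pos, length, _ = self.slots[name]
        v = np.ravel(values)
        assert v.size == length
        self._data[pos:pos + length] = v

    def matrix(self) -> sp.csc_matrix:
        csc = self._csc_template.copy()
        csc.data = self._data[self._perm]
        return csc


def _corner_avg(c):
    """Average a cell field (nx, nz) to interior corners (nx-1, nz-1)."""
    return 0.25 * (c[:-1, :-1] + c[1:, :-1] + c[:-1, 1:] + c[1:, 1:])


def _harmonic2(a, b):
    return 2.0 / (1.0 / a + 1.0 / b)


def _harmonic4(c):
    """Harmonic mean of a cell field at interior corners."""
    return 4.0 / (1.0 / c[:-1, :-1] + 1.0 / c[1:, :-1]
                  + 1.0 / c[:-1, 1:] + 1.0 / c[1:, 1:])


class FlowSolver:
    """Marrow/air VOF solver bound to one domain + rheology + config."""

    def __init__(self, domain, rheo: MarrowRheology, config: FlowConfig):
        self.domain = domain
        self.rheo = rheo
        self.config = config
        d = domain
        self.fluid = d.cell_type == FLUID
        if not self.fluid.any():
            raise ValueError("domain has no fluid cells")
        fx, fz = d.fx, d.fz
        self.open_fx = np.zeros(fx.shape, bool)
        self.open_fx[1:-1, :] = (fx[1:-1, :] == 0) & self.fluid[:-1, :] \
            & self.fluid[1:, :]
        self.open_fz = np.zeros(fz.shape, bool)
        self.open_fz[:, 1:-1] = (fz[:, 1:-1] == 0) & self.fluid[:, :-1] \
            & self.fluid[:, 1:]
        self.inlet_fx = (fx == FACE_INLET_SIDE) | (fx == FACE_INLET_BOTTOM)
        self.inlet_fz = (fz == FACE_INLET_SIDE) | (fz == FACE_INLET_BOTTOM)
        self.outlet_fx = fx == FACE_OUTLET
        self.outlet_fz = fz == FACE_OUTLET
        n_inlet = int(self.inlet_fx.sum() + self.inlet_fz.sum())
        n_outlet = int(self.outlet_fx.sum() + self.outlet_fz.sum())
        if n_inlet > 0 and n_outlet == 0:
            raise ValueError("sealed domain: inlet faces present but no "
                             "outlet (air has no vent)")
        self.closed = n_outlet == 0
        # inward sign of prescribed inlet velocity: fluid side decides
        self.sign_fx = np.zeros(fx.shape)
        fl = np.zeros(fx.shape, bool)
        fl[:-1, :] = self.fluid
        fr = np.zeros(fx.shape, bool)
        fr[1:, :] = self.fluid
        self.sign_fx[self.inlet_fx & fl] = 1.0   # fluid on +x side
        self.sign_fx[self.inlet_fx & fr & ~fl] = -1.0
        self.sign_fz = np.zeros(fz.shape)
        fb = np.zeros(fz.shape, bool)
        fb[:, :-1] = self.fluid
        ft = np.zeros(fz.shape, bool)
        ft[:, 1:] = self.fluid
        self.sign_fz[self.inlet_fz & fb] = 1.0
        self.sign_fz[self.inlet_fz & ft & ~fb] = -1.0
        # outlet orientation: +1 if the fluid cell sits below/left
        self.out_sign_fz = np.where(fb, 1.0, -1.0) * self.outlet_fz
        self.out_sign_fx = np.where(fl, 1.0, -1.0) * self.outlet_fx
        nx, nz = d.nx, d.nz
        self._sten_p = _Stencil5(nx, nz)
        self._lu_p = None
        self._beta_cache = None
        self._phi_prev = None
        self._pin = None
        # columns of u faces lying under a top outlet (free-slip ghost)
        self._u_top_free = np.zeros(nx + 1, bool)
        topout = self.outlet_fz[:, -1]
        self._u_top_free[:-1] |= topout
        self._u_top_free[1:] |= topout
        self.lid = getattr(d, "lid", None)
        self.lid_speed = getattr(d, "lid_speed", 0.0)

    # -- setup -------------------------------------------------------------

    def initialize_state(self, alpha0: float = 0.0) -> FlowState:
        """Air-filled quiescent state at t = 0 (alpha0 overrides)."""
        d = self.domain
        alpha = np.where(self.fluid, float(alpha0), 0.0)
        st = FlowState(u=np.zeros((d.nx + 1, d.nz)),
                       w=np.zeros((d.nx, d.nz + 1)),
                       p=np.zeros((d.nx, d.nz)), alpha=alpha, solver=self)
        return st

    # -- property fields ---------------------------------------------------

    def mixture(self, state: FlowState):
        """Cell-centred mixture density and viscosity.

        Solid/exterior cells inherit the mean of their fluid neighbours
        (they only enter through wall-tangential couplings), so wall
        friction sees the adjacent fluid's viscosity.
        """
        cfg, rh = self.config, self.rheo
        a = state.alpha
        rho = a * rh.rho + (1.0 - a) * cfg.air_density
        gd = self.shear_rate_field(state)
        eta_m = apparent_viscosity(rh, gd)
        mu = a * eta_m + (1.0 - a) * cfg.air_viscosity
        rho = self._fill_solid(rho)
        mu = self._fill_solid(mu)
        return rho, mu

    def _fill_solid(self, field):
        """Replace non-fluid cells by their fluid-neighbour mean."""
        fluid = self.fluid
        if fluid.all():
            return field
        vals = np.where(fluid, field, 0.0)
        w = fluid.astype(float)
        num = np.zeros_like(vals)
        den = np.zeros_like(vals)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            num += np.roll(vals, shift, axis=axis)
            den += np.roll(w, shift, axis=axis)
        # np.roll wraps around; wrapped contributions only matter on the
        # outermost ring, which is exterior in every domain we build
        filled = np.where(den > 0, num / np.maximum(den, 1.0),
                          float(field[fluid].mean()))
        return np.where(fluid, field, filled)

    def shear_rate_field(self, state: FlowState) -> np.ndarray:
        """Cell-centred gamma_dot = sqrt(2 S:S); zero outside fluid."""
        d = self.domain
        uc = 0.5 * (state.u[1:, :] + state.u[:-1, :])
        wc = 0.5 * (state.w[:, 1:] + state.w[:, :-1])
        ux = (state.u[1:, :] - state.u[:-1, :]) / d.dx
        wz = (state.w[:, 1:] - state.w[:, :-1]) / d.dz
        uz = np.gradient(uc, d.dz, axis=1)
        wx = np.gradient(wc, d.dx, axis=0)
        gd = np.sqrt(2.0 * (ux**2 + wz**2) + (uz + wx)**2)
        return np.where(self.fluid, gd, 0.0)

    def marrow_volume(self, state: FlowState) -> float:
        """Marrow volume (m^3 at unit section depth)."""
        d = self.domain
        return float(np.sum(state.alpha[self.fluid]) * d.dx * d.dz)

    def void_volume(self) -> float:
        return float(self.fluid.sum() * self.domain.dx * self.domain.dz)

    def injecting(self, t: float) -> bool:
        cfg = self.config
        return t < cfg.fill_duration or cfg.post_fill_inflow

    # -- boundary values ---------------------------------------------------

    def _apply_velocity_bcs(self, u, w, t):
        speed = self.config.inlet_speed if self.injecting(t) else 0.0
        u[~self.open_fx & ~self.outlet_fx] = 0.0
        w[~self.open_fz & ~self.outlet_fz] = 0.0
        u[self.inlet_fx] = speed * self.sign_fx[self.inlet_fx]
        w[self.inlet_fz] = speed * self.sign_fz[self.inlet_fz]

    # -- time step ---------------------------------------------------------

    def suggest_dt(self, state: FlowState) -> float:
        cfg = self.config
        if cfg.dt is not None:
            return cfg.dt
        d = self.domain
        vmax_u = float(np.max(np.abs(state.u))) + 1e-12
        vmax_w = float(np.max(np.abs(state.w))) + 1e-12
        dt = cfg.cfl_limit * min(d.dx / vmax_u, d.dz / vmax_w)
        return min(dt, cfg.dt_max)

    def step(self, state: FlowState, dt: float | None = None) -> FlowState:
        cfg = self.config
        d = self.domain
        dt = float(dt if dt is not None else self.suggest_dt(state))
        t = state.time
        u = state.u.copy()
        w = state.w.copy()
        self._apply_velocity_bcs(u, w, t)
        rho, mu = self.mixture(state)
        state.mu_field = mu

        # explicit advection + gravity
        u_hat = u + dt * (self._advect_u(u, w, rho, mu) + cfg.gravity[0])
        w_hat = w + dt * (self._advect_w(u, w, rho, mu) + cfg.gravity[1])
        self._apply_bc_to(u_hat, w_hat, t)

        # diffusion, subcycled to its explicit stability limit
        u_star, w_star = self._diffuse(u_hat, w_hat, rho, mu, dt)
        self._apply_bc_to(u_star, w_star, t)

        # projection
        u_new, w_new, phi = self._project(u_star, w_star, rho, dt, t)
        self._apply_bc_to(u_new, w_new, t)
        div = self._divergence(u_new, w_new)
        maxdiv = float(np.max(np.abs(div[self.fluid]))) if self.fluid.any() else 0.0
        if maxdiv > cfg.divergence_tol:
            raise RuntimeError(f"projection failed: max divergence {maxdiv:.3e} "
                               f"exceeds tolerance {cfg.divergence_tol:.3e}")

        # VOF transport
        alpha, din, dout, clipped = self._advect_alpha(state.alpha, u_new,
                                                       w_new, dt, t)
        state.u, state.w = u_new, w_new
        state.p = phi
        state.alpha = alpha
        state.time = t + dt
        state.influx += din
        state.outflux += dout
        state.clip_residual += clipped
        state.max_divergence = maxdiv
        return state

    def _apply_bc_to(self, u, w, t):
        self._apply_velocity_bcs(u, w, t)

    # -- advection ---------------------------------------------------------

    def _hybrid(self, q, vel, h, nu, axis):
        """vel * dq/dx_axis, central blended toward upwind at Pe > 2."""
        qp = np.roll(q, -1, axis=axis)
        qm = np.roll(q, 1, axis=axis)
        # non-periodic edges: zero-gradient
        sl_lo = [slice(None)] * q.ndim
        sl_lo[axis] = 0
        sl_hi = [slice(None)] * q.ndim
        sl_hi[axis] = -1
        qm[tuple(sl_lo)] = q[tuple(sl_lo)]
        qp[tuple(sl_hi)] = q[tuple(sl_hi)]
        central = (qp - qm) / (2 * h)
        up = np.where(vel > 0, (q - qm) / h, (qp - q) / h)
        pe = np.abs(vel) * h / np.maximum(nu, 1e-12)
        theta = np.clip(2.0 / np.maximum(pe, 1e-12), 0.0, 1.0)
        return -vel * (theta * central + (1 - theta) * up)

    def _advect_u(self, u, w, rho, mu):
        d = self.domain
        # kinematic viscosity at u faces (cell average)
        nu_c = mu / rho
        nu_f = np.empty_like(u)
        nu_f[1:-1, :] = 0.5 * (nu_c[:-1, :] + nu_c[1:, :])
        nu_f[0, :] = nu_c[0, :]
        nu_f[-1, :] = nu_c[-1, :]
        w_at_u = np.zeros_like(u)
        wavg = 0.5 * (w[:, :-1] + w[:, 1:])       # (nx, nz) at centres
        w_at_u[1:-1, :] = 0.5 * (wavg[:-1, :] + wavg[1:, :])
        return (self._hybrid(u, u, d.dx, nu_f, 0)
                + self._hybrid(u, w_at_u, d.dz, nu_f, 1))

    def _advect_w(self, u, w, rho, mu):
        d = self.domain
        nu_c = mu / rho
        nu_f = np.empty_like(w)
        nu_f[:, 1:-1] = 0.5 * (nu_c[:, :-1] + nu_c[:, 1:])
        nu_f[:, 0] = nu_c[:, 0]
        nu_f[:, -1] = nu_c[:, -1]
        u_at_w = np.zeros_like(w)
        uavg = 0.5 * (u[:-1, :] + u[1:, :])
        u_at_w[:, 1:-1] = 0.5 * (uavg[:, :-1] + uavg[:, 1:])
        return (self._hybrid(w, u_at_w, d.dx, nu_f, 0)
                + self._hybrid(w, w, d.dz, nu_f, 1))

    # -- diffusion (explicit, subcycled to its stability limit) ------------
    #
    # Viscosity at faces/corners uses harmonic averaging: at marrow/air
    # interfaces it keeps the effective diffusivity bounded by the less
    # viscous side, which both matches the physics of a viscosity jump
    # and keeps the explicit substep count moderate.

    def _diffuse(self, u_hat, w_hat, rho, mu, dt):
        d = self.domain
        nx, nz = d.nx, d.nz
        dx2, dz2 = d.dx**2, d.dz**2

        rho_fu = np.empty((nx + 1, nz))
        rho_fu[1:-1, :] = 0.5 * (rho[:-1, :] + rho[1:, :])
        rho_fu[0, :], rho_fu[-1, :] = rho[0, :], rho[-1, :]
        rho_fw = np.empty((nx, nz + 1))
        rho_fw[:, 1:-1] = 0.5 * (rho[:, :-1] + rho[:, 1:])
        rho_fw[:, 0], rho_fw[:, -1] = rho[:, 0], rho[:, -1]

        mu_c = _harmonic4(mu)                       # (nx-1, nz-1) corners
        # u: vertical coupling coefficients at corner levels, incl. edges
        muz_u = np.empty((nx + 1, nz - 1)) if nz > 1 else np.zeros((nx + 1, 0))
        if nz > 1:
            muz_u[1:-1, :] = mu_c
            muz_u[0, :] = _harmonic2(mu[0, :-1], mu[0, 1:])
            muz_u[-1, :] = _harmonic2(mu[-1, :-1], mu[-1, 1:])
        mu_bot_u = np.empty(nx + 1)
        mu_bot_u[1:-1] = _harmonic2(mu[:-1, 0], mu[1:, 0])
        mu_bot_u[0], mu_bot_u[-1] = mu[0, 0], mu[-1, 0]
        mu_top_u = np.empty(nx + 1)
        mu_top_u[1:-1] = _harmonic2(mu[:-1, -1], mu[1:, -1])
        mu_top_u[0], mu_top_u[-1] = mu[0, -1], mu[-1, -1]
        # w: horizontal coupling coefficients at corner levels, incl. edges
        mux_w = np.empty((nx - 1, nz + 1)) if nx > 1 else np.zeros((0, nz + 1))
        if nx > 1:
            mux_w[:, 1:-1] = mu_c
            mux_w[:, 0] = _harmonic2(mu[:-1, 0], mu[1:, 0])
            mux_w[:, -1] = _harmonic2(mu[:-1, -1], mu[1:, -1])
        mu_l_w = np.empty(nz + 1)
        mu_l_w[1:-1] = _harmonic2(mu[0, :-1], mu[0, 1:])
        mu_l_w[0], mu_l_w[-1] = mu[0, 0], mu[0, -1]
        mu_r_w = np.empty(nz + 1)
        mu_r_w[1:-1] = _harmonic2(mu[-1, :-1], mu[-1, 1:])
        mu_r_w[0], mu_r_w[-1] = mu[-1, 0], mu[-1, -1]

        # Gershgorin bound on the explicit update for the substep count
        row_u = np.zeros((nx + 1, nz))
        row_u[1:, :] += mu / dx2
        row_u[:-1, :] += mu / dx2
        if nz > 1:
            row_u[:, 1:] += muz_u / dz2
            row_u[:, :-1] += muz_u / dz2
        row_u[:, 0] += 2 * mu_bot_u / dz2
        row_u[:, -1] += 2 * mu_top_u / dz2
        row_w = np.zeros((nx, nz + 1))
        row_w[:, 1:] += mu / dz2
        row_w[:, :-1] += mu / dz2
        if nx > 1:
            row_w[1:, :] += mux_w / dx2
            row_w[:-1, :] += mux_w / dx2
        row_w[0, :] += 2 * mu_l_w / dx2
        row_w[-1, :] += 2 * mu_r_w / dx2
        lam = max(float(np.max(row_u / rho_fu)),
                  float(np.max(row_w / rho_fw)), 1e-300)
        n_sub = max(1, int(np.ceil(dt * lam / 0.9)))
        h = dt / n_sub

        u = u_hat.copy()
        w = w_hat.copy()
        mask_u = self.open_fx | self.outlet_fx
        mask_w = self.open_fz | self.outlet_fz
        for _ in range(n_sub):
            du = self._diff_rate_u(u, mu, muz_u, mu_bot_u, mu_top_u, rho_fu)
            dw = self._diff_rate_w(w, mu, mux_w, mu_l_w, mu_r_w, rho_fw)
            u[mask_u] += h * du[mask_u]
            w[mask_w] += h * dw[mask_w]
        return u, w

    def _diff_rate_u(self, u, mu, muz_u, mu_bot, mu_top, rho_f):
        """(1/rho) div(mu grad u) at x-faces, half-cell wall ghosts."""
        d = self.domain
        nx, nz = d.nx, d.nz
        Fx = np.zeros((nx + 2, nz))
        Fx[1:-1, :] = mu * (u[1:, :] - u[:-1, :]) / d.dx
        Fz = np.zeros((nx + 1, nz + 1))
        if nz > 1:
            Fz[:, 1:-1] = muz_u * (u[:, 1:] - u[:, :-1]) / d.dz
        # bottom wall at z = 0: ghost = -u half a cell below
        Fz[:, 0] = mu_bot * 2.0 * u[:, 0] / d.dz
        # top: lid ghost 2U - u, outlet columns free slip, else no-slip
        if self.lid == "top":
            Fz[:, -1] = mu_top * 2.0 * (self.lid_speed - u[:, -1]) / d.dz
        else:
            Fz[:, -1] = np.where(self._u_top_free, 0.0,
                                 -mu_top * 2.0 * u[:, -1] / d.dz)
        return ((Fx[1:, :] - Fx[:-1, :]) / d.dx
                + (Fz[:, 1:] - Fz[:, :-1]) / d.dz) / rho_f

    def _diff_rate_w(self, w, mu, mux_w, mu_l, mu_r, rho_f):
        """(1/rho) div(mu grad w) at z-faces, half-cell wall ghosts."""
        d = self.domain
        nx, nz = d.nx, d.nz
        Fz = np.zeros((nx, nz + 2))
        Fz[:, 1:-1] = mu * (w[:, 1:] - w[:, :-1]) / d.dz
        Fx = np.zeros((nx + 1, nz + 1))
        if nx > 1:
            Fx[1:-1, :] = mux_w * (w[1:, :] - w[:-1, :]) / d.dx
        # side walls at the x extents: ghost = -w half a cell outside
        Fx[0, :] = mu_l * 2.0 * w[0, :] / d.dx
        Fx[-1, :] = -mu_r * 2.0 * w[-1, :] / d.dx
        return ((Fx[1:, :] - Fx[:-1, :]) / d.dx
                + (Fz[:, 1:] - Fz[:, :-1]) / d.dz) / rho_f

    # -- projection --------------------------------------------------------

    def _divergence(self, u, w):
        d = self.domain
        return ((u[1:, :] - u[:-1, :]) / d.dx
                + (w[:, 1:] - w[:, :-1]) / d.dz)

    def _face_betas(self, rho):
        """1/rho on open faces, 0 on closed, inside-cell on outlets."""
        d = self.domain
        nx, nz = d.nx, d.nz
        bx = np.zeros((nx + 1, nz))
        bx[1:-1, :] = 2.0 / (rho[:-1, :] + rho[1:, :])
        bx *= self.open_fx
        bz = np.zeros((nx, nz + 1))
        bz[:, 1:-1] = 2.0 / (rho[:, :-1] + rho[:, 1:])
        bz *= self.open_fz
        # outlet faces: beta of the interior cell (only top fz occurs)
        bz_out = np.zeros((nx, nz + 1))
        bz_out[:, -1] = 1.0 / rho[:, -1]
        bz_out[:, 0] = 1.0 / rho[:, 0]
        if nz > 1:
            bz_out[:, 1:-1] = 1.0 / (0.5 * (rho[:, :-1] + rho[:, 1:]))
        bz_out *= self.outlet_fz
        return bx, bz, bz_out

    def _apply_S(self, phi, bx, bz, bz_out):
        """Matrix-free action of the SPD (negated) pressure operator."""
        d = self.domain
        out = np.zeros_like(phi)
        fx = bx[1:-1, :] * (phi[1:, :] - phi[:-1, :]) / d.dx**2
        out[:-1, :] -= fx
        out[1:, :] += fx
        fz = bz[:, 1:-1] * (phi[:, 1:] - phi[:, :-1]) / d.dz**2
        out[:, :-1] -= fz
        out[:, 1:] += fz
        out += 2.0 * (bz_out[:, 1:] + bz_out[:, :-1]) / d.dz**2 * phi
        out[~self.fluid] = phi[~self.fluid]
        if self.closed:
            out[self._pin] = phi[self._pin]
        return out

    def _build_pressure_lu(self, bx, bz, bz_out):
        """Factorize the SPD pressure operator (also the preconditioner)."""
        d = self.domain
        nx, nz = d.nx, d.nz
        st = self._sten_p
        aE = bx[1:-1, :] / d.dx**2       # face between cell i and i+1
        aN = bz[:, 1:-1] / d.dz**2
        diag = np.zeros((nx, nz))
        diag[:-1, :] += aE
        diag[1:, :] += aE
        diag[:, :-1] += aN
        diag[:, 1:] += aN
        diag += 2.0 * (bz_out[:, 1:] + bz_out[:, :-1]) / d.dz**2
        diag[~self.fluid] = 1.0
        vE = -np.array(aE)
        vW = -np.array(aE)
        vN = -np.array(aN)
        vS = -np.array(aN)
        if self.closed:
            # Neumann system is singular; with a mean-free RHS it is
            # consistent, so pinning one cell to phi = 0 still solves
            # every remaining (dependent) equation exactly.
            pi, pk = self._pin
            diag[pi, pk] = 1.0
            if pi < nx - 1:
                vE[pi, pk] = 0.0
            if pi >= 1:
                vW[pi - 1, pk] = 0.0
            if pk < nz - 1:
                vN[pi, pk] = 0.0
            if pk >= 1:
                vS[pi, pk - 1] = 0.0
        st.set("C", diag)
        st.set("E", vE)
        st.set("W", vW)
        st.set("N", vN)
        st.set("S", vS)
        self._lu_p = spla.splu(st.matrix())

    def _pcg(self, b, x0, bx, bz, bz_out, tol, maxiter=200):
        """Preconditioned CG on the SPD operator; inf-norm stopping."""
        lu = self._lu_p
        shape = b.shape
        x = x0.copy()
        x[~self.fluid] = 0.0
        r = b - self._apply_S(x, bx, bz, bz_out)
        if float(np.max(np.abs(r))) <= tol:
            return x, 0
        z = lu.solve(r.ravel()).reshape(shape)
        p = z.copy()
        rz = float(np.sum(r * z))
        for i in range(1, maxiter + 1):
            q = self._apply_S(p, bx, bz, bz_out)
            pq = float(np.sum(p * q))
            if pq == 0.0:
                break
            a = rz / pq
            x += a * p
            r -= a * q
            if float(np.max(np.abs(r))) <= tol:
                return x, i
            z = lu.solve(r.ravel()).reshape(shape)
            rz_new = float(np.sum(r * z))
            p = z + (rz_new / rz) * p
            rz = rz_new
        return x, maxiter + 1

    def _project(self, u_star, w_star, rho, dt, t):
        """Variable-density pressure projection.

        Open domains use matrix-free preconditioned CG with a direct LU
        kept from an earlier step as preconditioner, refreshed whenever
        convergence degrades; closed (single-phase benchmark) domains
        solve directly with a cached factorization.  The iteration stops
        once the post-correction divergence bound dt * ||residual||_inf
        is below half the divergence tolerance.
        """
        d = self.domain
        nx, nz = d.nx, d.nz
        bx, bz, bz_out = self._face_betas(rho)
        if self.closed and self._pin is None:
            self._pin = tuple(np.unravel_index(np.argmax(self.fluid),
                                               self.fluid.shape))
        rhs = self._divergence(u_star, w_star) / dt
        rhs[~self.fluid] = 0.0
        if self.closed:
            rhs[self.fluid] -= rhs[self.fluid].mean()
            rhs[self._pin] = 0.0
        b = -rhs
        if self.closed:
            scale = max(float(bx.max()), float(bz.max()), 1e-300)
            stale = (self._beta_cache is None
                     or np.max(np.abs(bx - self._beta_cache[0])) > 1e-9 * scale
                     or np.max(np.abs(bz - self._beta_cache[1])) > 1e-9 * scale)
            if self._lu_p is None or stale:
                self._build_pressure_lu(bx, bz, bz_out)
                self._beta_cache = (bx.copy(), bz.copy())
            phi = self._lu_p.solve(b.ravel()).reshape(nx, nz)
        else:
            if self._lu_p is None:
                self._build_pressure_lu(bx, bz, bz_out)
            tol = 0.5 * self.config.divergence_tol / dt
            x0 = (self._phi_prev if self._phi_prev is not None
                  else np.zeros_like(b))
            phi, iters = self._pcg(b, x0, bx, bz, bz_out, tol)
            if iters > 8:
                # preconditioner has drifted too far from the current
                # density field; refresh it for the coming steps
                self._build_pressure_lu(bx, bz, bz_out)
                if iters > 50:
                    phi, _ = self._pcg(b, phi, bx, bz, bz_out, tol)
            self._phi_prev = phi
        u = u_star.copy()
        w = w_star.copy()
        u[1:-1, :] -= dt * bx[1:-1, :] * (phi[1:, :] - phi[:-1, :]) / d.dx
        w[:, 1:-1] -= dt * bz[:, 1:-1] * (phi[:, 1:] - phi[:, :-1]) / d.dz
        # outlet faces: Dirichlet phi = 0 at the face (half-cell gradient)
        out_top = self.outlet_fz[:, -1]
        w[out_top, -1] = w_star[out_top, -1] \
            + 2 * dt * bz_out[out_top, -1] * phi[out_top, -1] / d.dz
        out_bot = self.outlet_fz[:, 0]
        w[out_bot, 0] = w_star[out_bot, 0] \
            - 2 * dt * bz_out[out_bot, 0] * phi[out_bot, 0] / d.dz
        return u, w, phi

    # -- VOF ---------------------------------------------------------------

    def _advect_alpha(self, alpha, u, w, dt, t):
        d = self.domain
        nx, nz = d.nx, d.nz
        injecting = self.injecting(t)
        Fx = np.zeros((nx + 1, nz))
        up = np.where(u[1:-1, :] > 0, alpha[:-1, :], alpha[1:, :])
        Fx[1:-1, :] = u[1:-1, :] * up * self.open_fx[1:-1, :]
        Fz = np.zeros((nx, nz + 1))
        upz = np.where(w[:, 1:-1] > 0, alpha[:, :-1], alpha[:, 1:])
        Fz[:, 1:-1] = w[:, 1:-1] * upz * self.open_fz[:, 1:-1]
        din = dout = 0.0
        if injecting:
            # inlet faces carry pure marrow at the prescribed speed
            Fx[self.inlet_fx] = u[self.inlet_fx]
            Fz[self.inlet_fz] = w[self.inlet_fz]
            din = dt * d.dz * float(np.sum(np.abs(u[self.inlet_fx]))) \
                + dt * d.dx * float(np.sum(np.abs(w[self.inlet_fz])))
        # outlet faces: donor value from the interior cell on outflow
        out_top = self.outlet_fz[:, -1]
        if out_top.any():
            wf = w[out_top, -1]
            a_in = alpha[out_top, -1]
            Fz[out_top, -1] = np.where(wf > 0, wf * a_in, 0.0)
            dout += dt * d.dx * float(np.sum(np.maximum(wf, 0.0) * a_in))
        out_bot = self.outlet_fz[:, 0]
        if out_bot.any():
            wf = w[out_bot, 0]
            a_in = alpha[out_bot, 0]
            Fz[out_bot, 0] = np.where(wf < 0, wf * a_in, 0.0)
            dout += dt * d.dx * float(np.sum(np.maximum(-wf, 0.0) * a_in))
        new = alpha + dt * ((Fx[:-1, :] - Fx[1:, :]) / d.dx
                            + (Fz[:, :-1] - Fz[:, 1:]) / d.dz)
        new[~self.fluid] = 0.0
        clipped = float(np.sum(np.abs(new - np.clip(new, 0.0, 1.0)))
                        * d.dx * d.dz)
        return np.clip(new, 0.0, 1.0), din, dout, clipped

    # -- audit -------------------------------------------------------------

    def conservation_error(self, state: FlowState) -> float:
        """|volume - net integrated flux| / max(volume, void volume)."""
        vol = self.marrow_volume(state)
        net = state.influx - state.outflux
        ref = max(vol, 1e-300)
        return abs(vol - net) / ref


# ---------------------------------------------------------------------------
# module-level wrappers mirroring the operation-style API
# ---------------------------------------------------------------------------

def initialize_state(domain, config: FlowConfig,
                     rheo: MarrowRheology | None = None) -> FlowState:
    """Build a solver for ``domain`` and return its initial state."""
    solver = FlowSolver(domain, rheo or MarrowRheology(), config)
    return solver.initialize_state()


def step(state: FlowState, domain=None, rheo=None, config=None,
         dt=None) -> FlowState:
    """Advance one time step using the solver bound to ``state``."""
    if state.solver is None:
        state.solver = FlowSolver(domain, rheo or MarrowRheology(),
                                  config or FlowConfig())
    return state.solver.step(state, dt=dt)


def shear_rate_field(state: FlowState, domain=None) -> np.ndarray:
    return state.solver.shear_rate_field(state)


def marrow_volume(state: FlowState, domain=None) -> float:
    return state.solver.marrow_volume(state)
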