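"""Lagrangian cell transport: injection, drag, impingement detection."""

import numpy as np
import pytest

from osteoseed.flow import FlowConfig, FlowSolver
from osteoseed.geometry import build_section_domain
from osteoseed.rheology import MarrowRheology
from osteoseed.synthetic import make_flow_fixture
from osteoseed.transport import (CellPhase, InjectionSchedule, advance,
                                 detect_impingement, fluid_velocity_at,
                                 inject)


def _march_schedule(schedule, domain, dts, rng):
    cells = CellPhase()
    t, injected = 0.0, 0
    for dt in dts:
        injected += inject(schedule, domain, cells, t, dt, rng,
                           injected_so_far=injected)
        t += dt
    return cells, injected, t


class TestInjection:
    def test_window_delivers_exact_count(self, coarse_section, rng):
        sched = InjectionSchedule(n_cells=4817, window=(0.0, 2.5),
                                  post_fill_mode="no_injection")
        dts = rng.uniform(2e-4, 2e-3, size=4000)
        dts = dts[np.cumsum(dts) <= 2.6]
        cells, injected, t = _march_schedule(sched, coarse_section, dts, rng)
        assert t > 2.5
        assert injected == 4817 and cells.n == 4817

    def test_no_injection_after_window(self, coarse_section, rng):
        sched = InjectionSchedule(n_cells=100, window=(0.0, 0.5),
                                  post_fill_mode="no_injection")
        cells = CellPhase()
        n = inject(sched, coarse_section, cells, 0.7, 1e-3, rng,
                   injected_so_far=100)
        assert n == 0

    def test_continued_mode_keeps_the_rate(self, coarse_section, rng):
        sched = InjectionSchedule(n_cells=1000, window=(0.0, 1.0),
                                  post_fill_mode="continued_injection")
        assert sched.cumulative(1.0) == 1000
        assert sched.cumulative(2.0) == 2000

    def test_same_seed_reproduces_positions(self, coarse_section):
        sched = InjectionSchedule(n_cells=500, window=(0.0, 1.0))
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            cells = CellPhase()
            inject(sched, coarse_section, cells, 0.0, 0.5, rng,
                   injected_so_far=0)
            out.append(cells.pos[:cells.n].copy())
        assert np.array_equal(out[0], out[1])

    def test_cells_start_inside_the_fluid(self, coarse_section, rng):
        sched = InjectionSchedule(n_cells=2000, window=(0.0, 1.0))
        cells = CellPhase()
        inject(sched, coarse_section, cells, 0.0, 1.0, rng, injected_so_far=0)
        geo = coarse_section.geometry
        p = cells.pos[:cells.n]
        assert np.all(geo.in_defect(p[:, 0], p[:, 1]))


class TestAdvance:
    def test_neutral_buoyancy_in_still_fluid_is_stationary(self):
        dom, state, _ = make_flow_fixture("settling_column")
        cells = CellPhase(density=1050.0)   # matches the marrow density
        cells.add([[5e-4, 7e-4]], [[0.0, 0.0]])
        p0 = cells.pos[0].copy()
        for _ in range(50):
            advance(cells, state, dom, MarrowRheology(), 1e-4)
        assert np.allclose(cells.pos[0], p0, atol=1e-12)

    def test_stokes_relaxation_matches_closed_form(self):
        # tau = rho_p d^2 / (18 mu); pick parameters with Re_p ~ 1e-4 so
        # the Schiller-Naumann correction is negligible
        mu = 0.001
        rheo = MarrowRheology(k=mu, n=1.0, eta_min=mu / 10, eta_max=mu,
                              rho=1050.0)
        U = 1e-5
        dom, state, _ = make_flow_fixture("uniform", speed=U, rheo=rheo)
        cells = CellPhase(diameter=25e-6, density=1000.0)
        cells.add([[5e-4, 7e-4]], [[0.0, 0.0]])
        tau = 1000.0 * (25e-6) ** 2 / (18 * mu)
        dt = tau / 100.0
        t = 0.0
        for _ in range(150):
            advance(cells, state, dom, rheo, dt, gravity=(0, 0))
            t += dt
        expected = U * (1.0 - np.exp(-t / tau))
        assert cells.vel[0, 0] == pytest.approx(expected, rel=0.01)

    def test_terminal_settling_speed_matches_stokes(self):
        mu = 0.001
        rheo = MarrowRheology(k=mu, n=1.0, eta_min=mu / 10, eta_max=mu,
                              rho=1050.0)
        dom, state, _ = make_flow_fixture("settling_column", rheo=rheo)
        d, rho_p, rho_f, g = 25e-6, 1100.0, 1050.0, 9.81
        cells = CellPhase(diameter=d, density=rho_p)
        cells.add([[5e-4, 1.4e-3]], [[0.0, 0.0]])
        tau = rho_p * d * d / (18 * mu)
        for _ in range(400):
            advance(cells, state, dom, rheo, tau / 20, gravity=(0.0, -g))
        v_term = (rho_p - rho_f) * g * d * d / (18 * mu)
        assert -cells.vel[0, 1] == pytest.approx(v_term, rel=0.01)

    def test_bilinear_sampling_is_exact_for_linear_fields(self):
        G = 10.0
        dom, state, _ = make_flow_fixture("linear_shear", shear=G)
        pts = np.array([[3.1e-4, 4.2e-4], [7.7e-4, 1.1e-3]])
        uf = fluid_velocity_at(state, dom, pts)
        assert np.allclose(uf[:, 0], G * pts[:, 1], rtol=1e-9)

    def test_stuck_cells_do_not_move(self):
        dom, state, _ = make_flow_fixture("uniform", speed=1e-3)
        cells = CellPhase()
        cells.add([[5e-4, 7e-4]], [[0.0, 0.0]])
        cells.status[0] = 1  # stuck
        p0 = cells.pos[0].copy()
        advance(cells, state, dom, MarrowRheology(), 1e-3)
        assert np.array_equal(cells.pos[0], p0)


@pytest.fixture(scope="module")
def section():
    return build_section_domain(nx=32, nz=48)


class TestImpingement:
    def test_parallel_motion_with_clearance_is_no_event(self, section):
        geo = section.geometry
        c = geo.beam_centers[0]
        r = 12.5e-6
        cells = CellPhase()
        # two beam radii away, moving tangentially
        cells.add([[c[0] + 2.5 * geo.beam_radius, c[1]]], [[0.0, 1e-3]])
        events = detect_impingement(cells, section, 1e-3)
        assert len(events) == 0

    def test_head_on_contact_reports_full_speed(self, section):
        geo = section.geometry
        c = geo.beam_centers[0]
        cells = CellPhase()
        x = c[0] + geo.beam_radius + 0.9 * cells.diameter / 2
        cells.add([[x, c[1]]], [[-1e-3, 0.0]])
        events = detect_impingement(cells, section, 1e-3)
        assert len(events) == 1
        assert events.kind[0] == "beam"
        assert events.v_normal[0] == pytest.approx(1e-3)
        assert np.allclose(events.normal[0], (1.0, 0.0))

    def test_randomized_swarm_matches_brute_force_oracle(self, section, rng):
        geo = section.geometry
        n = 400
        cells = CellPhase()
        # scatter cells around the domain, biased near surfaces
        base = rng.uniform([-4e-3, 0.0], [4e-3, geo.depth], size=(n, 2))
        pick = rng.integers(0, len(geo.beam_centers), size=n // 2)
        base[:n // 2] = geo.beam_centers[pick] + rng.normal(
            scale=geo.beam_radius * 0.3, size=(n // 2, 2)) \
            + np.array([geo.beam_radius, 0.0])
        vel = rng.normal(scale=1e-3, size=(n, 2))
        cells.add(base, vel)
        inside = geo.in_defect(base[:, 0], base[:, 1]) \
            & ~geo.in_scaffold(base[:, 0], base[:, 1])
        cells.status[:n][~inside] = 3  # ignore cells placed inside solids
        events = detect_impingement(cells, section, 1e-3)
        r = cells.diameter / 2
        expected = set()
        for i in np.nonzero(inside)[0]:
            p, v = base[i], vel[i]
            best_d, best_n = np.inf, None
            for cb in geo.beam_centers:   # brute-force surface scan
                dd = np.hypot(*(p - cb)) - geo.beam_radius
                if dd < best_d:
                    best_d, best_n = dd, (p - cb) / np.hypot(*(p - cb))
            dw, nw, _ = geo.wall_distance(p[None, :])
            if dw[0] < best_d:
                best_d, best_n = dw[0], nw[0]
            if best_d <= r and (np.dot(v, best_n) < 0 or best_d < r * 0.999):
                expected.add(i)
        assert set(events.index) == expected

    def test_counts_are_conserved_through_a_short_run(self):
        import dataclasses

        from osteoseed.config import SimulationConfig
        from osteoseed.pipeline import run_simulation

        cfg = SimulationConfig(seed=3, nx=24, nz=36)
        cfg.injection = dataclasses.replace(cfg.injection, n_cells=300)
        cfg.flow = dataclasses.replace(cfg.flow, fill_duration=0.3,
                                       total_duration=0.5)
        cfg.sync()
        res = run_simulation(cfg)
        counts = res.counts()
        assert sum(counts.values()) == res.injected
        assert res.injected >= 300

    def test_disabled_adhesion_keeps_cells_suspended_in_the_void(self):
        import dataclasses

        from osteoseed.config import SimulationConfig
        from osteoseed.pipeline import run_simulation

        cfg = SimulationConfig(seed=4, nx=24, nz=36)
        cfg.injection = dataclasses.replace(cfg.injection, n_cells=300)
        cfg.flow = dataclasses.replace(cfg.flow, fill_duration=0.4,
                                       total_duration=0.4)
        cfg.adhesion = dataclasses.replace(cfg.adhesion, enabled=False)
        cfg.sync()
        cfg.adhesion = dataclasses.replace(cfg.adhesion, enabled=False)
        res = run_simulation(cfg)
        counts = res.counts()
        assert counts["stuck"] == 0 and counts["spread"] == 0
        geo = res.domain.geometry
        idx = res.cells.suspended_idx()
        p = res.cells.pos[idx]
        r = res.cells.diameter / 2
        assert np.all(geo.in_defect(p[:, 0], p[:, 1]))
        d_beam, _ = geo.nearest_beam(p)
        assert np.all(d_beam > -r)  # at most surface-grazing overlap

    def test_zero_cells_gives_an_empty_ledger(self):
        import dataclasses

        from osteoseed.config import SimulationConfig
        from osteoseed.pipeline import run_simulation

        cfg = SimulationConfig(seed=1, nx=16, nz=24)
        cfg.injection = dataclasses.replace(cfg.injection, n_cells=0)
        cfg.flow = dataclasses.replace(cfg.flow, fill_duration=0.1,
                                       total_duration=0.15)
        cfg.sync()
        res = run_simulation(cfg)
        assert res.injected == 0
        assert res.ledger.attached_count() == 0
        assert (res.band_table().mass == 0.0).all()
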