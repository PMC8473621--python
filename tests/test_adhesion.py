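"""Impingement regimes, rebound energetics, and the attachment ledger."""

import numpy as np
import pytest

from osteoseed.adhesion import (AdhesionConfig, AttachmentLedger, classify,
                                region_density, resolve, weber_number)
from osteoseed.geometry import DefectSpec, ScaffoldSpec, SectionGeometry
from osteoseed.transport import (STUCK, SUSPENDED, CellPhase,
                                 ImpingementEvents)


def _events(cells, idx, normals, v_n, kinds=None, beam_ids=None):
    n = len(idx)
    return ImpingementEvents(
        index=np.asarray(idx), kind=np.asarray(kinds if kinds is not None
                                               else ["boundary"] * n,
                                               dtype=object),
        beam_id=np.asarray(beam_ids if beam_ids is not None else [-1] * n),
        normal=np.asarray(normals, float), v_normal=np.asarray(v_n, float),
        point=cells.pos[np.asarray(idx)].copy())


class TestWeberNumber:
    def test_zero_speed_gives_zero(self):
        assert weber_number(CellPhase(), 0.0) == 0.0

    def test_default_cell_at_one_mm_per_s(self):
        # rho d v^2 / sigma = 1000 * 25e-6 * 1e-6 / 0.03
        expected = 1000.0 * 25e-6 * (1e-3) ** 2 / 0.03
        assert expected == pytest.approx(8.333e-7, rel=1e-3)
        assert weber_number(CellPhase(), 1e-3) == pytest.approx(expected)

    def test_quadratic_speed_scaling(self):
        cells = CellPhase()
        assert weber_number(cells, 2e-3) == pytest.approx(
            4 * weber_number(cells, 1e-3))

    def test_rejects_nonpositive_surface_tension(self):
        with pytest.raises(ValueError):
            weber_number(CellPhase(surface_tension=0.0), 1.0)


class TestClassify:
    CFG = AdhesionConfig(we_stick_max=5.0, we_spread_min=10.0)

    def test_zero_weber_sticks(self):
        assert classify(0.0, self.CFG) == "stick"

    def test_spread_threshold_is_inclusive(self):
        assert classify(10.0, self.CFG) == "spread"

    def test_stick_threshold_is_inclusive(self):
        assert classify(5.0, self.CFG) == "stick"

    def test_between_thresholds_rebounds(self):
        assert classify(7.0, self.CFG) == "rebound"

    def test_matches_three_way_oracle_on_random_values(self, rng):
        we = rng.uniform(0.0, 20.0, size=500)
        got = classify(we, self.CFG)
        for w, g in zip(we, got):
            if w <= 5.0:
                assert g == "stick"
            elif w < 10.0:
                assert g == "rebound"
            else:
                assert g == "spread"

    def test_huge_surface_tension_always_sticks(self):
        cells = CellPhase(surface_tension=1e9)
        we = weber_number(cells, 10.0)  # violent impact, enormous sigma
        assert classify(we, self.CFG) == "stick"


class TestResolve:
    def test_stick_moves_cell_to_attached(self):
        cells = CellPhase()
        cells.add([[0.0, 0.0]], [[0.0, -1e-3]])
        ev = _events(cells, [0], [[0.0, 1.0]], [1e-3])
        out = resolve(cells, ev, AdhesionConfig(attach_start=0.0), t=1.0)
        assert out["stick"] == 1
        assert cells.status[0] == STUCK
        assert np.all(cells.vel[0] == 0.0)

    def test_elastic_rebound_preserves_speed(self):
        cells = CellPhase(surface_tension=1e-9)  # force the rebound regime
        v = np.array([3e-4, -4e-4])
        cells.add([[0.0, 0.0]], [v])
        ev = _events(cells, [0], [[0.0, 1.0]], [4e-4])
        cfg = AdhesionConfig(we_stick_max=1.0, we_spread_min=10.0,
                             restitution=1.0, attach_start=0.0)
        assert classify(weber_number(cells, ev.v_normal[0]), cfg) == "rebound"
        out = resolve(cells, ev, cfg, t=1.0)
        assert out["rebound"] == 1 and cells.status[0] == SUSPENDED
        assert np.linalg.norm(cells.vel[0]) == pytest.approx(
            np.linalg.norm(v))
        assert np.allclose(cells.vel[0], [3e-4, 4e-4])  # specular flip

    def test_scaffold_contact_before_attach_start_rebounds(self):
        cells = CellPhase()
        v = np.array([-1e-3, 0.0])
        cells.add([[0.0, 0.0]], [v])
        ev = _events(cells, [0], [[1.0, 0.0]], [1e-3], kinds=["beam"],
                     beam_ids=[0])
        out = resolve(cells, ev, AdhesionConfig(attach_start=2.5), t=1.0)
        assert out["rebound"] == 1
        assert cells.status[0] == SUSPENDED
        # elastic specular reflection
        assert np.allclose(cells.vel[0], [1e-3, 0.0])

    def test_outlet_contact_escapes(self):
        cells = CellPhase()
        cells.add([[0.0, 0.0]], [[0.0, 1e-3]])
        ev = _events(cells, [0], [[0.0, -1.0]], [1e-3], kinds=["outlet"])
        out = resolve(cells, ev, AdhesionConfig(), t=1.0)
        assert out["escaped"] == 1

    def test_rebound_energy_non_increasing(self, rng):
        cfg = AdhesionConfig(restitution=0.8, attach_start=10.0)
        for _ in range(50):
            cells = CellPhase()
            v = rng.normal(scale=1e-3, size=2)
            n = rng.normal(size=2)
            n /= np.linalg.norm(n)
            if np.dot(v, n) > 0:
                v = -v
            cells.add([[0.0, 0.0]], [v])
            ev = _events(cells, [0], [n], [max(-np.dot(v, n), 0.0)],
                         kinds=["beam"], beam_ids=[0])
            resolve(cells, ev, cfg, t=0.0)
            assert np.linalg.norm(cells.vel[0]) <= np.linalg.norm(v) + 1e-15


@pytest.fixture(scope="module")
def geometry():
    return SectionGeometry(ScaffoldSpec(), DefectSpec())


class TestRegionDensity:
    def test_empty_ledger_gives_zero_everywhere(self, geometry):
        table = region_density(AttachmentLedger(), geometry, "radial")
        assert (table.mass == 0.0).all()
        assert (table.n_beams > 0).all()

    def test_single_beam_carries_everything(self, geometry):
        led = AttachmentLedger()
        c = geometry.beam_centers[0]
        band = int(geometry.radial_band(c[0]))
        for _ in range(7):
            led.log(3.0, c[0], c[1], 1e-12, "beam", band,
                    int(geometry.beam_layers[0]), 0, "stick")
        table = region_density(led, geometry, "radial")
        assert table.mass.sum() == pytest.approx(7e-12)
        assert table[table.band == band].mass.iloc[0] == pytest.approx(7e-12)
        assert (table[table.band != band].mass == 0.0).all()

    def test_uniform_attachment_gives_equal_per_beam_density(self, geometry):
        led = AttachmentLedger()
        for bid, c in enumerate(geometry.beam_centers):
            band = int(geometry.radial_band(c[0]))
            led.log(3.0, c[0], c[1], 1e-12, "beam", band,
                    int(geometry.beam_layers[bid]), bid, "stick")
        table = region_density(led, geometry, "radial")
        assert np.allclose(table.mass_per_beam, 1e-12)

    def test_partition_sums_match_global_total(self, geometry, rng):
        led = AttachmentLedger()
        n = 100
        pick = rng.integers(0, len(geometry.beam_centers), size=n)
        for bid in pick:
            c = geometry.beam_centers[bid]
            led.log(4.0, c[0], c[1], 2e-12, "beam",
                    int(geometry.radial_band(c[0])),
                    int(geometry.beam_layers[bid]), int(bid), "stick")
        radial = region_density(led, geometry, "radial")
        rows = region_density(led, geometry, "rows")
        assert radial.mass.sum() == pytest.approx(led.total_mass("beam"))
        assert rows.mass.sum() == pytest.approx(led.total_mass("beam"))

    def test_surface_partition_reports_densities(self, geometry):
        led = AttachmentLedger()
        led.log(3.0, 0.0, 0.0, 1e-12, "boundary", 1, -1, -1, "stick")
        table = region_density(led, geometry, "surface")
        wall = table[table.surface == "boundary"].iloc[0]
        assert wall.density == pytest.approx(1e-12 / wall.area)

    def test_unknown_partition_rejected(self, geometry):
        with pytest.raises(ValueError):
            region_density(AttachmentLedger(), geometry, "spiral")
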