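"""Lattice construction, voxel morphometrics, and domain labeling."""

import numpy as np
import pytest

from osteoseed.geometry import (DefectSpec, ScaffoldSpec, SectionDomain,
                                SectionGeometry, build_defect_domain,
                                build_titanium_lattice, build_section_domain,
                                porosity, surface_area, voxelize,
                                FACE_OUTLET, FLUID, SCAFFOLD)


class _Cylinder:
    """x-axis cylinder through the unit cube (test-only implicit solid)."""

    def __init__(self, radius=0.2, length=1.0):
        self.r, self.L = radius, length

    @property
    def bounds(self):
        return (0.0, -0.5, -0.5), (self.L, 0.5, 0.5)

    def contains(self, pts):
        p = np.asarray(pts, float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        return (x >= 0) & (x <= self.L) & (y * y + z * z <= self.r**2)

    def field(self, pts):
        p = np.asarray(pts, float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        rad = self.r - np.sqrt(y * y + z * z)
        return np.minimum(np.minimum(x, self.L - x), rad)


class _Cube:
    bounds = ((0.0, 0.0, 0.0), (1.0, 1.0, 1.0))

    def contains(self, pts):
        p = np.asarray(pts, float)
        return np.all((p >= 0.0) & (p <= 1.0), axis=-1)

    def field(self, pts):
        p = np.asarray(pts, float)
        return np.min(np.minimum(p, 1.0 - p), axis=-1)


class _Frustum:
    """Full truncated cone (no lattice), for the frustum-volume oracle."""

    def __init__(self, spec):
        self.spec = spec

    @property
    def bounds(self):
        r = self.spec.top_diameter / 2.0
        return (-r, -r, 0.0), (r, r, self.spec.height)

    def contains(self, pts):
        p = np.asarray(pts, float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        s = self.spec
        return (z >= 0) & (z <= s.height) \
            & (x * x + y * y <= s.radius_at(z) ** 2)


class TestLattice:
    def test_no_sublayers_gives_empty_solid(self):
        lat = build_titanium_lattice(ScaffoldSpec(n_sublayers=0))
        assert porosity(voxelize(lat, 0.1)) == 1.0

    def test_default_porosity_near_table_value(self):
        # the one morphometric anchor: 78.6% void in the titanium layer
        lat = build_titanium_lattice(ScaffoldSpec())
        assert porosity(voxelize(lat, 0.1)) == pytest.approx(0.786, abs=0.03)

    def test_porosity_converges_under_refinement(self, default_lattice):
        p_coarse = porosity(voxelize(default_lattice, 0.05))
        p_fine = porosity(voxelize(default_lattice, 0.025))
        assert abs(p_fine - p_coarse) < 0.01

    def test_porosity_plus_solid_fraction_is_one(self, default_lattice):
        dom = voxelize(default_lattice, 0.1)
        xs, ys, zs = dom.centers()
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        R = dom.frustum.radius_at(zs)[None, None, :]
        inside = (X * X + Y * Y)[:, :, None] <= R * R
        solid_frac = np.sum((dom.occupancy == SCAFFOLD) & inside) / inside.sum()
        assert porosity(dom) + solid_frac == pytest.approx(1.0, abs=1e-12)

    def test_rejects_beam_wider_than_cone(self):
        with pytest.raises(ValueError):
            build_titanium_lattice(ScaffoldSpec(top_diameter=8.0,
                                                bottom_diameter=0.4))

    def test_invalid_spacing_rejected(self, default_lattice):
        with pytest.raises(ValueError):
            voxelize(default_lattice, 0.0)


class TestVoxelizeOracles:
    def test_cylinder_volume_matches_closed_form(self):
        cyl = _Cylinder(radius=0.2, length=1.0)
        dom = voxelize(cyl, 0.02)
        vol = np.sum(dom.occupancy == SCAFFOLD) * dom.spacing**3
        assert vol == pytest.approx(np.pi * 0.2**2 * 1.0, rel=0.02)

    def test_frustum_solid_fraction_matches_formula(self):
        spec = ScaffoldSpec()
        dom = voxelize(_Frustum(spec), 0.05)
        vol = np.sum(dom.occupancy == SCAFFOLD) * dom.spacing**3
        R, r, h = spec.top_diameter / 2, spec.bottom_diameter / 2, spec.height
        v_frustum = np.pi * h / 3.0 * (R * R + R * r + r * r)
        assert vol == pytest.approx(v_frustum, rel=0.02)

    def test_voxelization_deterministic(self, default_lattice):
        a = voxelize(default_lattice, 0.1).occupancy
        b = voxelize(default_lattice, 0.1).occupancy
        assert np.array_equal(a, b)


class TestSurfaceArea:
    def test_unit_cube(self):
        assert surface_area(_Cube(), 0.04) == pytest.approx(6.0, rel=0.05)

    def test_single_beam_matches_cylinder_formula(self):
        r, L = 0.2, 1.0
        expected = 2 * np.pi * r * L + 2 * np.pi * r * r
        assert surface_area(_Cylinder(r, L), 0.015) == pytest.approx(
            expected, rel=0.05)

    def test_default_lattice_reports_positive_area(self, default_lattice):
        assert surface_area(default_lattice, 0.1) > 0.0


@pytest.fixture(scope="module")
def scaffold_domain():
    return voxelize(build_titanium_lattice(ScaffoldSpec()), 0.1)


class TestDefectDomain:
    def test_default_outlet_ring_nonempty(self, scaffold_domain):
        dom = build_defect_domain(scaffold_domain, DefectSpec())
        counts = dom.face_counts()
        assert counts["outlet_gap"] > 0
        assert counts["inlet_side"] > 0
        assert counts["inlet_bottom"] > 0

    def test_zero_gap_has_no_outlet(self, scaffold_domain):
        dom = build_defect_domain(scaffold_domain, DefectSpec(outlet_gap=0.0))
        assert dom.face_counts()["outlet_gap"] == 0

    def test_wider_gap_gives_more_outlet_faces(self, scaffold_domain):
        n = [build_defect_domain(scaffold_domain, DefectSpec(outlet_gap=g))
             .face_counts()["outlet_gap"] for g in (0.1, 0.3, 0.5)]
        assert n[0] < n[1] < n[2]

    def test_rejects_protruding_scaffold(self, scaffold_domain):
        with pytest.raises(ValueError):
            build_defect_domain(scaffold_domain, DefectSpec(depth=5.0))

    def test_face_labels_partition_the_boundary(self, scaffold_domain):
        dom = build_defect_domain(scaffold_domain, DefectSpec())
        fluid = dom.occupancy == FLUID
        n_boundary = 0
        for axis in range(3):
            a = fluid[tuple(slice(None, -1) if ax == axis else slice(None)
                            for ax in range(3))]
            b = fluid[tuple(slice(1, None) if ax == axis else slice(None)
                            for ax in range(3))]
            n_boundary += int(np.sum(a ^ b))
        # plus fluid faces on the grid boundary itself
        for axis in range(3):
            first = fluid[tuple(0 if ax == axis else slice(None)
                                for ax in range(3))]
            last = fluid[tuple(-1 if ax == axis else slice(None)
                               for ax in range(3))]
            n_boundary += int(first.sum()) + int(last.sum())
        assert sum(dom.face_counts().values()) == n_boundary


class TestSection:
    def test_face_census_matches_tags(self, coarse_section):
        counts = coarse_section.face_counts()
        assert counts["outlet_gap"] == 2      # one vent column per side
        assert counts["inlet_side"] > 0 and counts["inlet_bottom"] > 0

    def test_beam_sections_live_inside_the_cone(self):
        geo = SectionGeometry(ScaffoldSpec(), DefectSpec())
        c = geo.beam_centers
        assert len(c) > 0
        assert np.all(np.abs(c[:, 0]) <= geo.scaffold_radius_at(c[:, 1])
                      + geo.beam_radius)

    def test_nearest_beam_distance_at_center_is_minus_radius(self):
        geo = SectionGeometry(ScaffoldSpec(), DefectSpec())
        d, idx = geo.nearest_beam(geo.beam_centers[:3])
        assert np.allclose(d, -geo.beam_radius)
        assert np.array_equal(idx, np.arange(3))

    def test_wall_distance_near_bottom(self):
        geo = SectionGeometry(ScaffoldSpec(), DefectSpec())
        d, n, kind = geo.wall_distance(np.array([[0.0, 1e-4]]))
        assert kind[0] == "bottom"
        assert d[0] == pytest.approx(1e-4)
        assert np.allclose(n[0], (0.0, 1.0))

    def test_radial_bands_cover_one_to_five(self):
        geo = SectionGeometry(ScaffoldSpec(), DefectSpec())
        xs = np.linspace(-3.9e-3, 3.9e-3, 101)
        bands = geo.radial_band(xs)
        assert bands.min() == 1 and bands.max() == 5
        assert np.all(np.diff(bands) >= 0)
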