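"""Geometry builders: label bookkeeping, fibers, AHA segments, pacing."""

import numpy as np
import pytest

from reentry_scout import (
    BZ,
    CORE,
    HEALTHY,
    ScarSpec,
    assign_aha_and_pacing,
    assign_fibers,
    build_ellipsoid_lv,
    build_slab,
)
from reentry_scout.geometry import build_annulus, build_disc


class TestSlab:
    def test_scar_free_slab_is_all_healthy(self):
        m = build_slab(40, 40, 0, 1.0)
        assert (m.tissue == HEALTHY).all()
        assert m.n_nodes >= 41**2

    def test_labeled_areas_match_analytic_shapes(self):
        # central 20x20 core with a 2 mm border-zone rim, 0.5 mm edges
        scar = ScarSpec(
            core_regions=[("box", (20, 20, 0), (20, 20, 0))], bz_rim_width=2.0
        )
        m = build_slab(40, 40, 0, 0.5, scar)
        areas = m.measures()
        core_area = areas[m.tissue == CORE].sum()
        bz_area = areas[m.tissue == BZ].sum()
        assert core_area == pytest.approx(400.0, rel=0.05)
        # offset band: 24x24 minus 20x20 (sharp-corner approximation of
        # the rounded offset; centroid labeling rounds the corners)
        assert bz_area == pytest.approx(24**2 - 20**2, rel=0.05)

    def test_channel_moves_area_from_core_to_bz(self):
        base = ScarSpec(core_regions=[("box", (20, 20, 0), (20, 20, 0))])
        chan = ScarSpec(
            core_regions=[("box", (20, 20, 0), (20, 20, 0))],
            channels=[(np.array([[20.0, 10.0], [20.0, 30.0]]), 2.0)],
        )
        m0 = build_slab(40, 40, 0, 0.5, base)
        m1 = build_slab(40, 40, 0, 0.5, chan)
        a0, a1 = m0.measures(), m1.measures()
        d_core = a0[m0.tissue == CORE].sum() - a1[m1.tissue == CORE].sum()
        d_bz = a1[m1.tissue == BZ].sum() - a0[m0.tissue == BZ].sum()
        # channel area inside the core: 2 mm x 20 mm
        assert d_core == pytest.approx(40.0, rel=0.05)
        assert d_bz == pytest.approx(d_core, rel=1e-12)

    def test_label_partition_is_exhaustive(self):
        scar = ScarSpec(
            core_regions=[("box", (20, 20, 0), (20, 20, 0))], bz_rim_width=2.0
        )
        m = build_slab(40, 40, 0, 0.5, scar)
        a = m.measures()
        total = a.sum()
        parts = sum(a[m.tissue == t].sum() for t in (HEALTHY, BZ, CORE))
        assert parts == pytest.approx(total, rel=1e-12)

    def test_scar_outside_mesh_warns_and_clips(self):
        scar = ScarSpec(core_regions=[("box", (200, 200, 0), (10, 10, 0))])
        with pytest.warns(UserWarning, match="outside the mesh"):
            m = build_slab(40, 40, 0, 1.0, scar)
        assert (m.tissue == HEALTHY).all()

    @pytest.mark.parametrize("dims", [(0, 40, 0), (40, -1, 0), (40, 40, -2)])
    def test_degenerate_dimensions_rejected(self, dims):
        with pytest.raises(ValueError):
            build_slab(dims[0], dims[1], dims[2], 1.0)

    def test_meshing_is_deterministic(self):
        a = build_slab(40, 40, 0, 1.0)
        b = build_slab(40, 40, 0, 1.0)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.elements, b.elements)

    def test_3d_slab_is_conforming_with_exact_volume(self):
        m = build_slab(10, 8, 6, 1.0)
        m.validate()
        assert m.measures().sum() == pytest.approx(480.0, rel=1e-9)


class TestPolarMeshes:
    def test_annulus_area(self):
        m = build_annulus(9, 11, 0.5)
        m.validate()
        assert m.measures().sum() == pytest.approx(
            np.pi * (11**2 - 9**2), rel=0.01
        )

    def test_disc_area(self):
        m = build_disc(11, 0.5)
        m.validate()
        assert m.measures().sum() == pytest.approx(np.pi * 11**2, rel=0.01)


class TestFibers:
    def test_midwall_angle_is_mean_of_endo_epi(self):
        m = build_slab(10, 10, 4, 0.5)
        assign_fibers(m, 60.0, -60.0)
        mid = np.abs(m.centroids()[:, 2] - 2.0) < 0.2
        ang = np.degrees(np.arctan2(m.fibers[mid, 1], m.fibers[mid, 0]))
        assert np.abs(ang).max() < 10.0  # 0 deg +/- interpolation error

    def test_equal_angles_give_identical_fibers(self):
        m = build_slab(10, 10, 4, 1.0)
        assign_fibers(m, 0.0, 0.0)
        assert np.allclose(m.fibers, m.fibers[0])

    def test_2d_model_gets_constant_endo_angle(self):
        m = build_slab(10, 10, 0, 1.0)
        assign_fibers(m, 30.0, -60.0)
        ang = np.degrees(np.arctan2(m.fibers[:, 1], m.fibers[:, 0]))
        assert np.allclose(ang, 30.0, atol=1e-9)

    def test_fiber_angle_slope_recovers_prescription(self):
        # regression of measured angle on transmural depth: slope must
        # match (alpha_epi - alpha_endo) on a refined slab
        m = build_slab(12, 12, 6, 0.5)
        assign_fibers(m, 60.0, -60.0)
        tm = m.transmural[m.elements].mean(axis=1)
        ang = np.degrees(np.arctan2(m.fibers[:, 1], m.fibers[:, 0]))
        slope = np.polyfit(tm, ang, 1)[0]
        assert slope == pytest.approx(-120.0, abs=2.0)

    def test_fibers_are_unit_norm(self):
        lv = build_ellipsoid_lv(60, 30, 9, 3.0)
        assign_fibers(lv, 60, -60)
        assert np.abs(np.linalg.norm(lv.fibers, axis=1) - 1).max() < 1e-6


class TestEllipsoidLV:
    def test_thin_wall_sphere_limit_volume(self):
        # long = short axis -> spherical shell; base plane keeps the
        # portion below z = base_frac * R of both sphere volumes
        R, w, frac = 30.0, 3.0, 0.25
        lv = build_ellipsoid_lv(R, R, w, 1.5, base_z_frac=frac)

        def below(r, z0):
            # sphere volume below plane z = z0 (cap removed above)
            cap_h = r - z0
            cap = np.pi * cap_h**2 * (3 * r - cap_h) / 3
            return 4 / 3 * np.pi * r**3 - cap

        analytic = below(R, frac * R) - below(R - w, frac * R)
        assert lv.measures().sum() == pytest.approx(analytic, rel=0.05)

    def test_no_scar_is_all_healthy(self):
        lv = build_ellipsoid_lv(60, 30, 9, 3.0)
        assert (lv.tissue == HEALTHY).all()

    def test_apical_core_volume_matches_monte_carlo(self):
        scar = ScarSpec(core_regions=[("ellipsoid", (0, 0, -50), (14, 14, 14))])
        lv = build_ellipsoid_lv(60, 30, 9, 1.5, scar)
        core_vol = lv.measures()[lv.tissue == CORE].sum()
        # Monte-Carlo oracle: sample the shell, count points in the core
        rng = np.random.default_rng(42)
        n = 200_000
        pts = rng.uniform([-30, -30, -60], [30, 30, 15], size=(n, 3))
        r_out = np.linalg.norm(pts / [30, 30, 60], axis=1)
        r_in = np.linalg.norm(pts / [30 - 9, 30 - 9, 60 - 9], axis=1)
        in_shell = (r_out <= 1) & (r_in >= 1) & (pts[:, 2] <= 0.25 * 60)
        in_core = np.linalg.norm((pts - [0, 0, -50]) / 14, axis=1) <= 1
        mc = (in_shell & in_core).mean() * 60 * 60 * 75
        assert core_vol == pytest.approx(mc, rel=0.10)

    def test_wall_thicker_than_short_axis_rejected(self):
        with pytest.raises(ValueError):
            build_ellipsoid_lv(60, 30, 31, 2.0)


class TestAhaPacing:
    def test_lv_gets_17_distinct_sites(self):
        lv = build_ellipsoid_lv(60, 30, 9, 2.5)
        seg, sites = assign_aha_and_pacing(lv)
        assert len(sites) == 17
        assert len(set(sites.sites)) == 17
        assert set(np.unique(seg)) == set(range(1, 18))

    def test_slab_surrogate_sites_on_boundary_not_in_core(self):
        scar = ScarSpec(core_regions=[("box", (20, 20, 0), (10, 10, 0))])
        m = build_slab(40, 40, 0, 1.0, scar)
        seg, sites = assign_aha_and_pacing(m, 8)
        assert len(sites) == 8
        node_t = m.node_tissue()
        for s in sites:
            assert node_t[s] != CORE

    def test_fully_scarred_apex_drops_its_site(self):
        scar = ScarSpec(core_regions=[("ellipsoid", (0, 0, -52), (22, 22, 22))])
        lv = build_ellipsoid_lv(60, 30, 9, 2.5, scar)
        with pytest.warns(UserWarning, match="entirely scar core"):
            seg, sites = assign_aha_and_pacing(lv)
        assert len(sites) == 16
        assert 17 not in sites.segments
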