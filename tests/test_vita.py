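"""Virtual induction engine: splits, RTTs, filtering, dedup, metrics."""

import numpy as np
import pytest

from reentry_scout import (
    Circuit,
    assign_aha_and_pacing,
    build_slab,
    compute_rtt,
    deduplicate,
    detect_splits,
    filter_circuits,
    run_vita,
    solve,
)
from conftest import nearest_node

ANNULUS_LOOP_MS = 2 * np.pi * 9.0 / 0.5  # inner-circumference geodesic


def _induce(model, vel, src_xy):
    src = nearest_node(model, (*src_xy, 0))
    amap = solve(model, vel, [src])
    return detect_splits(model, amap, vel)


class TestDetectSplits:
    def test_disc_core_yields_one_opposite_isthmus(self, disc_core, iso_vel):
        isthmuses = _induce(disc_core, iso_vel, (11, 0))
        assert len(isthmuses) == 1
        isth = isthmuses[0]
        assert isth.encloses_scar
        # collision cluster sits diametrically opposite the pacing site
        mid = disc_core.nodes[isth.collision_edges.ravel()].mean(axis=0)
        assert mid[0] == pytest.approx(-10.0, abs=1.5)
        assert abs(mid[1]) < 1.5
        assert len(np.intersect1d(isth.side_a, isth.side_b)) == 0

    def test_scar_free_slab_has_no_isthmus(self, slab_homog, iso_vel):
        assert _induce(slab_homog, iso_vel, (0, 0)) == []

    def test_central_core_yields_one_cluster(self, central_core_slab, iso_vel):
        assert len(_induce(central_core_slab, iso_vel, (20, 0))) == 1

    def test_single_channel_yields_one_cluster(self, single_channel_slab, iso_vel):
        assert len(_induce(single_channel_slab, iso_vel, (20, 0))) == 1

    def test_two_channels_yield_two_clusters(self, two_channel_slab, iso_vel):
        assert len(_induce(two_channel_slab, iso_vel, (20, 0))) == 2

    def test_detection_is_deterministic(self, single_channel_slab, iso_vel):
        a = _induce(single_channel_slab, iso_vel, (20, 0))
        b = _induce(single_channel_slab, iso_vel, (20, 0))
        assert len(a) == len(b)
        assert np.array_equal(a[0].collision_edges, b[0].collision_edges)
        assert np.array_equal(a[0].side_a, b[0].side_a)


class TestRtt:
    def test_annular_loop_matches_analytic_circumference(self, disc_core, iso_vel):
        isth = _induce(disc_core, iso_vel, (11, 0))[0]
        for direction in ("a_to_b", "b_to_a"):
            c = compute_rtt(disc_core, iso_vel, isth, direction)
            assert c is not None
            assert c.rtt_ms == pytest.approx(ANNULUS_LOOP_MS, rel=0.05)

    def test_doubling_speed_halves_rtt(self, disc_core, iso_vel):
        isth = _induce(disc_core, iso_vel, (11, 0))[0]
        slow = compute_rtt(disc_core, iso_vel, isth, "a_to_b")
        isth2 = _induce(disc_core, iso_vel, (11, 0))[0]
        fast = compute_rtt(disc_core, iso_vel.scaled(2.0), isth2, "a_to_b")
        assert fast.rtt_ms == pytest.approx(slow.rtt_ms / 2.0, rel=0.02)

    def test_directional_symmetry_on_symmetric_loop(self, disc_core, iso_vel):
        isth = _induce(disc_core, iso_vel, (11, 0))[0]
        ab = compute_rtt(disc_core, iso_vel, isth, "a_to_b")
        ba = compute_rtt(disc_core, iso_vel, isth, "b_to_a")
        assert ab.rtt_ms == pytest.approx(ba.rtt_ms, rel=0.02)

    def test_reentry_map_finite_on_loop(self, disc_core, iso_vel):
        isth = _induce(disc_core, iso_vel, (11, 0))[0]
        c = compute_rtt(disc_core, iso_vel, isth, "a_to_b")
        assert np.isfinite(c.reentry_map[isth.loop_nodes]).all()

    def test_unknown_direction_rejected(self, disc_core, iso_vel):
        isth = _induce(disc_core, iso_vel, (11, 0))[0]
        with pytest.raises(ValueError):
            compute_rtt(disc_core, iso_vel, isth, "sideways")


def _dummy_circuit(rtt, seed=0, n=400, direction="a_to_b"):
    rng = np.random.default_rng(seed)
    return Circuit(
        isthmus=None, direction=direction, rtt_ms=rtt,
        reentry_map=rng.uniform(0, 2 * rtt, n), pacing_site=0,
        loop_mask=np.ones(n, dtype=bool),
    )


class TestFilter:
    def test_fifty_ms_cutoff(self):
        circuits = [_dummy_circuit(r) for r in (40.0, 55.0, 120.0)]
        kept = filter_circuits(circuits, 50.0)
        assert [c.rtt_ms for c in kept] == [55.0, 120.0]

    def test_zero_cutoff_keeps_all(self):
        circuits = [_dummy_circuit(r) for r in (40.0, 55.0)]
        assert len(filter_circuits(circuits, 0.0)) == 2

    def test_empty_input(self):
        assert filter_circuits([], 50.0) == []

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_circuits([], -1.0)


class TestDeduplicate:
    def test_same_circuit_from_three_sites_collapses(self, single_channel_slab, iso_vel):
        # the same isthmus induced from three pacing sites: maps differ by
        # where along the loop the block line sat (a phase offset)
        circuits = []
        for src_xy in [(20, 0), (0, 0), (40, 40)]:
            for isth in _induce(single_channel_slab, iso_vel, src_xy):
                c = compute_rtt(single_channel_slab, iso_vel, isth, "a_to_b")
                if c is not None:
                    circuits.append(c)
        assert len(circuits) == 3
        uniques = deduplicate(circuits, 0.9)
        assert len(uniques) <= 2  # one circuit (orientation may flip labels)

    def test_identical_maps_with_phase_shift_are_one(self):
        base = _dummy_circuit(100.0, seed=1)
        shifted = Circuit(
            isthmus=None, direction="a_to_b", rtt_ms=100.0,
            reentry_map=np.mod(base.reentry_map + 37.0, 100.0),
            pacing_site=1, loop_mask=base.loop_mask,
        )
        assert len(deduplicate([base, shifted], 0.9)) == 1

    def test_disjoint_circuits_never_merge(self, two_channel_slab, iso_vel):
        isthmuses = _induce(two_channel_slab, iso_vel, (20, 0))
        circuits = [
            compute_rtt(two_channel_slab, iso_vel, isth, "a_to_b")
            for isth in isthmuses
        ]
        circuits = [c for c in circuits if c is not None]
        assert len(circuits) == 2
        assert len(deduplicate(circuits, 0.9)) == 2

    def test_opposite_directions_stay_distinct(self, single_channel_slab, iso_vel):
        isth = _induce(single_channel_slab, iso_vel, (20, 0))[0]
        ab = compute_rtt(single_channel_slab, iso_vel, isth, "a_to_b")
        ba = compute_rtt(single_channel_slab, iso_vel, isth, "b_to_a")
        assert len(deduplicate([ab, ba], 0.9)) == 2

    def test_tiny_map_kept_as_own_group(self):
        a = _dummy_circuit(100.0, seed=2)
        tiny = Circuit(
            isthmus=None, direction="a_to_b", rtt_ms=100.0,
            reentry_map=np.full_like(a.reentry_map, np.inf),
            pacing_site=0, loop_mask=a.loop_mask,
        )
        assert len(deduplicate([a, tiny], 0.9)) == 2

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            deduplicate([], 0.0)


class TestRunVita:
    def test_scar_free_model_gives_zero_metrics(self, slab_homog, iso_vel):
        _, sites = assign_aha_and_pacing(slab_homog, 8)
        metrics, circuits, uniques = run_vita(slab_homog, iso_vel, sites)
        assert metrics.as_dict() == {
            "total_vts": 0, "unique_vts": 0, "mean_rtt_ms": 0.0, "max_rtt_ms": 0.0
        }
        assert metrics.no_circuits

    def test_metric_arithmetic_over_unique_rtts(self):
        circuits = [_dummy_circuit(100.0, seed=3), _dummy_circuit(150.0, seed=4)]
        from reentry_scout.vita import VitaMetrics

        rtts = np.array([c.rtt_ms for c in circuits])
        m = VitaMetrics(
            total_vts=5, unique_vts=2,
            mean_rtt_ms=float(rtts.mean()), max_rtt_ms=float(rtts.max()),
        )
        assert m.mean_rtt_ms == 125.0
        assert m.max_rtt_ms == 150.0
        assert m.unique_vts <= m.total_vts

    def test_single_channel_metrics(self, single_channel_slab, iso_vel):
        _, sites = assign_aha_and_pacing(single_channel_slab, 8)
        m1, c1, u1 = run_vita(single_channel_slab, iso_vel, sites)
        assert m1.unique_vts in (1, 2)
        assert m1.total_vts >= m1.unique_vts
        assert m1.max_rtt_ms >= m1.mean_rtt_ms
        m2, _, _ = run_vita(single_channel_slab, iso_vel, sites)
        assert m1.as_dict() == m2.as_dict()

    def test_removing_a_site_never_raises_total(self, single_channel_slab, iso_vel):
        _, sites = assign_aha_and_pacing(single_channel_slab, 8)
        full, _, _ = run_vita(single_channel_slab, iso_vel, list(sites))
        fewer, _, _ = run_vita(single_channel_slab, iso_vel, list(sites)[:-1])
        assert fewer.total_vts <= full.total_vts

    def test_rtt_scaling_with_velocity(self, single_channel_slab, iso_vel):
        _, sites = assign_aha_and_pacing(single_channel_slab, 8)
        slow, _, _ = run_vita(single_channel_slab, iso_vel, sites)
        fast, _, us = run_vita(
            single_channel_slab, iso_vel.scaled(2.0), sites, rtt_min_ms=25.0
        )
        assert fast.max_rtt_ms == pytest.approx(slow.max_rtt_ms / 2, rel=0.02)

    def test_upper_rtt_cutoff_drops_slow_circuits(self, single_channel_slab, iso_vel):
        _, sites = assign_aha_and_pacing(single_channel_slab, 8)
        m, _, _ = run_vita(single_channel_slab, iso_vel, sites, rtt_max_ms=60.0)
        assert m.total_vts == 0
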