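"""VM anchoring: classification boundaries, neighbor pairs, angle maps."""

import numpy as np
import pytest

from cytoarch.anchoring import (
    anchored_angle_map,
    anchored_distance_map,
    anchored_summary,
    classify_anchored,
    neighbor_pairs,
    periphery_height,
)
from cytoarch.errors import ValidationError
from cytoarch.model import Filament, MembraneModel

from conftest import straight_filament


def vertical(fid, x, y, z0, up=True, length=60.0):
    d = (0, 0, 1) if up else (0, 0, -1)
    return straight_filament(fid, start=(x, y, z0), direction=d, length=length)


class TestClassifyAnchored:
    @pytest.mark.parametrize("z,expect_anchored", [
        (59.0, True),   # within the threshold
        (60.0, True),   # boundary is inclusive
        (61.0, False),  # just outside
    ])
    def test_threshold_boundary(self, vm_plane, z, expect_anchored):
        f = vertical("f", 0, 0, z)
        anchored, rejected = classify_anchored([f], vm_plane)
        assert (len(anchored) == 1) == expect_anchored
        assert (["f"] == rejected) != expect_anchored

    def test_near_endpoint_is_closer_terminus(self, vm_plane):
        f = vertical("f", 0, 0, 100, up=False)  # runs 100 -> 40 nm
        (a,), _ = classify_anchored([f], vm_plane)
        assert a.vm_distance_nm == pytest.approx(40.0)
        np.testing.assert_allclose(a.near_endpoint, [0, 0, 40])
        np.testing.assert_allclose(a.directed_vector, [0, 0, 1])

    def test_equidistant_tie_takes_first_point_and_flags(self, vm_plane):
        f = straight_filament("f", start=(0, 0, 30), direction=(1, 0, 0))
        (a,), _ = classify_anchored([f], vm_plane)
        np.testing.assert_allclose(a.near_endpoint, f.points[0])
        assert a.tie_degenerate

    def test_monotone_in_threshold(self, vm_plane, rng):
        fils = [vertical(f"f{i}", i * 10.0, 0, rng.uniform(0, 120))
                for i in range(40)]
        a60, _ = classify_anchored(fils, vm_plane, 60.0)
        a61, _ = classify_anchored(fils, vm_plane, 61.0)
        assert {a.filament_id for a in a60} <= {a.filament_id for a in a61}

    def test_missing_vm_rejected(self):
        with pytest.raises(ValidationError):
            classify_anchored([straight_filament()], None)

    def test_near_endpoint_is_geometric_under_reversal(self, vm_plane):
        # with distinct terminus distances the near endpoint is the closer
        # one regardless of stored point order
        f = vertical("f", 0, 0, 10)
        g = Filament(id="f", kind="actin", points=f.points[::-1])
        (a,), _ = classify_anchored([f], vm_plane)
        (b,), _ = classify_anchored([g], vm_plane)
        np.testing.assert_allclose(a.directed_vector, b.directed_vector)

    def test_tie_reversal_flips_directed_angle(self, vm_plane):
        # equidistant termini: stored order decides, so reversal flips the
        # directed vector and maps a pair angle theta -> 180 - theta
        ref = vertical("ref", 0, 0, 10)
        h = straight_filament("h", start=(10, 0, 30), direction=(1, 0, 0))
        hr = Filament(id="h", kind="actin", points=h.points[::-1])
        from cytoarch.anchoring import neighbor_pairs as np_pairs
        from cytoarch.geometry import pair_angle

        (a1, b1), _ = classify_anchored([ref, h], vm_plane)
        (a2, b2), _ = classify_anchored([ref, hr], vm_plane)
        t1 = pair_angle(a1.directed_vector, b1.directed_vector, directed=True)
        t2 = pair_angle(a2.directed_vector, b2.directed_vector, directed=True)
        assert t1 + t2 == pytest.approx(180.0)


class TestNeighborPairs:
    @pytest.mark.parametrize("sep,expect_pair", [(119.0, True), (120.0, False)])
    def test_radius_boundary_strict(self, vm_plane, sep, expect_pair):
        fils = [vertical("a", 0, 0, 10), vertical("b", sep, 0, 10)]
        anchored, _ = classify_anchored(fils, vm_plane)
        pairs = neighbor_pairs(anchored)
        assert (len(pairs) == 1) == expect_pair

    def test_matches_brute_force_scan(self, vm_plane, rng):
        fils = [vertical(f"f{i}", *rng.uniform(0, 400, 2), rng.uniform(0, 50))
                for i in range(30)]
        anchored, _ = classify_anchored(fils, vm_plane)
        pairs = neighbor_pairs(anchored)
        got = {frozenset((p.id_a, p.id_b)) for p in pairs}
        near = {a.filament_id: a.near_endpoint for a in anchored}
        ids = sorted(near)
        expected = {
            frozenset((ids[i], ids[j]))
            for i in range(len(ids)) for j in range(i + 1, len(ids))
            if np.linalg.norm(near[ids[i]] - near[ids[j]]) < 120.0
        }
        assert got == expected
        assert all(p.id_a != p.id_b for p in pairs)


class TestAnchoredAngleMap:
    def test_codirected_vertical_pair(self, vm_plane):
        fils = [vertical("a", 0, 0, 10), vertical("b", 50, 0, 10)]
        anchored, _ = classify_anchored(fils, vm_plane)
        samples, hists = anchored_angle_map(anchored, neighbor_pairs(anchored))
        assert len(samples) == 2  # one per member
        np.testing.assert_allclose(samples.orientation_deg, 90.0)
        np.testing.assert_allclose(samples.directed_angle_deg, 0.0, atol=1e-9)
        assert hists["quasi_orthogonal"][0].sum() == 2
        assert hists["semi_parallel"][0].sum() == 0

    def test_antidirected_inplane_pair_gives_180(self, vm_plane):
        a = straight_filament("a", start=(0, 0, 10), direction=(1, 0, 0))
        b = straight_filament("b", start=(80, 0, 10), direction=(-1, 0, 0))
        anchored, _ = classify_anchored([a, b], vm_plane)
        samples, _ = anchored_angle_map(anchored, neighbor_pairs(anchored))
        np.testing.assert_allclose(samples.directed_angle_deg, 180.0)

    def test_blooming_scene_concentrates_small_angles(self, vm_plane, rng):
        # quasi-orthogonal co-directed filaments radiating from the VM
        fils = []
        for i in range(20):
            tilt = rng.uniform(0, 20)
            az = rng.uniform(0, 360)
            d = np.array([np.sin(np.radians(tilt)) * np.cos(np.radians(az)),
                          np.sin(np.radians(tilt)) * np.sin(np.radians(az)),
                          np.cos(np.radians(tilt))])
            start = np.array([*rng.uniform(100, 300, 2), rng.uniform(0, 20)])
            fils.append(Filament(id=f"f{i}", kind="actin",
                                 points=np.vstack([start, start + 60 * d])))
        anchored, _ = classify_anchored(fils, vm_plane)
        samples, hists = anchored_angle_map(anchored, neighbor_pairs(anchored))
        counts, edges = hists["quasi_orthogonal"]
        in_0_30 = counts[:2].sum()  # 15 deg bins
        assert in_0_30 > 0.6 * counts.sum()

    def test_empty_pairs_warns(self, vm_plane):
        anchored, _ = classify_anchored([vertical("a", 0, 0, 10)], vm_plane)
        with pytest.warns(UserWarning, match="empty"):
            samples, hists = anchored_angle_map(anchored, [])
        assert samples.empty

    def test_distance_map_variant(self, vm_plane):
        fils = [vertical("a", 0, 0, 10), vertical("b", 50, 0, 10)]
        anchored, _ = classify_anchored(fils, vm_plane)
        table = anchored_distance_map(anchored, neighbor_pairs(anchored))
        np.testing.assert_allclose(table.endpoint_separation_nm, 50.0)


class TestPeripheryHeight:
    def test_parallel_planes(self):
        vm = MembraneModel.xy_plane("vm", 0.0)
        dorsal = MembraneModel.xy_plane("dorsal", 200.0)
        assert periphery_height(vm, dorsal) == pytest.approx(200.0)

    def test_tilted_dorsal_mean_of_per_point_distances(self):
        # VM sampled on a grid; dorsal tilted 1 deg about y over a 1 um support
        xs = np.linspace(0, 1000, 101)
        ys = np.linspace(0, 1000, 11)
        gx, gy = np.meshgrid(xs, ys)
        vm_pts = np.column_stack([gx.ravel(), gy.ravel(),
                                  np.zeros(gx.size)])
        vm = MembraneModel.from_surface_points("vm", vm_pts)
        theta = np.radians(1.0)
        normal = np.array([-np.sin(theta), 0.0, np.cos(theta)])
        dorsal = MembraneModel.from_plane("dorsal", (0, 0, 200.0), normal)
        # analytic: |(p - p0) . n| = 200 cos t + x sin t, averaged over x
        expected = np.mean(200.0 * np.cos(theta) + xs * np.sin(theta))
        assert periphery_height(vm, dorsal) == pytest.approx(expected, rel=1e-9)

    def test_missing_dorsal_rejected(self):
        vm = MembraneModel.xy_plane("vm", 0.0)
        with pytest.raises(ValidationError):
            periphery_height(vm, None)


class TestAnchoredSummary:
    def test_nine_of_ten(self, vm_plane):
        fils = [vertical(f"f{i}", i * 200.0, 0, 10) for i in range(9)]
        fils.append(vertical("far", 2000, 0, 100))
        anchored, _ = classify_anchored(fils, vm_plane)
        count, percent = anchored_summary(anchored, fils)
        assert (count, percent) == (9, 90.0)

    def test_none_anchored(self, vm_plane):
        fils = [vertical("f", 0, 0, 100)]
        anchored, _ = classify_anchored(fils, vm_plane)
        assert anchored_summary(anchored, fils) == (0, 0.0)

    def test_consistent_with_flags_on_random_scenes(self, vm_plane, rng):
        fils = [vertical(f"f{i}", i * 10.0, 0, rng.uniform(0, 150))
                for i in range(50)]
        anchored, rejected = classify_anchored(fils, vm_plane)
        count, percent = anchored_summary(anchored, fils)
        assert count + len(rejected) == 50
        assert percent == pytest.approx(100.0 * count / 50)

    def test_zero_filaments_rejected(self):
        with pytest.raises(ValidationError):
            anchored_summary([], [])
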