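"""Scene model invariants and format round trips."""

import numpy as np
import pytest
import tifffile

from cytoarch.errors import ConfigurationError, FormatError, ValidationError
from cytoarch.io import (
    read_filament_table,
    read_scene,
    read_spatialgraph,
    read_volume_mask,
    surface_points_from_mask,
    write_filament_table,
    write_scene,
    write_spatialgraph,
    write_volume_mask,
)
from cytoarch.model import (
    Filament,
    MembraneModel,
    OrganelleSet,
    Scene,
    SceneFrame,
)

from conftest import straight_filament


class TestFilamentInvariants:
    def test_rejects_single_point(self):
        with pytest.raises(ValidationError, match="2 points"):
            Filament(id="a", kind="actin", points=np.array([[0.0, 0.0, 0.0]]))

    def test_rejects_duplicate_consecutive_points(self):
        with pytest.raises(ValidationError, match="duplicate"):
            Filament(id="a", kind="actin",
                     points=np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0.0]]))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValidationError, match="finite"):
            Filament(id="a", kind="actin",
                     points=np.array([[0, 0, 0], [np.nan, 0, 0.0]]))

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValidationError, match="kind"):
            straight_filament(kind="vimentin")


class TestSceneInvariants:
    def test_one_membrane_per_role(self, frame):
        vm1 = MembraneModel.xy_plane("vm", 0.0)
        vm2 = MembraneModel.xy_plane("vm", 5.0)
        with pytest.raises(ValidationError, match="role"):
            Scene(frame=frame, membranes=[vm1, vm2])

    def test_out_of_bounds_filament_warns_not_fails(self, frame):
        far = straight_filament(start=(5000, 0, 0))
        with pytest.warns(UserWarning, match="outside"):
            scene = Scene(frame=frame, filaments=[far])
        assert len(scene.filaments) == 1


class TestFilamentTable:
    def test_nm_identity_and_round_trip(self, tmp_path):
        fils = [straight_filament("a"), straight_filament("b", kind="mt",
                                                          start=(10, 20, 30))]
        path = tmp_path / "t.csv"
        write_filament_table(fils, path)
        back = read_filament_table(path)
        assert [f.id for f in back] == ["a", "b"]
        assert [f.kind for f in back] == ["actin", "mt"]
        for f, g in zip(fils, back):
            np.testing.assert_allclose(f.points, g.points, atol=1e-6)

    def test_voxel_units_converted_axiswise(self, tmp_path, frame):
        path = tmp_path / "t.csv"
        path.write_text(
            "filament_id,kind,x,y,z\nf,actin,10,0,0\nf,actin,10,0,5\n")
        (fil,) = read_filament_table(path, frame, units="voxel")
        # 10 voxels at 1.34 nm/voxel (13.4 A pixel) -> 13.4 nm
        np.testing.assert_allclose(fil.points[0], [13.4, 0.0, 0.0])
        np.testing.assert_allclose(fil.points[1], [13.4, 0.0, 6.7])

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("filament_id,x,y,z\nf,0,0,0\n")
        with pytest.raises(FormatError, match="kind"):
            read_filament_table(path)

    def test_one_point_filament_named_in_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("filament_id,kind,x,y,z\nlonely,actin,0,0,0\n"
                        "ok,actin,0,0,0\nok,actin,1,0,0\n")
        with pytest.raises(ValidationError, match="lonely"):
            read_filament_table(path)


class TestSpatialGraph:
    def test_single_edge_five_points(self, tmp_path):
        pts = np.column_stack([np.linspace(0, 40, 5), np.zeros(5), np.zeros(5)])
        fil = Filament(id="e", kind="actin", points=pts)
        path = tmp_path / "g.am"
        write_spatialgraph([fil], path)
        (back,) = read_spatialgraph(path)
        assert back.points.shape == (5, 3)

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        from conftest import random_polyline

        fils = [Filament(id=f"f{i}", kind="actin",
                         points=random_polyline(rng, n_pts=4))
                for i in range(3)]
        path = tmp_path / "g.am"
        write_spatialgraph(fils, path)
        back = read_spatialgraph(path)
        assert len(back) == 3
        for f, g in zip(fils, back):
            np.testing.assert_allclose(f.points, g.points, atol=1e-6)

    def test_dangling_vertex_reference(self, tmp_path):
        path = tmp_path / "g.am"
        write_spatialgraph([straight_filament()], path)
        text = path.read_text().replace("0 1", "0 9")
        path.write_text(text)
        with pytest.raises(FormatError, match="vertex"):
            read_spatialgraph(path)

    def test_empty_point_section(self, tmp_path):
        path = tmp_path / "g.am"
        write_spatialgraph([straight_filament()], path)
        path.write_text(path.read_text().replace("define POINT 2",
                                                 "define POINT 0"))
        with pytest.raises(FormatError):
            read_spatialgraph(path)


class TestVolumeMask:
    def test_round_trip_single_voxel(self, tmp_path):
        frame = SceneFrame(voxel_size_nm=(1.34,) * 3, dims_voxels=(10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[3, 4, 5] = True
        path = tmp_path / "m.mrc"
        write_volume_mask(mask, frame, path)
        back, bframe = read_volume_mask(path)
        assert back.sum() == 1
        assert back[3, 4, 5]
        # 13.4 A header pixel -> 1.34 nm
        np.testing.assert_allclose(bframe.voxel_size_nm, (1.34,) * 3, rtol=1e-5)

    def test_non_volume_file_is_format_error(self, tmp_path):
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, np.zeros((8, 8), np.uint8))
        with pytest.raises(FormatError):
            read_volume_mask(path)

    def test_zero_voxel_size_requires_override(self, tmp_path):
        frame = SceneFrame(voxel_size_nm=(1.0,) * 3, dims_voxels=(4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        path = tmp_path / "m.mrc"
        write_volume_mask(mask, frame, path)
        import struct

        data = bytearray(path.read_bytes())
        struct.pack_into("<3f", data, 40, 0.0, 0.0, 0.0)  # zero the cell
        path.write_bytes(bytes(data))
        with pytest.raises(ConfigurationError):
            read_volume_mask(path)
        _, bframe = read_volume_mask(path, voxel_size_nm=(2.0, 2.0, 2.0))
        assert bframe.voxel_size_nm == (2.0, 2.0, 2.0)


class TestSurfacePoints:
    def test_full_block_has_26_boundary_voxels(self):
        frame = SceneFrame(voxel_size_nm=(1.0,) * 3, dims_voxels=(3, 3, 3))
        mask = np.ones((3, 3, 3), bool)
        pts = surface_points_from_mask(mask, frame)
        assert len(pts) == 26  # all but the center voxel

    def test_single_voxel_center(self):
        frame = SceneFrame(voxel_size_nm=(2.0, 3.0, 4.0), dims_voxels=(8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        mask[1, 2, 3] = True  # (z, y, x)
        (pt,) = surface_points_from_mask(mask, frame)
        np.testing.assert_allclose(pt, [3 * 2.0, 2 * 3.0, 1 * 4.0])

    def test_empty_mask_rejected(self):
        frame = SceneFrame(voxel_size_nm=(1.0,) * 3, dims_voxels=(4, 4, 4))
        with pytest.raises(ValidationError):
            surface_points_from_mask(np.zeros((4, 4, 4), bool), frame)

    def test_matches_brute_force_neighbor_scan(self, rng):
        frame = SceneFrame(voxel_size_nm=(1.0,) * 3, dims_voxels=(8, 8, 8))
        for _ in range(5):
            mask = rng.random((8, 8, 8)) < 0.4
            if not mask.any():
                continue
            expected = set()
            padded = np.pad(mask, 1)
            for (z, y, x) in np.argwhere(mask):
                nbrs = [padded[z + 1 + dz, y + 1 + dy, x + 1 + dx]
                        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                           (0, -1, 0), (0, 0, 1), (0, 0, -1))]
                if not all(nbrs):
                    expected.add((float(x), float(y), float(z)))
            got = {tuple(p) for p in surface_points_from_mask(mask, frame)}
            assert got == expected
            assert len(got) <= mask.sum()


class TestSceneBundle:
    def test_round_trip(self, tmp_path, frame):
        scene = Scene(
            frame=frame,
            filaments=[straight_filament("a"),
                       straight_filament("m", kind="mt", start=(5, 5, 5))],
            membranes=[MembraneModel.xy_plane("vm", 0.0),
                       MembraneModel.xy_plane("dorsal", 200.0)],
            organelles=[OrganelleSet(
                kind="isg", centers=np.array([[100.0, 100.0, 100.0]]),
                radii=np.array([50.0]))],
            provenance={"origin": "test"},
        )
        write_scene(scene, tmp_path / "scene")
        back = read_scene(tmp_path / "scene")
        assert [f.id for f in back.filaments] == ["a", "m"]
        for f, g in zip(scene.filaments, back.filaments):
            np.testing.assert_allclose(f.points, g.points, atol=1e-6)
        assert back.membrane("vm") is not None
        assert back.membrane("dorsal") is not None
        assert len(back.organelle_set("isg")) == 1
        assert back.provenance["origin"] == "test"

    def test_missing_manifest(self, tmp_path):
        with pytest.raises(FormatError):
            read_scene(tmp_path)
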