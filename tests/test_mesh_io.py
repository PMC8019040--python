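"""Mesh reading, validation, exact volumes and heatmap export."""

import numpy as np
import pytest

import alphamorph as am
from alphamorph.errors import MeshFormatError, MeshValidationError
from alphamorph.heatmap import HeatmapMesh
from alphamorph.mesh_io import read_heatmap_sidecar, validate_mesh

from oracles import column_parity_volume


class TestReadValidate:
    def test_cube_ply_roundtrip(self, cube_mesh, tmp_path):
        path = am.write_mesh(cube_mesh, tmp_path / "cube.ply")
        mesh = am.read_mesh(path)
        assert mesh.n_vertices == 8
        assert mesh.n_faces == 12
        assert am.mesh_volume(mesh) == pytest.approx(1.0, rel=1e-12)

    def test_icosphere_obj_vertex_count(self, tmp_path):
        # subdivision n has 10*4^n + 2 vertices
        sph = am.make_primitive("sphere", 1.0, resolution=3)
        path = am.write_mesh(sph, tmp_path / "sphere.obj")
        mesh = am.read_mesh(path, format="obj")
        assert mesh.n_vertices == 10 * 4**3 + 2 == 642

    def test_stl_roundtrip_revalidates(self, cube_mesh, tmp_path):
        path = am.write_mesh(cube_mesh, tmp_path / "cube.stl")
        mesh = am.read_mesh(path)
        assert am.mesh_volume(mesh) == pytest.approx(1.0, rel=1e-9)

    def test_open_mesh_rejected_with_boundary_edges(self, cube_mesh):
        with pytest.raises(MeshValidationError, match="not watertight"):
            validate_mesh(cube_mesh.vertices, cube_mesh.faces[:-1])

    def test_degenerate_face_rejected(self, cube_mesh):
        faces = cube_mesh.faces.copy()
        faces[0] = [0, 0, 1]
        with pytest.raises(MeshValidationError, match="degenerate"):
            validate_mesh(cube_mesh.vertices, faces)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MeshFormatError):
            am.read_mesh(tmp_path / "nope.ply")

    def test_winding_normalized(self, cube_mesh):
        flipped = validate_mesh(cube_mesh.vertices, cube_mesh.faces[:, ::-1])
        assert am.mesh_volume(flipped) == pytest.approx(1.0, rel=1e-12)


class TestVolume:
    def test_sphere_volume(self):
        sph = am.make_primitive("sphere", 2.0, resolution=4)
        assert am.mesh_volume(sph) == pytest.approx(4 / 3 * np.pi * 8, rel=0.01)

    @pytest.mark.parametrize("shift", [(1.0, -2.0, 3.5), (100.0, 0.0, -7.0)])
    def test_translation_invariance(self, small_tube_mesh, shift):
        moved = am.SurfaceMesh(
            small_tube_mesh.vertices + np.asarray(shift), small_tube_mesh.faces,
            _validated=True,
        )
        assert am.mesh_volume(moved) == pytest.approx(
            am.mesh_volume(small_tube_mesh), rel=1e-9
        )

    @pytest.mark.parametrize("s", [0.1, 10.0])
    def test_scaling_cubes_volume(self, small_tube_mesh, s):
        scaled = am.SurfaceMesh(
            small_tube_mesh.vertices * s, small_tube_mesh.faces, _validated=True
        )
        assert am.mesh_volume(scaled) == pytest.approx(
            s**3 * am.mesh_volume(small_tube_mesh), rel=1e-9
        )

    def test_rotation_invariance(self, small_tube_mesh, rng):
        from scipy.stats import special_ortho_group

        R = special_ortho_group.rvs(3, random_state=np.random.RandomState(5))
        rot = am.SurfaceMesh(
            small_tube_mesh.vertices @ R.T, small_tube_mesh.faces, _validated=True
        )
        assert am.mesh_volume(rot) == pytest.approx(
            am.mesh_volume(small_tube_mesh), rel=1e-9
        )

    def test_tube_volume_matches_column_integration_oracle(self, small_tube_mesh):
        oracle = column_parity_volume(
            small_tube_mesh.vertices, small_tube_mesh.faces, n=128
        )
        assert am.mesh_volume(small_tube_mesh) == pytest.approx(oracle, rel=5e-3)


class TestHeatmapExport:
    def _tiny_heatmap(self, cube_mesh, vertex_k):
        vk = np.asarray(vertex_k, dtype=float)
        fk = np.nanmean(vk[cube_mesh.faces], axis=1)
        return HeatmapMesh(base=cube_mesh, vertex_k=vk, face_k=fk,
                           k_min=0.1, k_max=10_000.0)

    def test_uniform_map_single_color(self, cube_mesh, tmp_path):
        hm = self._tiny_heatmap(cube_mesh, np.full(8, 10_000.0))
        ply, sidecar = am.write_heatmap_mesh(hm, tmp_path / "hm.ply")
        import trimesh

        back = trimesh.load(str(ply), process=False)
        colors = np.asarray(back.visual.vertex_colors)
        assert (colors == colors[0]).all()

    def test_extreme_values_get_extreme_colors(self, cube_mesh, tmp_path):
        vk = np.full(8, 0.1)
        vk[4:] = 10_000.0
        hm = self._tiny_heatmap(cube_mesh, vk)
        ply, _ = am.write_heatmap_mesh(hm, tmp_path / "hm2.ply")
        import trimesh

        colors = np.asarray(trimesh.load(str(ply), process=False).visual.vertex_colors)
        warmth = colors[:, 0].astype(int) - colors[:, 2].astype(int)
        assert warmth[:4].min() > 0  # low k renders warm
        assert warmth[4:].max() < 0  # high k renders cool

    def test_colormap_monotone_cooling_in_k(self):
        from alphamorph.mesh_io import _heatmap_colors

        ks = np.logspace(-1, 4, 30)
        rgba = _heatmap_colors(ks, 0.1, 10_000.0).astype(int)
        warmth = rgba[:, 0] - rgba[:, 2]
        assert (np.diff(warmth) <= 0).all()
        assert warmth[0] > 0 > warmth[-1]

    def test_sidecar_roundtrip_bit_exact(self, cube_mesh, tmp_path):
        rng = np.random.default_rng(3)
        vk = 10.0 ** rng.uniform(-1, 4, size=8)
        hm = self._tiny_heatmap(cube_mesh, vk)
        _, sidecar = am.write_heatmap_mesh(hm, tmp_path / "hm3.ply")
        vk2, fk2 = read_heatmap_sidecar(sidecar)
        np.testing.assert_array_equal(vk2, hm.vertex_k)
        np.testing.assert_array_equal(fk2, hm.face_k)
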