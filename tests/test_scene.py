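"""Scene assembly, export round-trips, flat rendering, and picking."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import elegansviz as ev
from elegansviz.scene import (
    SceneError,
    dequantize_rgba,
    quantize_rgba,
)
from conftest import brute_force_nearest_cell


@pytest.fixture(scope="module")
def nested_scene(nested_fixture):
    model, roster, table, partition = nested_fixture
    cmap = ev.assign_colors(partition)
    return ev.build_scene(model, cmap, partition)


class TestBuildScene:
    def test_three_block_scene_materials(self, nested_fixture):
        model, _, _, partition = nested_fixture
        cmap = ev.assign_colors(partition)
        scene = ev.build_scene(model, cmap, partition)
        assert len(set(scene.cell_colors.values())) == 3
        assert scene.show_context and model.context_meshes

    def test_empty_partition_neutral_scene(self, nested_fixture):
        model, _, _, _ = nested_fixture
        scene = ev.build_scene(model, ev.ColorMap(entries={}), None)
        assert scene.cell_colors == {}
        assert scene.visible_cells == set(model.neuron_meshes)

    def test_missing_mesh_gets_soma_sphere(self, nested_fixture):
        model, roster, _, partition = nested_fixture
        import copy
        stripped = copy.copy(model)
        stripped.neuron_meshes = dict(model.neuron_meshes)
        pos = model.soma_positions["AVKL"]
        del stripped.neuron_meshes["AVKL"]
        cmap = ev.assign_colors(partition)
        scene = ev.build_scene(stripped, cmap, partition, soma_radius=0.7)
        assert "AVKL" in scene.stand_ins
        center = scene.stand_ins["AVKL"].vertices.mean(axis=0)
        np.testing.assert_allclose(center, pos, atol=1e-8)

    def test_unknown_colored_cell_rejected(self, nested_fixture):
        model, _, _, _ = nested_fixture
        with pytest.raises(SceneError, match="not in roster"):
            ev.build_scene(model, ev.role_colormap(),
                           {"NOTACELL": "sender"})


class TestExportRoundTrip:
    @pytest.mark.parametrize("fmt,name", [("gltf", "s.gltf"),
                                          ("obj", "s.obj"),
                                          ("ply", "plydir")])
    def test_color_binding_preserved(self, nested_scene, tmp_path, fmt, name):
        path = ev.export_scene(nested_scene, fmt, tmp_path / name)
        back = ev.import_scene_colors(path)
        for cell in nested_scene.visible_cells:
            assert quantize_rgba(back[cell]) == \
                quantize_rgba(nested_scene.color_of(cell))

    def test_gltf_validates(self, nested_scene, tmp_path):
        path = ev.export_scene(nested_scene, "gltf", tmp_path / "v.gltf")
        assert ev.validate_gltf(path) == []

    def test_glb_container(self, nested_scene, tmp_path):
        path = ev.export_scene(nested_scene, "gltf", tmp_path / "v.glb")
        assert ev.validate_gltf(path) == []
        back = ev.import_scene_colors(path)
        assert set(nested_scene.visible_cells) <= set(back)

    def test_obj_one_material_per_distinct_color(self, nested_scene, tmp_path):
        path = ev.export_scene(nested_scene, "obj", tmp_path / "m.obj")
        mtl = (tmp_path / "m.mtl").read_text()
        n_materials = mtl.count("newmtl")
        distinct = {quantize_rgba(nested_scene.color_of(c))
                    for c in nested_scene.visible_cells}
        distinct.add(quantize_rgba(nested_scene.colormap.context_color))
        assert n_materials == len(distinct)

    def test_unsupported_format(self, nested_scene, tmp_path):
        with pytest.raises(SceneError, match="format"):
            ev.export_scene(nested_scene, "stl", tmp_path / "x.stl")


def _allowed_colors(scene):
    """Quantized colors a flat render may contain."""
    bg = np.array(scene.colormap.background_color[:3])
    # renderer quantizes material RGBA (incl. alpha) before blending
    qctx = dequantize_rgba(quantize_rgba(scene.colormap.context_color))
    ctx_over_bg = qctx[3] * np.array(qctx[:3]) + (1 - qctx[3]) * bg
    allowed = {tuple(np.clip(np.round(bg * 255), 0, 255).astype(int)),
               tuple(np.clip(np.round(ctx_over_bg * 255), 0, 255).astype(int)),
               quantize_rgba(scene.colormap.neutral_color)[:3]}
    for cell in scene.visible_cells:
        allowed.add(quantize_rgba(scene.color_of(cell))[:3])
    return allowed


class TestRender:
    def test_resolution_and_color_set(self, nested_scene):
        spec = ev.camera_preset(nested_scene.model, "whole_worm", (160, 120))
        img = ev.render(nested_scene, spec)
        assert img.shape == (120, 160, 3)
        present = {tuple(c) for c in np.unique(img.reshape(-1, 3), axis=0)}
        assert present <= _allowed_colors(nested_scene)
        assert len(present) > 2  # blocks actually visible

    def test_determinism(self, nested_scene, tmp_path):
        spec = ev.camera_preset(nested_scene.model, "head", (100, 80))
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        ev.render(nested_scene, spec, p1)
        ev.render(nested_scene, spec, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_green_cube_fills_view(self, default_roster, tmp_path):
        """Flat rendering of one opaque object yields only that color."""
        from elegansviz import mesh_io
        cube = trimesh.creation.box(extents=(2, 2, 2))
        cube.apply_translation([1, 2, 3])
        p = mesh_io.write_obj(
            mesh_io.NamedMeshes(meshes={"AVKL": cube}), tmp_path / "c.obj")
        model = ev.load_model(p, default_roster)
        green = (0.0, 0.8, 0.0, 1.0)
        cmap = ev.role_colormap({"sender": green})
        scene = ev.build_scene(model, cmap, {"AVKL": "sender"})
        spec = ev.CameraSpec(eye=(1, 2, 4.6), target=(1, 2, 3), fov=90,
                             resolution=(64, 64))
        img = ev.render(scene, spec)
        colors = {tuple(c) for c in np.unique(img.reshape(-1, 3), axis=0)}
        assert colors == {quantize_rgba(green)[:3]}

    def test_turntable_frames(self, nested_scene, tmp_path):
        spec = ev.camera_preset(nested_scene.model, "whole_worm", (64, 48))
        paths = ev.turntable(nested_scene, 4, tmp_path / "frames", spec)
        assert len(paths) == 4
        assert all(p.exists() for p in paths)
        # frame 0 equals a direct render at the start camera
        direct = ev.render(nested_scene, spec)
        from PIL import Image
        frame0 = np.asarray(Image.open(paths[0]))
        np.testing.assert_array_equal(frame0, direct)

    def test_camera_validation(self):
        with pytest.raises(ValueError):
            ev.CameraSpec(eye=(0, 0, 0), target=(0, 0, 0))
        with pytest.raises(ValueError):
            ev.CameraSpec(resolution=(0, 10))


class TestPick:
    def test_soma_center_distance_zero(self, nested_scene):
        model = nested_scene.model
        cell, dist = ev.pick_neuron(nested_scene,
                                    model.soma_positions["RIML"])
        assert (cell, dist) == ("RIML", 0.0)

    def test_tie_breaks_lexicographic(self, nested_scene):
        model = nested_scene.model
        mid = (model.soma_positions["AVKL"]
               + model.soma_positions["AVKR"]) / 2.0
        cell, _dist = ev.pick_neuron(nested_scene, mid)
        assert cell == "AVKL"

    def test_matches_brute_force_scan(self, nested_scene):
        model = nested_scene.model
        rng = np.random.default_rng(11)
        cells = sorted(model.neuron_meshes)
        for _ in range(25):
            name = cells[rng.integers(len(cells))]
            point = model.soma_positions[name] + rng.normal(scale=1.5, size=3)
            got_cell, got_dist = ev.pick_neuron(nested_scene, point)
            oracle_cell, oracle_dist = brute_force_nearest_cell(model, point)
            if got_dist == 0.0:  # inside: surface oracle must agree on cell
                assert got_cell == oracle_cell
            else:
                assert got_cell == oracle_cell
                assert got_dist == pytest.approx(oracle_dist, abs=1e-9)

    def test_no_visible_neurons_is_error(self, nested_fixture):
        model, _, _, _ = nested_fixture
        scene = ev.build_scene(model, ev.ColorMap(entries={}), None,
                               include_uncolored=False)
        with pytest.raises(SceneError):
            ev.pick_neuron(scene, (0.0, 0.0, 0.0))
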