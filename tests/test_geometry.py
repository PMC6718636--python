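"""Geometry construction: layouts, voxelization, symmetry, config I/O."""

import dataclasses
import itertools

import numpy as np
import pytest

from protustim import (
    CONDUCTOR,
    GeometryError,
    ResolutionError,
    StructureConfig,
    build_structure,
    load_structure_config,
    protuberance_layout,
    save_structure_config,
    standard_configs,
    write_vtk_structured_points,
)


class TestStructureConfig:
    def test_size_ordering_enforced(self):
        with pytest.raises(ValueError):
            StructureConfig(80, 80, 12)  # Y must be < X
        with pytest.raises(ValueError):
            StructureConfig(100, 80, 90)  # Z must be < Y

    def test_cap_narrower_than_stem_rejected(self):
        with pytest.raises(ValueError):
            StructureConfig(100, 80, 12, cap_diameter_um=10.0)

    @pytest.mark.parametrize("n", [-1, 5])
    def test_protuberance_count_domain(self, n):
        with pytest.raises(ValueError):
            StructureConfig(100, 80, 12, n_protuberances=n)

    def test_code(self):
        assert StructureConfig(100, 80, 12).code == "100/80/12"


class TestProtuberanceLayout:
    def test_center_placement_single(self):
        assert protuberance_layout(1, 80.0) == [(0.0, 0.0)]

    def test_pair_symmetric_about_origin(self):
        pts = np.array(protuberance_layout(2, 80.0))
        assert np.allclose(pts.sum(axis=0), 0.0)

    def test_square_by_distance_matrix(self):
        """Four points must form a square: brute-force all pairwise distances."""
        pts = np.array(protuberance_layout(4, 80.0))
        d = sorted(
            float(np.hypot(*(pts[i] - pts[j])))
            for i, j in itertools.combinations(range(4), 2)
        )
        side, diag = d[0], d[-1]
        assert np.allclose(d[:4], side)  # four equal sides
        assert np.allclose(d[4:], diag)  # two equal diagonals
        assert diag == pytest.approx(side * np.sqrt(2))

    def test_radius_fraction(self):
        for n in (1, 2, 3, 4):
            pts = np.array(protuberance_layout(n, 80.0))
            r = np.hypot(pts[:, 0], pts[:, 1])
            if n == 1:
                assert np.allclose(r, 0.0)
            else:
                assert np.allclose(r, 0.5 * 40.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            protuberance_layout(5, 80.0)


class TestStandardConfigs:
    def test_attested_codes_present(self):
        codes = {c.code for c in standard_configs()}
        assert {"100/80/12", "80/60/10", "60/40/8"} <= codes

    def test_size_ordering_invariant(self):
        for c in standard_configs():
            assert c.pillar_base_diameter_um < c.electrode_diameter_um \
                < c.well_length_um

    def test_instantiable_with_all_pillar_counts(self):
        for n in range(5):
            assert all(
                c.n_protuberances == n for c in standard_configs(n_protuberances=n)
            )


class TestBuildStructure:
    def test_too_coarse_spacing_rejected(self, small_config):
        with pytest.raises(ResolutionError):
            build_structure(small_config, spacing_um=4.0, margin_um=60.0)

    def test_margin_must_cover_bath(self, small_config):
        with pytest.raises(ValueError):
            build_structure(small_config, spacing_um=2.0, margin_um=10.0)

    def test_layout_exceeding_electrode_rejected(self):
        cfg = StructureConfig(60, 40, 8, n_protuberances=4, cap_diameter_um=30.0)
        with pytest.raises(GeometryError):
            build_structure(cfg, spacing_um=2.0, margin_um=60.0)

    def test_no_pillar_equals_flat_geometry(self, small_config):
        """n=0 grid is voxelwise identical to the flat-electrode structure."""
        g0 = build_structure(small_config, 2.0, 60.0)
        flat = build_structure(
            dataclasses.replace(small_config, n_protuberances=0), 2.0, 60.0
        )
        assert np.array_equal(g0.labels, flat.labels)
        assert np.array_equal(g0.electrode_ids, flat.electrode_ids)

    def test_caps_below_ground_plane_top(self):
        cfg = StructureConfig(100, 80, 12, n_protuberances=2)
        grid = build_structure(cfg, 1.0, 100.0)
        assert grid.meta["pillar_top_um"] < grid.meta["ground_top_um"]
        centers = np.array(grid.meta["pillar_centers_um"])
        assert np.allclose(centers.sum(axis=0), 0.0)  # symmetric about center

    def test_pillar_volume_matches_closed_form(self, small_config):
        """Conductor volume added by one pillar ≈ analytic stem + cap volume."""
        h = 1.0
        cfg1 = dataclasses.replace(small_config, n_protuberances=1)
        v0 = build_structure(small_config, h, 60.0).material_volume_um3(CONDUCTOR)
        v1 = build_structure(cfg1, h, 60.0).material_volume_um3(CONDUCTOR)
        stem_h = cfg1.pillar_height_um - 2.0
        cap_h = 2.0
        analytic = (
            np.pi * (cfg1.pillar_base_diameter_um / 2) ** 2 * stem_h
            + np.pi * (cfg1.cap_diameter_um / 2) ** 2 * cap_h
        )
        # one-voxel-shell tolerance on the pillar surface area
        area = (
            2 * np.pi * (cfg1.pillar_base_diameter_um / 2) * stem_h
            + 2 * np.pi * (cfg1.cap_diameter_um / 2) * cap_h
            + 2 * np.pi * (cfg1.cap_diameter_um / 2) ** 2
        )
        assert abs((v1 - v0) - analytic) < area * h

    def test_mirror_symmetry_symmetric_layouts(self, small_config):
        """Label grids for n ∈ {0,1,2,4} are exactly invariant under x-reflection."""
        for n in (0, 1, 2, 4):
            cfg = dataclasses.replace(small_config, n_protuberances=n)
            grid = build_structure(cfg, 2.0, 60.0)
            assert np.array_equal(grid.labels, grid.labels[::-1, :, :]), n
            assert np.array_equal(grid.labels, grid.labels[:, ::-1, :]), n

    def test_determinism(self, small_config):
        a = build_structure(small_config, 2.0, 60.0)
        b = build_structure(small_config, 2.0, 60.0)
        assert a.labels.tobytes() == b.labels.tobytes()
        assert a.electrode_ids.tobytes() == b.electrode_ids.tobytes()

    def test_resolution_consistency(self, small_config):
        """Halving the spacing moves each material volume by less than a
        surface-shell bound (domain area × coarse spacing)."""
        coarse = build_structure(small_config, 2.0, 60.0)
        fine = build_structure(small_config, 1.0, 60.0)
        for label in (0, 1, 2):
            v_c = coarse.material_volume_um3(label)
            v_f = fine.material_volume_um3(label)
            nx, ny, nz = coarse.dims
            h = coarse.spacing_um
            domain_area = 6 * max(nx * ny, nx * nz, ny * nz) * h * h
            assert abs(v_c - v_f) < domain_area * h


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        save_structure_config(small_config, path)
        assert load_structure_config(path) == small_config

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("well_length_um: 100\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            load_structure_config(path)


def test_vtk_export_header_and_size(tmp_path, small_config):
    grid = build_structure(small_config, 2.0, 60.0)
    path = tmp_path / "grid.vtk"
    write_vtk_structured_points(path, grid)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("# vtk DataFile")
    nx, ny, nz = grid.dims
    assert f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}" in lines
    assert f"CELL_DATA {nx * ny * nz}" in lines
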