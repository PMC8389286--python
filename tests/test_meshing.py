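"""Synthetic head and box geometry: labels, volumes, symmetry, validation."""
import dataclasses

import numpy as np
import pytest

from ocufield.meshing import (GeometryError, HeadGeometryParams, VolumeMesh,
                              generate_homogeneous_box, generate_layered_head,
                              validate_mesh)
from ocufield.tissues import TISSUES, ConductivityTable


class TestHeadGeometry:
    def test_default_head_carries_all_six_tissues(self, head_mesh):
        assert head_mesh.tissue_names() == set(TISSUES)

    def test_total_volume_matches_sphere_minus_exposure_carve(self):
        # at 4 mm resolution the summed tet volume approximates the
        # analytic ball; the carved exposure channels remove well under 1%
        params = HeadGeometryParams(target_edge_length=4.0)
        mesh = generate_layered_head(params)
        total = mesh.tet_volumes().sum()
        analytic = 4.0 / 3.0 * np.pi * params.skin_radius ** 3
        assert abs(total - analytic) / analytic < 0.02

    def test_deterministic_for_fixed_seed(self, head_mesh, head_params):
        again = generate_layered_head(head_params)
        assert again.content_hash() == head_mesh.content_hash()

    def test_seed_changes_tessellation(self, head_mesh, head_params):
        other = generate_layered_head(
            dataclasses.replace(head_params, seed=head_params.seed + 1))
        assert other.content_hash() != head_mesh.content_hash()

    def test_mirror_symmetric_tissue_volumes(self, head_mesh):
        # geometry (not tessellation) is statistically mirror symmetric:
        # per-tissue volume in each x half agrees within 2%
        vols = head_mesh.tet_volumes()
        cx = head_mesh.tet_centroids()[:, 0]
        for code in np.unique(head_mesh.tet_labels):
            sel = head_mesh.tet_labels == code
            right = vols[sel & (cx > 0)].sum()
            left = vols[sel & (cx < 0)].sum()
            assert abs(right - left) / max(right, left) < 0.02

    def test_degenerate_eye_radius_rejected(self):
        with pytest.raises(GeometryError):
            HeadGeometryParams(eye_radius=0.0).validate()

    def test_non_increasing_radii_rejected(self):
        with pytest.raises(GeometryError):
            HeadGeometryParams(layer_radii=(74, 78, 78, 82, 85)).validate()

    def test_overlapping_eyes_rejected(self):
        with pytest.raises(GeometryError):
            HeadGeometryParams(
                eye_center_offsets=((5, 65, 5), (-5, 65, 5))).validate()

    def test_buried_eye_rejected(self):
        with pytest.raises(GeometryError):
            HeadGeometryParams(
                eye_center_offsets=((20, 40, 5), (-20, 40, 5))).validate()


class TestHomogeneousBox:
    def test_single_label(self):
        mesh = generate_homogeneous_box(200.0, 1.0, 25.0)
        assert mesh.tissue_names() == {"medium"}

    def test_exact_volume(self):
        mesh = generate_homogeneous_box(200.0, 1.0, 25.0)
        assert mesh.tet_volumes().sum() == pytest.approx(200.0 ** 3,
                                                         rel=1e-12)

    def test_refinement_scaling(self):
        coarse = generate_homogeneous_box(100.0, 1.0, 10.0)
        fine = generate_homogeneous_box(100.0, 1.0, 5.0)
        ratio = fine.n_tets / coarse.n_tets
        assert 8 / 1.5 <= ratio <= 8 * 1.5

    def test_six_tagged_faces(self):
        mesh = generate_homogeneous_box(100.0, 1.0, 20.0)
        names = {"x_min", "x_max", "y_min", "y_max", "z_min", "z_max"}
        assert names <= set(mesh.boundary_patches)
        n_face_tris = sum(len(mesh.boundary_patches[n]) for n in names)
        faces, _ = mesh.exterior_faces()
        assert n_face_tris == len(faces)

    def test_nonpositive_edge_rejected(self):
        with pytest.raises(GeometryError):
            generate_homogeneous_box(-1.0, 1.0, 10.0)

    def test_mirror_tessellation_is_x_symmetric(self):
        mesh = generate_homogeneous_box(80.0, 1.0, 20.0, mirror_x=True)
        flipped = mesh.nodes * np.array([-1.0, 1.0, 1.0])
        key = {tuple(np.round(p, 9)) for p in mesh.nodes}
        assert {tuple(np.round(p, 9)) for p in flipped} == key
        assert validate_mesh(
            mesh, ConductivityTable({"medium": 1.0})).passed


class TestValidation:
    def test_default_head_passes_all_checks(self, head_mesh):
        assert validate_mesh(head_mesh).passed

    def test_inverted_tet_detected(self, small_box):
        mesh, table = small_box
        tets = mesh.tets.copy()
        tets[0] = tets[0][[0, 2, 1, 3]]     # flip orientation
        bad = VolumeMesh(nodes=mesh.nodes, tets=tets,
                         tet_labels=mesh.tet_labels,
                         label_names=mesh.label_names)
        report = validate_mesh(bad, table)
        assert not report.checks["positive_volume"]

    def test_unknown_label_detected(self, small_box):
        mesh, table = small_box
        labels = mesh.tet_labels.copy()
        labels[0] = 99
        bad = VolumeMesh(nodes=mesh.nodes, tets=mesh.tets, tet_labels=labels,
                         label_names={**mesh.label_names, 99: "muscle"})
        report = validate_mesh(bad, table)
        assert not report.checks["label_coverage"]

    def test_watertight_exterior(self, head_mesh):
        assert validate_mesh(head_mesh).checks["watertight_exterior"]


class TestConductivityTable:
    def test_reference_values(self):
        table = ConductivityTable()
        assert table["white_matter"] == 0.027656
        assert table["gray_matter"] == 0.027512
        assert table["csf"] == 2.0000
        assert table["bone"] == 0.020028
        assert table["skin"] == 2.0000e-4
        assert table["eyeball"] == 0.41113

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ConductivityTable({"skin": 0.0})

    def test_overrides_are_explicit(self):
        table = ConductivityTable(overrides={"skin": 0.465})
        assert table["skin"] == 0.465
        assert ConductivityTable()["skin"] == 2.0e-4
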