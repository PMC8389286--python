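"""Montage families, patch projection and phasor superposition."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocufield.fem import ChannelUnitSolution
from ocufield.meshing import HeadGeometryParams, generate_layered_head
from ocufield.montage import (ElectrodePatch, Montage, StimulationChannel,
                              apply_phase_condition, build_study_montages,
                              project_patch_to_scalp, superpose,
                              validate_montage, SWEEP_PAIRS, STATIONS)


def make_unit(field) -> ChannelUnitSolution:
    field = np.asarray(field, dtype=float)
    return ChannelUnitSolution(
        channel_id="synthetic", phi=np.zeros(4), field=field,
        delivered_current=1.0, anode_nodes=np.array([0]),
        cathode_nodes=np.array([1]))


def make_channel(current=1.0, phase=0.0, x=50.0) -> StimulationChannel:
    fh = ElectrodePatch(center=(x, 60.0, 30.0))
    ck = ElectrodePatch(center=(x, 60.0, -30.0))
    return StimulationChannel(forehead=fh, cheek=ck, current_mA=current,
                              phase_deg=phase)


class TestFamilies:
    def test_separation_sweep_counts(self):
        montages = build_study_montages("separation_sweep")
        assert len(montages) == 15
        assert sum(1 for m in montages if len(m.channels) == 2) == 9

    def test_two_pair_composition(self):
        by_id = {m.id: m for m in build_study_montages("separation_sweep")}
        for k, (r, l) in SWEEP_PAIRS.items():
            pair = by_id[f"electrode_{k}"]
            assert pair.constituents == (f"electrode_{r}", f"electrode_{l}")
            assert pair.channels[0] is by_id[f"electrode_{r}"].channels[0]
            assert pair.channels[1] is by_id[f"electrode_{l}"].channels[0]

    def test_intended_region_annotations(self):
        by_id = {m.id: m for m in build_study_montages("intended_region")}
        assert len(by_id) == 7
        assert by_id["II"].annotation.startswith(
            "Right and center of the visual field")
        assert by_id["i"].annotation == "Right hand of the visual field"

    def test_center_boost_currents(self):
        for m in build_study_montages("center_boost"):
            currents = sorted(ch.current_mA for ch in m.channels)
            assert currents == [1.0, 1.5]
            boosted = [ch for ch in m.channels if ch.current_mA == 1.5][0]
            # the boosted channel targets the eyeball-surface centre via
            # the nasal forehead / low cheek pair
            assert "nasal" in boosted.forehead.station

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            build_study_montages("spiral")

    def test_all_montages_disjoint_on_default_head(self, head_mesh):
        for fam in ("separation_sweep", "intended_region", "one_eye",
                    "center_boost"):
            for m in build_study_montages(fam):
                checks = validate_montage(head_mesh, m)
                assert all(checks.values()), (fam, m.id, checks)


class TestPhaseConditions:
    def test_anti_phase_flips_right_side_of_two_pair(self):
        pair = [m for m in build_study_montages("separation_sweep")
                if m.id == "electrode_7"][0]
        anti = apply_phase_condition(pair, "anti")
        right = [ch for ch in anti.channels if ch.on_right_side][0]
        left = [ch for ch in anti.channels if not ch.on_right_side][0]
        assert right.phase_deg == 180.0
        assert left.phase_deg == 0.0

    def test_anti_phase_flips_single_pair(self):
        single = [m for m in build_study_montages("separation_sweep")
                  if m.id == "electrode_1"][0]
        anti = apply_phase_condition(single, "anti")
        assert anti.channels[0].phase_deg == 180.0


class TestPatchProjection:
    def test_surface_center_is_fixed_point(self, head_mesh):
        patch = ElectrodePatch.at_station("F_mid_R", 85.0)
        sp = project_patch_to_scalp(head_mesh, patch)
        assert np.linalg.norm(sp.center - np.asarray(patch.center)) < 6.0

    def test_area_tracks_square_at_fine_resolution(self):
        mesh = generate_layered_head(
            HeadGeometryParams(target_edge_length=3.0))
        for name in ("F_mid_R", "C_L", "F_temporal_far_L"):
            sp = project_patch_to_scalp(
                mesh, ElectrodePatch.at_station(name, 85.0))
            assert abs(sp.area_mm2 - 42.0 ** 2) / 42.0 ** 2 < 0.20

    def test_opposite_side_patches_disjoint(self, head_mesh):
        a = project_patch_to_scalp(
            head_mesh, ElectrodePatch.at_station("F_temporal_R", 85.0))
        b = project_patch_to_scalp(
            head_mesh, ElectrodePatch.at_station("F_temporal_L", 85.0))
        assert np.intersect1d(a.nodes, b.nodes).size == 0

    def test_far_center_rejected(self, head_mesh):
        from ocufield.fem import MontageError
        with pytest.raises(MontageError):
            project_patch_to_scalp(
                head_mesh, ElectrodePatch(center=(0.0, 200.0, 0.0)))


class TestSuperposition:
    def test_single_channel_any_phase_reproduces_unit_norm(self, rng):
        field = rng.normal(size=(50, 3))
        for phase in (0.0, 45.0, 90.0, 180.0, 300.0):
            combined = superpose([make_unit(field)],
                                 [make_channel(1.0, phase)])
            assert np.allclose(combined.peak_norm,
                               np.linalg.norm(field, axis=1), rtol=1e-12)

    def test_identical_channels_in_anti_phase_cancel_exactly(self, rng):
        field = rng.normal(size=(40, 3))
        combined = superpose(
            [make_unit(field), make_unit(field)],
            [make_channel(1.0, 0.0), make_channel(1.0, 180.0)])
        assert np.all(combined.peak_norm == 0.0)

    def test_same_phase_norm_is_weighted_vector_sum(self, rng):
        f1, f2 = rng.normal(size=(2, 30, 3))
        a, b = 1.25, 2.5
        combined = superpose(
            [make_unit(f1), make_unit(f2)],
            [make_channel(a, 0.0), make_channel(b, 0.0)])
        assert np.allclose(combined.peak_norm,
                           np.linalg.norm(a * f1 + b * f2, axis=1),
                           rtol=1e-12)

    def test_polarity_flip_leaves_norm_bit_identical(self, rng):
        field = rng.normal(size=(30, 3))
        n0 = superpose([make_unit(field)], [make_channel(1.0, 0.0)]).peak_norm
        n180 = superpose([make_unit(field)],
                         [make_channel(1.0, 180.0)]).peak_norm
        assert np.array_equal(n0, n180)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            superpose([make_unit(rng.normal(size=(5, 3)))],
                      [make_channel(), make_channel()])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1),
           c=st.floats(0.1, 8.0),
           i1=st.floats(0.1, 3.0), i2=st.floats(0.1, 3.0))
    def test_current_scaling_and_triangle_inequality(self, seed, c, i1, i2):
        r = np.random.default_rng(seed)
        f1, f2 = r.normal(size=(2, 20, 3))
        units = [make_unit(f1), make_unit(f2)]
        chans = [make_channel(i1, 0.0), make_channel(i2, 180.0)]
        norm = superpose(units, chans).peak_norm
        # |c| scaling, exact
        scaled = superpose(units, [make_channel(c * i1, 0.0),
                                   make_channel(c * i2, 180.0)]).peak_norm
        assert np.allclose(scaled, c * norm, rtol=1e-12)
        # triangle inequality against the single-channel norms
        bound = (i1 * np.linalg.norm(f1, axis=1)
                 + i2 * np.linalg.norm(f2, axis=1))
        assert np.all(norm <= bound * (1 + 1e-12) + 1e-300)

    def test_quadrature_component_zero_for_surveyed_phases(self, rng):
        field = rng.normal(size=(10, 3))
        combined = superpose(
            [make_unit(field), make_unit(field)],
            [make_channel(1.0, 0.0), make_channel(1.0, 180.0)])
        assert np.all(combined.quadrature == 0.0)

    def test_general_phase_peak_norm_bounded_by_components(self, rng):
        f1, f2 = rng.normal(size=(2, 25, 3))
        combined = superpose([make_unit(f1), make_unit(f2)],
                             [make_channel(1.0, 0.0), make_channel(1.0, 90.0)])
        lo = np.maximum(np.linalg.norm(f1, axis=1),
                        np.linalg.norm(f2, axis=1))
        hi = np.linalg.norm(f1, axis=1) + np.linalg.norm(f2, axis=1)
        assert np.all(combined.peak_norm >= lo - 1e-12)
        assert np.all(combined.peak_norm <= hi + 1e-12)


def test_station_table_is_left_right_mirror():
    for name, (az, el) in STATIONS.items():
        if name.endswith("_R"):
            partner = name[:-2] + "_L"
            paz, pel = STATIONS[partner]
            assert paz == -az and pel == el
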