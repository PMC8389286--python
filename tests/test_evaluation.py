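"""Observation points, profile sampling, differences and peak finding."""
import numpy as np
import pytest

from ocufield.evaluation import (EYE_SEQ, NormProfile, compare_profiles,
                                 default_observation_points, find_peaks,
                                 locate_observation_elements,
                                 run_step1_separation_sweep,
                                 sample_norm_profile, sum_profiles)
from ocufield.montage import CombinedField


def profile(values, montage="m", condition="c") -> NormProfile:
    return NormProfile(montage_id=montage, condition=condition,
                       point_ids=np.arange(1, 16),
                       values=np.asarray(values, dtype=float))


def arc_profile(right, nose, left_nasal_to_temporal):
    """Build a 15-point profile from per-eye sequences (nasal->temporal)."""
    vals = np.empty(15)
    for v, pid in zip(right, EYE_SEQ["right_eye"]):
        vals[pid - 1] = v
    vals[7] = nose
    for v, pid in zip(left_nasal_to_temporal, EYE_SEQ["left_eye"]):
        vals[pid - 1] = v
    return profile(vals)


class TestObservationPoints:
    def test_fifteen_points_with_region_split(self, head_mesh):
        pts = default_observation_points(head_mesh)
        assert [p.id for p in pts] == list(range(1, 16))
        regions = [p.region for p in pts]
        assert regions.count("right_eye") == 7
        assert regions.count("nose") == 1
        assert regions.count("left_eye") == 7

    def test_right_eye_positive_x_left_eye_negative_x(self, head_mesh):
        pts = default_observation_points(head_mesh)
        for p in pts:
            if p.id <= 7:
                assert p.coords[0] > 0
            elif p.id >= 9:
                assert p.coords[0] < 0
        assert abs(pts[7].coords[0]) < 1.0      # nose on the midline

    def test_x_strictly_decreasing_with_id(self, head_mesh):
        # the shared profile axis of the study: ids ordered by x coordinate
        pts = default_observation_points(head_mesh)
        xs = [p.coords[0] for p in pts if p.region != "nose"]
        assert all(a > b for a, b in zip(xs, xs[1:]))

    def test_eye_points_lie_on_eye_sphere(self, head_mesh, head_params):
        pts = default_observation_points(head_mesh)
        centers = np.asarray(head_params.eye_center_offsets)
        for p in pts:
            if p.region == "nose":
                continue
            c = centers[0] if p.region == "right_eye" else centers[1]
            d = np.linalg.norm(np.asarray(p.coords) - c)
            assert d == pytest.approx(head_params.eye_radius, abs=1e-9)

    def test_points_close_to_admissible_elements(self, head_mesh,
                                                 head_params):
        pts = default_observation_points(head_mesh)
        entries = locate_observation_elements(head_mesh, pts)
        cents = head_mesh.tet_centroids()
        h = head_params.target_edge_length
        for p, (els, w) in zip(pts, entries):
            d = np.linalg.norm(cents[els[0]] - np.asarray(p.coords))
            assert d <= 2.0 * h
            assert w.sum() == pytest.approx(1.0)

    def test_box_mesh_rejected(self, small_box):
        from ocufield.evaluation import EvaluationError
        with pytest.raises(EvaluationError):
            default_observation_points(small_box[0])


class TestProfileSampling:
    def test_zero_field_gives_zero_profile(self, head_mesh):
        pts = default_observation_points(head_mesh)
        els = locate_observation_elements(head_mesh, pts)
        zero = CombinedField(inphase=np.zeros((head_mesh.n_tets, 3)),
                             quadrature=np.zeros((head_mesh.n_tets, 3)))
        prof = sample_norm_profile(zero, pts, els)
        assert np.all(prof.values == 0.0)

    def test_profiles_are_nonnegative(self, step1_report):
        assert (step1_report.profiles["norm_V_per_m"] >= 0).all()

    def test_right_side_single_pair_stimulates_right_eye(self, step1_report):
        # temporal right-side placement: argmax on the right eye, left eye
        # uniformly low
        prof = step1_report.raw_profiles[("electrode_4", "same-1mA")]
        right = prof.eye_values("right_eye")
        left = prof.eye_values("left_eye")
        assert right.max() > 3 * left.max()
        full = prof.values
        assert prof.point_ids[np.argmax(full)] <= 7


class TestProfileAlgebra:
    def test_self_difference_is_zero(self):
        p = profile(np.linspace(0, 1, 15))
        d = compare_profiles(p, p)
        assert np.all(d.values == 0.0)

    def test_antisymmetric_under_swap(self, rng):
        a = profile(rng.uniform(0, 5, 15))
        b = profile(rng.uniform(0, 5, 15))
        assert np.array_equal(compare_profiles(a, b).values,
                              -compare_profiles(b, a).values)

    def test_ordering_mismatch_rejected(self):
        a = profile(np.ones(15))
        b = profile(np.ones(15))
        b.point_ids = b.point_ids[::-1].copy()
        with pytest.raises(ValueError):
            compare_profiles(a, b)

    def test_doubled_minus_single_equals_single(self, step1_report):
        # linearity: the (2 mA - 1 mA) difference is the 1 mA profile
        p1 = step1_report.raw_profiles[("electrode_7", "same-1mA")]
        p2 = step1_report.raw_profiles[("electrode_7", "same-2mA")]
        d = compare_profiles(p2, p1)
        assert np.allclose(d.values, p1.values, rtol=1e-9)

    def test_sum_profiles_adds_pointwise(self, rng):
        a = profile(rng.uniform(0, 5, 15))
        b = profile(rng.uniform(0, 5, 15))
        s = sum_profiles([a, b])
        assert np.array_equal(s.values, a.values + b.values)


class TestPeakFinding:
    def test_monotone_increasing_arc_peaks_at_temporal_end(self):
        p = arc_profile(right=[1, 2, 3, 4, 5, 6, 7], nose=0,
                        left_nasal_to_temporal=[1, 2, 3, 4, 5, 6, 7])
        rep = find_peaks(p)
        assert rep.peak_ids("right_eye") == [1]      # id 1 = temporal end
        assert rep.peak_ids("left_eye") == [15]

    def test_interior_peak_detected(self):
        p = arc_profile(right=[1, 2, 5, 2, 1, 1, 1], nose=0,
                        left_nasal_to_temporal=[0, 1, 0, 0, 0, 2, 1])
        rep = find_peaks(p)
        # right: third from nasal (id 5); left: peaks at id 10 and id 14
        assert rep.peak_ids("right_eye") == [5]
        assert rep.peak_ids("left_eye") == [10, 14]

    def test_plateau_tie_resolves_toward_temporal(self):
        p = arc_profile(right=[1, 3, 3, 3, 1, 1, 1], nose=0,
                        left_nasal_to_temporal=[1, 1, 1, 1, 1, 1, 1])
        rep = find_peaks(p)
        peaks = rep.peaks["right_eye"]
        assert len(peaks) == 1
        pid, _, _, tie = peaks[0]
        assert pid == 4 and tie          # temporal end of the plateau
        # an all-flat eye is one giant plateau, flagged as a tie
        left = rep.peaks["left_eye"]
        assert len(left) == 1 and left[0][3]

    def test_mirror_montages_have_mirror_peaks(self, step1_report):
        # placements 4 and 1 are left/right mirrors on a statistically
        # symmetric head: their strongest peaks mirror (id k <-> 16-k)
        p4 = find_peaks(step1_report.raw_profiles[("electrode_4", "same-1mA")])
        p1 = find_peaks(step1_report.raw_profiles[("electrode_1", "same-1mA")])
        id4 = p4.argmax("right_eye")[0]
        id1 = p1.argmax("left_eye")[0]
        assert id1 == 16 - id4


class TestStudyStructure:
    def test_step1_has_all_condition_combinations(self, step1_report):
        assert len(step1_report.raw_profiles) == 15 * 2 * 2
        assert step1_report.summary["n_profiles"] == 60

    def test_step1_peak_invariance_under_current(self, step1_report):
        assert all(r["peaks_invariant_1_vs_2_mA"]
                   for r in step1_report.summary["peak_invariance"])

    def test_step2_interference_scores_finite(self, step2_report):
        for row in step2_report.summary["classification"]:
            assert np.isfinite(row["interference_score"])
            assert row["interference_score"] >= 0

    def test_step2_composed_interference_below_step1_worst(
            self, step1_report, step2_report):
        # the intended-region placements are farther apart, so same-phase
        # composed interference is weaker than the sweep's worst case
        d1 = step1_report.differences
        d2 = step2_report.differences
        worst1 = d1[(d1.kind == "composed")
                    & (d1.phase == "same")].difference.abs().max()
        worst2 = d2[(d2.kind == "composed")
                    & (d2.phase == "same")].difference.abs().max()
        assert worst2 < worst1

    def test_mitigation_recommendation_table_has_five_rows(
            self, mitigation_report):
        recs = mitigation_report.summary["recommendations"]
        assert len(recs) == 5
        assert {r["presentation"] for r in recs} == {
            "right/left direction", "right/center direction",
            "center/left direction"}

    def test_study_reports_embed_mesh_hash(self, step1_report, head_mesh):
        assert step1_report.summary["mesh_hash"] == head_mesh.content_hash()
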