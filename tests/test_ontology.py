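"""Weak-label derivation: step/phase/time tracks, gap rules, file round trips."""

import numpy as np
import pytest

from weaksurg.ontology import (
    UNLABELED,
    AnnotationError,
    Ontology,
    StepSegment,
    VideoAnnotation,
    derive_phase_track,
    derive_step_track,
    derive_time_track,
    read_annotations,
    read_ontology,
    read_track,
    write_annotations,
    write_ontology,
    write_track,
)


def brute_force_step_labels(segments, duration_s, fps):
    """Independent oracle: per-frame membership check against every segment."""
    n = int(duration_s * fps)
    out = []
    for t in range(n):
        time = t / fps
        lab = UNLABELED
        for s in segments:
            if s.start_s <= time < s.end_s:
                lab = s.step_label
        out.append(lab)
    return out


class TestStepTrack:
    def test_full_cover_single_segment(self, make_segments):
        track = derive_step_track(make_segments((0, 30, "a1")), 30, fps=1)
        assert track.labels == ["a1"] * 30

    def test_gap_between_segments_matches_bruteforce(self, make_segments):
        segments = make_segments((0, 10, "a1"), (20, 30, "a2"))
        track = derive_step_track(segments, 30, fps=1)
        assert track.labels == brute_force_step_labels(segments, 30, 1)
        assert track.labels[:10] == ["a1"] * 10
        assert track.labels[10:20] == [UNLABELED] * 10
        assert track.labels[20:] == ["a2"] * 10

    def test_empty_segment_list_all_unlabeled(self):
        track = derive_step_track([], 5, fps=1)
        assert track.labels == [UNLABELED] * 5

    @pytest.mark.parametrize("fps", [1.0, 2.0, 0.5])
    def test_fractional_boundaries_match_bruteforce(self, make_segments, fps):
        segments = make_segments((0.5, 10.25, "a1"), (10.25, 17.8, "a2"),
                                 (21.0, 29.9, "a3"))
        track = derive_step_track(segments, 30, fps=fps)
        assert track.labels == brute_force_step_labels(segments, 30, fps)
        assert track.n_frames == int(30 * fps)

    def test_overlap_rejected_with_pair_named(self, make_segments):
        segments = make_segments((0, 10, "a1"), (5, 15, "a2"))
        with pytest.raises(AnnotationError, match="overlap") as err:
            derive_step_track(segments, 20)
        assert "a1" in str(err.value) and "a2" in str(err.value)

    def test_shared_boundary_is_not_overlap(self, make_segments):
        segments = make_segments((0, 10, "a1"), (10, 20, "a2"))
        track = derive_step_track(segments, 20)
        assert track.labels[9] == "a1" and track.labels[10] == "a2"

    def test_segment_past_duration_rejected(self, make_segments):
        with pytest.raises(AnnotationError, match="duration"):
            derive_step_track(make_segments((0, 25, "a1")), 20)

    def test_invalid_segment_rejected_at_construction(self):
        with pytest.raises(AnnotationError, match="start >= end"):
            StepSegment("v0", 10, 10, "a1")
        with pytest.raises(AnnotationError):
            StepSegment("v0", -1, 5, "a1")


class TestPhaseTrack:
    def test_same_phase_gap_filled_with_that_phase(self, toy_ontology, make_segments):
        # a1 and a2 both map to P: the gap belongs to P
        segments = make_segments((0, 10, "a1"), (15, 25, "a2"))
        track = derive_phase_track(segments, toy_ontology, "proc_a", 25)
        assert track.labels[10:15] == ["P"] * 5

    def test_cross_phase_gap_backfilled_with_earlier_phase(self, toy_ontology, make_segments):
        # a1 -> P, a3 -> Q: the gap takes the phase of the first step
        segments = make_segments((0, 10, "a1"), (15, 25, "a3"))
        track = derive_phase_track(segments, toy_ontology, "proc_a", 25)
        assert track.labels[10:15] == ["P"] * 5
        assert track.labels[15:25] == ["Q"] * 10

    def test_single_step_spanning_video_constant_phase(self, toy_ontology, make_segments):
        track = derive_phase_track(make_segments((0, 12, "a3")), toy_ontology,
                                   "proc_a", 12)
        assert track.labels == ["Q"] * 12

    def test_outside_annotated_span_unlabeled(self, toy_ontology, make_segments):
        segments = make_segments((5, 10, "a1"), (10, 20, "a2"))
        track = derive_phase_track(segments, toy_ontology, "proc_a", 30)
        assert track.labels[:5] == [UNLABELED] * 5
        assert track.labels[20:] == [UNLABELED] * 10

    def test_unknown_step_rejected_naming_label(self, toy_ontology, make_segments):
        with pytest.raises(AnnotationError, match="zz"):
            derive_phase_track(make_segments((0, 5, "zz")), toy_ontology,
                               "proc_a", 5)

    def test_gap_closure_and_consistency_on_random_inputs(self, toy_ontology):
        """No UNLABELED inside the annotated span; labeled steps map to their phase."""
        rng = np.random.default_rng(11)
        steps = toy_ontology.steps["proc_a"]
        for _ in range(300):
            t, segments = 0.0, []
            for k in range(rng.integers(1, 6)):
                t += rng.exponential(3.0) if rng.random() < 0.5 else 0.0
                dur = 1.0 + rng.exponential(5.0)
                segments.append(
                    StepSegment("v", t, t + dur, steps[rng.integers(len(steps))])
                )
                t += dur
            duration = t + rng.exponential(2.0)
            phase = derive_phase_track(segments, toy_ontology, "proc_a", duration)
            step = derive_step_track(segments, duration)
            first = int(np.ceil(segments[0].start_s))
            last_covered = [i for i, lab in enumerate(step.labels) if lab != UNLABELED]
            if last_covered:
                span = phase.labels[first:last_covered[-1] + 1]
                assert UNLABELED not in span
            for s_lab, p_lab in zip(step.labels, phase.labels):
                if s_lab != UNLABELED:
                    assert p_lab == toy_ontology.phase_of("proc_a", s_lab)
            # determinism
            again = derive_phase_track(segments, toy_ontology, "proc_a", duration)
            assert again.labels == phase.labels


class TestTimeTrack:
    def test_ten_equal_bins_closed_form(self):
        track = derive_time_track(100, fps=1, n_bins=10)
        for t, lab in enumerate(track.labels):
            assert lab == str(t // 10)
        counts = np.unique(track.labels, return_counts=True)[1]
        assert set(counts) == {10}

    def test_single_bin(self):
        assert derive_time_track(17, n_bins=1).labels == ["0"] * 17

    def test_default_is_ten_bins(self):
        track = derive_time_track(200)
        assert len(set(track.labels)) == 10

    @pytest.mark.parametrize("duration,fps,n_bins", [
        (97, 1.0, 10), (53, 2.0, 10), (31, 1.0, 7), (10, 1.0, 10), (9, 1.0, 10),
    ])
    def test_bins_balanced_monotone_never_unlabeled(self, duration, fps, n_bins):
        track = derive_time_track(duration, fps, n_bins)
        labels = [int(x) for x in track.labels]
        assert labels == sorted(labels)
        assert max(labels) <= n_bins - 1
        assert UNLABELED not in track.labels
        counts = np.bincount(labels, minlength=n_bins)
        present = counts[counts > 0]
        assert present.max() - present.min() <= 1

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(AnnotationError):
            derive_time_track(0)


class TestFileIO:
    def test_annotation_round_trip(self, tmp_path, make_segments):
        videos = [
            VideoAnnotation("v1", "proc_a", make_segments((0, 10.5, "a1"),
                                                          (12.25, 20, "a3"),
                                                          video_id="v1")),
            VideoAnnotation("v2", "proc_b", make_segments((3, 9, "b1"),
                                                          video_id="v2")),
        ]
        path = tmp_path / "ann.csv"
        write_annotations(videos, path)
        back = read_annotations(path)
        assert set(back) == {"v1", "v2"}
        assert back["v1"].procedure == "proc_a"
        assert back["v1"].segments == videos[0].segments
        assert back["v2"].segments == videos[1].segments

    def test_empty_annotation_file(self, tmp_path):
        path = tmp_path / "ann.csv"
        write_annotations([], path)
        assert read_annotations(path) == {}

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("video_id,procedure,start_s,end_s,step\n"
                        "v1,proc_a,10,5,a1\n")
        with pytest.raises(AnnotationError, match=r"bad\.csv:2"):
            read_annotations(path)

    def test_ontology_round_trip(self, tmp_path, toy_ontology):
        path = tmp_path / "ont.yaml"
        write_ontology(toy_ontology, path)
        back = read_ontology(path)
        assert back.steps == toy_ontology.steps
        assert back.step_to_phase == toy_ontology.step_to_phase
        assert back.phases("proc_a") == ["P", "Q"]

    def test_track_round_trip(self, tmp_path, make_segments):
        track = derive_step_track(make_segments((0, 4, "a1"), (6, 9, "a2")), 10)
        path = tmp_path / "track.csv"
        write_track(track, path)
        back = read_track(path, "step")
        assert back.labels == track.labels
        assert back.video_id == track.video_id

    def test_ontology_missing_mapping_rejected(self):
        with pytest.raises(AnnotationError, match="lack a phase"):
            Ontology(steps={"p": ["s1"]}, step_to_phase={"p": {}})
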