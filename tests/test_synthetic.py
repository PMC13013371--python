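"""Synthetic corpus: workflow structure, rendering latents, learnability."""

import dataclasses

import numpy as np
import pytest

from weaksurg.ontology import UNLABELED, derive_phase_track, derive_step_track, read_annotations, read_ontology
from weaksurg.synthetic import (
    CorpusSpec,
    ProcedureSpec,
    default_corpus_spec,
    export_corpus,
    generate_corpus,
    render_frame,
    render_video,
)


class TestWorkflowGeneration:
    def test_default_spec_structure(self):
        corpus = generate_corpus(default_corpus_spec(0))
        assert corpus.procedure_names == ["slg", "hys", "cho", "rpy"]
        counts = {p: len(corpus.videos_of(p)) for p in corpus.procedure_names}
        assert counts == {"slg": 24, "hys": 32, "cho": 48, "rpy": 64}
        ont = corpus.ontology
        for proc in corpus.procedure_names:
            for step in ont.steps[proc]:
                assert step in ont.step_to_phase[proc]  # many-to-one, total

    def test_videos_follow_phase_sequence(self, tiny_corpus):
        ont = tiny_corpus.ontology
        for video in tiny_corpus.videos:
            proc = video.procedure
            phases = [ont.phase_of(proc, s.step_label) for s in video.segments]
            order = {ph: i for i, ph in enumerate(ont.phases(proc))}
            assert [order[p] for p in phases] == sorted(order[p] for p in phases)

    def test_same_seed_byte_identical_annotations(self, tiny_spec, tmp_path):
        for sub in ("one", "two"):
            export_corpus(generate_corpus(tiny_spec), tmp_path / sub)
        a = (tmp_path / "one" / "annotations.csv").read_bytes()
        b = (tmp_path / "two" / "annotations.csv").read_bytes()
        assert a == b

    def test_different_seed_different_corpus(self, tiny_spec):
        c1 = generate_corpus(tiny_spec)
        c2 = generate_corpus(dataclasses.replace(tiny_spec, seed=8))
        d1 = [s.end_s for v in c1.videos for s in v.segments]
        d2 = [s.end_s for v in c2.videos for s in v.segments]
        assert d1 != d2

    def test_no_skip_no_gap_every_step_contiguous(self, tiny_spec):
        procs = tuple(
            dataclasses.replace(p, skip_prob=0.0, gap_prob=0.0)
            for p in tiny_spec.procedures
        )
        corpus = generate_corpus(dataclasses.replace(tiny_spec, procedures=procs))
        for video in corpus.videos:
            proc = next(p for p in corpus.spec.procedures if p.name == video.procedure)
            assert [s.step_label for s in video.segments] == list(proc.steps)
            for prev, cur in zip(video.segments, video.segments[1:]):
                assert cur.start_s == pytest.approx(prev.end_s)

    def test_gaps_of_both_kinds_occur(self, tiny_corpus):
        ont = tiny_corpus.ontology
        same = cross = 0
        for video in tiny_corpus.videos:
            for prev, cur in zip(video.segments, video.segments[1:]):
                if cur.start_s > prev.end_s:
                    pp = ont.phase_of(video.procedure, prev.step_label)
                    pc = ont.phase_of(video.procedure, cur.step_label)
                    same += pp == pc
                    cross += pp != pc
        assert same > 0 and cross > 0

    def test_empty_phase_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty phase"):
            ProcedureSpec(name="x", n_videos=5, phases=(), steps_by_phase={})

    def test_derived_tracks_satisfy_label_invariants(self, tiny_corpus):
        for video in tiny_corpus.videos[:6]:
            step = derive_step_track(video.segments, video.duration_s)
            phase = derive_phase_track(video.segments, tiny_corpus.ontology,
                                       video.procedure, video.duration_s)
            for s_lab, p_lab in zip(step.labels, phase.labels):
                if s_lab != UNLABELED:
                    assert p_lab == tiny_corpus.ontology.phase_of(
                        video.procedure, s_lab)


class TestRendering:
    def test_deterministic_rendering(self, tiny_corpus):
        v = tiny_corpus.videos[0]
        a = render_video(tiny_corpus, v)
        b = render_video(tiny_corpus, v)
        assert np.array_equal(a, b)

    def test_render_frame_matches_video_slice(self, tiny_corpus):
        v = tiny_corpus.videos[0]
        frames = render_video(tiny_corpus, v)
        single = render_frame(tiny_corpus, v, 3)
        assert np.array_equal(single,
                              (frames[3] * 255.0).round().astype(np.uint8))

    def test_out_of_range_frame_rejected(self, tiny_corpus):
        v = tiny_corpus.videos[0]
        with pytest.raises(IndexError):
            render_frame(tiny_corpus, v, int(v.duration_s) + 5)

    def test_zero_noise_zero_signal_frames_identical_across_steps(self, tiny_spec_factory):
        spec = tiny_spec_factory(step_signal=0.0, phase_signal=0.0,
                                 drift_signal=0.0, noise_sd=0.0,
                                 pixel_noise_sd=0.0)
        corpus = generate_corpus(spec)
        v = corpus.videos[0]
        frames = render_video(corpus, v)
        # without step/phase/drift signal every frame of a video is the same
        assert np.allclose(frames, frames[0])

    def test_sharing_coefficient_one_gives_identical_mean_renders(self):
        """With full sharing and matched step indices, the aligned steps of
        two procedures render to the same mean image once phase/drift/site
        and style components are silenced."""
        pa = ProcedureSpec(name="pa", n_videos=5, phases=("pa_P0",),
                           steps_by_phase={"pa_P0": ("pa_s0", "pa_s1")},
                           skip_prob=0.0, gap_prob=0.0, n_sites=1)
        pb = dataclasses.replace(pa, name="pb",  phases=("pb_P0",),
                                 steps_by_phase={"pb_P0": ("pb_s0", "pb_s1")})
        spec = CorpusSpec(procedures=(pa, pb), image_hw=(12, 12),
                          step_patch=5, phase_patch=6, drift_patch=7,
                          phase_signal=0.0, drift_signal=0.0,
                          site_signal=0.0, video_signal=0.0,
                          share={("pb", "pa"): 1.0}, seed=3)
        corpus = generate_corpus(spec)
        for sa, sb in zip(("pa_s0", "pa_s1"), ("pb_s0", "pb_s1")):
            assert np.allclose(corpus.step_codes["pa"][sa],
                               corpus.step_codes["pb"][sb])
        # mean over noise renders: compare noise-free pixel maps per step
        va = corpus.videos_of("pa")[0]
        vb = corpus.videos_of("pb")[0]
        sa0 = va.segments[0]
        sb0 = vb.segments[0]
        from weaksurg.synthetic import _component_sum, _to_pixels

        fa = _to_pixels(corpus, _component_sum(corpus, va))[int(sa0.start_s)]
        fb = _to_pixels(corpus, _component_sum(corpus, vb))[int(sb0.start_s)]
        assert np.allclose(fa, fb)

    def test_zero_sharing_distinct_codes(self, tiny_corpus):
        codes_a = tiny_corpus.step_codes["pa"]
        codes_b = tiny_corpus.step_codes["pb"]
        for sa in codes_a.values():
            for sb in codes_b.values():
                assert not np.allclose(sa, sb)


class TestExport:
    def test_export_reimport_round_trip(self, tiny_corpus, tmp_path):
        export_corpus(tiny_corpus, tmp_path)
        videos = read_annotations(tmp_path / "annotations.csv")
        ont = read_ontology(tmp_path / "ontology.yaml")
        assert len(videos) == len(tiny_corpus.videos)
        for v in tiny_corpus.videos:
            assert videos[v.video_id].segments == v.segments
            assert videos[v.video_id].procedure == v.procedure
        assert ont.steps == tiny_corpus.ontology.steps
        assert ont.step_to_phase == tiny_corpus.ontology.step_to_phase

    def test_frame_png_export_counts(self, tiny_spec, tmp_path):
        spec = dataclasses.replace(
            tiny_spec,
            procedures=(dataclasses.replace(tiny_spec.procedures[0], n_videos=5),),
        )
        corpus = generate_corpus(spec)
        export_corpus(corpus, tmp_path, write_frames=True)
        for video in corpus.videos:
            pngs = sorted((tmp_path / "frames" / video.video_id).glob("*.png"))
            assert len(pngs) == int(video.duration_s * spec.fps)


class TestLearnability:
    def test_step_classifier_beats_majority_and_degrades_with_signal(self, tiny_spec_factory):
        """Held-out step accuracy: well above majority at default signal,
        indistinguishable from majority at zero signal (binomial test, 5%)."""
        from scipy.stats import binomtest
        from weaksurg.pipeline import FrameStore, frame_dataset
        from weaksurg.trainer import TrainConfig, init_model, predict, train_stage

        def heldout_accuracy(scale):
            # scale multiplies every step-predictive component (step code,
            # phase code, drift); at 0 no pixel carries step information
            spec = tiny_spec_factory(step_signal=1.2 * scale,
                                     phase_signal=1.2 * scale,
                                     drift_signal=1.2 * scale, seed=13)
            corpus = generate_corpus(spec)
            store = FrameStore(corpus)
            vids = [v.video_id for v in corpus.videos_of("pa")]
            X, y = frame_dataset(store, vids, "step")
            rng = np.random.default_rng(17)
            perm = rng.permutation(len(y))
            n_tr = int(0.8 * len(y))
            tr, te = perm[:n_tr], perm[n_tr:]
            Xva, yva = X[te], y[te]  # held-out 20% doubles as val here
            cfg = TrainConfig(seed=5, max_epochs=20, patience=4)
            model = init_model("mlp-64", X.shape[1], sorted(set(y[tr])), 5)
            model, _ = train_stage(model, X[tr], y[tr], Xva, yva, cfg)
            pred, _ = predict(model, X[te])
            classes, counts = np.unique(y[te], return_counts=True)
            majority = counts.max() / counts.sum()
            return (pred == y[te]).mean(), majority, len(te)

        acc, majority, _ = heldout_accuracy(scale=1.0)
        assert acc > majority + 0.15

        acc0, majority0, n0 = heldout_accuracy(scale=0.0)
        assert acc0 <= acc  # monotone: less signal never helps
        k = int(round(acc0 * n0))
        test = binomtest(k, n0, p=majority0, alternative="greater")
        assert test.pvalue > 0.05  # not above majority at zero signal
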