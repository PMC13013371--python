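"""Generate a synthetic surgical-workflow corpus and inspect it.

The default corpus has four procedures with unequal sizes (one is a
pre-training-only donor). Here a reduced corpus is generated, one frame is
rendered, and the annotations are exported as CSV + YAML.
"""

import tempfile

from weaksurg import default_corpus_spec, export_corpus, generate_corpus, render_frame

spec = default_corpus_spec(seed=0)
corpus = generate_corpus(spec)

print("procedure  videos  steps  phases  mean frames/video")
for proc in spec.procedures:
    vids = corpus.videos_of(proc.name)
    mean_frames = sum(v.duration_s for v in vids) / len(vids)
    print(f"{proc.name:<10} {len(vids):>6} {len(proc.steps):>6} "
          f"{len(proc.phases):>7} {mean_frames:>10.0f}")

video = corpus.videos_of("slg")[0]
frame = render_frame(corpus, video, 0)
print(f"\nframe 0 of {video.video_id}: shape {frame.shape}, "
      f"dtype {frame.dtype}, range [{frame.min()}, {frame.max()}]")
print(f"ground-truth segments: {len(video.segments)} "
      f"(first: {video.segments[0].step_label} "
      f"[{video.segments[0].start_s:.0f}, {video.segments[0].end_s:.0f}) s)")

with tempfile.TemporaryDirectory() as out:
    export_corpus(corpus, out)
    print(f"\nexported annotations.csv + ontology.yaml to {out}")

# The video counts mirror a realistic multi-procedure corpus: small and
# mid-sized evaluation targets plus a large donor procedure used only for
# cross-procedure step pre-training.
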