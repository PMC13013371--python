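"""Derive per-frame weak labels from step annotations.

Builds a small annotated video by hand, then derives the three label
tracks: steps (with unlabeled gaps), phases (gaps closed by the same-phase
and back-fill rules), and 10-bin elapsed time.
"""

from weaksurg import (
    Ontology,
    StepSegment,
    derive_phase_track,
    derive_step_track,
    derive_time_track,
)

ontology = Ontology(
    steps={"demo": ["expose", "dissect", "clip", "extract"]},
    step_to_phase={"demo": {"expose": "access", "dissect": "resection",
                            "clip": "resection", "extract": "closure"}},
)

# four steps, with a same-phase gap (dissect->clip) and a cross-phase gap
# (clip->extract); seconds
segments = [
    StepSegment("case01", 0, 30, "expose"),
    StepSegment("case01", 35, 70, "dissect"),
    StepSegment("case01", 80, 100, "clip"),
    StepSegment("case01", 110, 140, "extract"),
]
duration = 150

step = derive_step_track(segments, duration)
phase = derive_phase_track(segments, ontology, "demo", duration)
time = derive_time_track(duration, n_bins=10, video_id="case01")

print("frame  step        phase      time-bin")
for t in range(0, duration, 15):
    print(f"{t:5d}  {step.labels[t]:<11} {phase.labels[t]:<10} {time.labels[t]}")

# What to look for: frames 70-79 (gap between two resection steps) carry
# the phase 'resection' (same-phase rule); frames 100-109 (gap between
# resection and closure) are back-filled with 'resection', the phase of the
# earlier step; frames past 140 are unlabeled in step and phase tracks but
# still carry a time bin, which needs no annotation at all.
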