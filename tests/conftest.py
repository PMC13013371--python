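import dataclasses

import pytest

from weaksurg.ontology import Ontology, StepSegment
from weaksurg.synthetic import CorpusSpec, ProcedureSpec, generate_corpus


@pytest.fixture
def toy_ontology() -> Ontology:
    """Two procedures; proc_a has 4 steps in 2 phases, proc_b has 2 steps."""
    return Ontology(
        steps={
            "proc_a": ["a1", "a2", "a3", "a4"],
            "proc_b": ["b1", "b2"],
        },
        step_to_phase={
            "proc_a": {"a1": "P", "a2": "P", "a3": "Q", "a4": "Q"},
            "proc_b": {"b1": "R", "b2": "R"},
        },
    )


def segs(*triples, video_id="v0"):
    """Shorthand: segs((0, 10, 'a1'), ...) -> [StepSegment, ...]."""
    return [StepSegment(video_id, a, b, lab) for a, b, lab in triples]


@pytest.fixture
def make_segments():
    return segs


def tiny_procedure(name: str, n_videos: int = 6,
                   steps_per_phase=(2, 2)) -> ProcedureSpec:
    phases = tuple(f"{name}_P{i}" for i in range(len(steps_per_phase)))
    steps_by_phase = {}
    k = 0
    for ph, cnt in zip(phases, steps_per_phase):
        steps_by_phase[ph] = tuple(f"{name}_s{k + j}" for j in range(cnt))
        k += cnt
    return ProcedureSpec(
        name=name, n_videos=n_videos, phases=phases,
        steps_by_phase=steps_by_phase,
        mu_log_duration=2.3, sigma_log_duration=0.3,  # ~10 s steps
        skip_prob=0.1, gap_prob=0.4, mean_gap_s=4.0, n_sites=2,
    )


@pytest.fixture
def tiny_spec() -> CorpusSpec:
    """Small, fast corpus: 2 procedures, 12x12 frames, short videos."""
    return CorpusSpec(
        procedures=(tiny_procedure("pa"), tiny_procedure("pb")),
        image_hw=(12, 12),
        step_patch=5, phase_patch=6, drift_patch=7,
        seed=7,
    )


@pytest.fixture
def tiny_corpus(tiny_spec):
    return generate_corpus(tiny_spec)


@pytest.fixture
def tiny_spec_factory():
    def factory(**over):
        base = CorpusSpec(
            procedures=(tiny_procedure("pa"), tiny_procedure("pb")),
            image_hw=(12, 12),
            step_patch=5, phase_patch=6, drift_patch=7,
            seed=7,
        )
        return dataclasses.replace(base, **over)

    return factory
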