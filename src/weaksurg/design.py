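"""Annotation-scarcity simulation and weak-supervision scenario enumeration.

The benchmark simulates scarce step annotations: per target procedure, 20%
of videos are held out once as a test set; from the remaining pool a
fraction alpha of videos is treated as step-labeled, over a grid
alpha in {0.25, 0.5, 0.75, 1.0}, repeated over five random splits ("seeds").
Within a labeled subset, 70% of videos train and 30% validate. Subsampling
is always at the video level — a video never straddles train/val/test.

Weak pre-training scenarios pair a source dataset with a cheap label type:

============  ==========  ================  ==================
Scenario      Label type  Source            Manual annotation?
============  ==========  ================  ==================
Phase-Within  phase       same procedure    yes
Phase-All     phase       all targets       yes
Step-RPY      step        donor procedure   yes
Time-Within   time        same procedure    no
Time-All      time        all targets       no
Baseline      --          no pre-training   --
============  ==========  ================  ==================

Phase-All, Time-All and Step-RPY each yield one shared pre-trained model;
Phase-Within and Time-Within yield one per target procedure — 9 models for
3 targets. Weak labels are available for the entire source dataset; only
step labels of the target are scarce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .random_utils import substream

DEFAULT_ALPHAS = (0.25, 0.5, 0.75, 1.0)

#: the scarce-label operating grid never includes 0: alpha is a fraction of
#: the pool that *is* labeled, and an empty labeled set is not a condition
WEAK_SCENARIOS = ("Phase-Within", "Phase-All", "Time-Within", "Time-All", "Step-RPY")
BASELINE = "Baseline"


@dataclass(frozen=True)
class ScenarioSpec:
    """One weak dataset-label pair, or the no-pre-training baseline."""

    name: str
    label_type: str | None          # "phase" | "time" | "step" | None
    source: str                     # "within" | "all" | "donor" | "none"
    requires_manual_annotation: bool

    @property
    def is_baseline(self) -> bool:
        return self.source == "none"

    @property
    def is_shared(self) -> bool:
        """Shared scenarios pre-train one model reused for every target."""
        return self.source in ("all", "donor")


_SCENARIOS: dict[str, ScenarioSpec] = {
    "Phase-Within": ScenarioSpec("Phase-Within", "phase", "within", True),
    "Phase-All": ScenarioSpec("Phase-All", "phase", "all", True),
    "Step-RPY": ScenarioSpec("Step-RPY", "step", "donor", True),
    "Time-Within": ScenarioSpec("Time-Within", "time", "within", False),
    "Time-All": ScenarioSpec("Time-All", "time", "all", False),
    BASELINE: ScenarioSpec(BASELINE, None, "none", False),
}


def scenario(name: str) -> ScenarioSpec:
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; known: {sorted(_SCENARIOS)}"
        ) from None


def all_scenarios(include_baseline: bool = True) -> list[ScenarioSpec]:
    names = WEAK_SCENARIOS + ((BASELINE,) if include_baseline else ())
    return [_SCENARIOS[n] for n in names]


@dataclass
class SeedSplit:
    """Per-split labeled subsets (nested over alpha) and train/val roles."""

    seed: int
    labeled: dict[float, list[str]]          # alpha -> video ids, nested
    train: dict[float, list[str]]            # alpha -> 70% of labeled
    val: dict[float, list[str]]              # alpha -> 30% of labeled


@dataclass
class SplitPlan:
    """Test holdout plus per-seed alpha-nested labeled subsets."""

    procedure: str
    test_ids: list[str]
    pool_ids: list[str]
    seeds: list[SeedSplit]
    alphas: tuple[float, ...]

    @property
    def n_train(self) -> int:
        """Size of the non-test pool (the N_train of the NNL formula)."""
        return len(self.pool_ids)

    def to_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "test_ids": self.test_ids,
            "pool_ids": self.pool_ids,
            "alphas": list(self.alphas),
            "seeds": [
                {
                    "seed": s.seed,
                    "labeled": {str(a): ids for a, ids in s.labeled.items()},
                    "train": {str(a): ids for a, ids in s.train.items()},
                    "val": {str(a): ids for a, ids in s.val.items()},
                }
                for s in self.seeds
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SplitPlan":
        return cls(
            procedure=d["procedure"],
            test_ids=list(d["test_ids"]),
            pool_ids=list(d["pool_ids"]),
            alphas=tuple(float(a) for a in d["alphas"]),
            seeds=[
                SeedSplit(
                    seed=int(s["seed"]),
                    labeled={float(a): list(v) for a, v in s["labeled"].items()},
                    train={float(a): list(v) for a, v in s["train"].items()},
                    val={float(a): list(v) for a, v in s["val"].items()},
                )
                for s in d["seeds"]
            ],
        )


def labeled_count(alpha: float, n_train: int) -> int:
    """Number of labeled videos at a given alpha: round(alpha*N) ties-to-even.

    alpha = 1.0 always labels the entire pool.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if alpha == 1.0:
        return n_train
    return round(alpha * n_train)


def make_split_plan(
    video_ids: Sequence[str],
    procedure: str,
    master_seed: int,
    seed_count: int = 5,
    test_frac: float = 0.2,
    alphas: Iterable[float] = DEFAULT_ALPHAS,
    train_frac: float = 0.7,
) -> SplitPlan:
    """Build the full scarcity-simulation plan for one procedure.

    The test holdout is drawn once (shared by all seeds, so paired
    comparisons across scenarios use identical test sets); the per-seed
    labeled subsets are nested over alpha — a prefix of a per-seed
    permutation of the pool — emulating incremental annotation.
    """
    alphas = tuple(sorted(float(a) for a in alphas))
    for a in alphas:
        if not 0.0 < a <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {a}")
    video_ids = list(video_ids)
    if len(video_ids) < 5:
        raise ValueError(f"need at least 5 videos, got {len(video_ids)}")
    n = len(video_ids)
    n_train = int((1.0 - test_frac) * n)  # floor
    rng = substream(master_seed, "holdout", procedure)
    order = list(rng.permutation(video_ids))
    pool, test = order[:n_train], order[n_train:]

    seeds: list[SeedSplit] = []
    for s in range(seed_count):
        rng_s = substream(master_seed, "labeled", procedure, s)
        perm = list(rng_s.permutation(pool))
        labeled: dict[float, list[str]] = {}
        train: dict[float, list[str]] = {}
        val: dict[float, list[str]] = {}
        for a in alphas:
            k = labeled_count(a, n_train)
            subset = perm[:k]
            labeled[a] = list(subset)
            rng_tv = substream(master_seed, "trainval", procedure, s, a)
            tv = list(rng_tv.permutation(subset))
            n_tr = round(train_frac * k)
            n_tr = min(max(n_tr, 1), k - 1) if k >= 2 else k
            train[a] = tv[:n_tr]
            val[a] = tv[n_tr:]
        seeds.append(SeedSplit(seed=s, labeled=labeled, train=train, val=val))
    return SplitPlan(procedure=procedure, test_ids=test, pool_ids=pool,
                     seeds=seeds, alphas=alphas)


@dataclass(frozen=True)
class PretrainJob:
    """One weak pre-training job: scenario x (target or shared) source."""

    scenario: str
    label_type: str
    #: procedures whose videos supply pre-training frames
    source_procedures: tuple[str, ...]
    #: target procedure for within-scenarios, None for shared jobs
    target: str | None = None
    #: fraction of source videos used (pre-training-size ablation)
    source_fraction: float = 1.0
    #: fine-tuning label availability paired with this job (ablation only)
    finetune_alpha: float | None = None


def enumerate_pretrain_jobs(
    target_procedures: Sequence[str],
    scenarios: Iterable[str | ScenarioSpec] = WEAK_SCENARIOS,
    donor_procedure: str = "rpy",
) -> list[PretrainJob]:
    """Enumerate the weak pre-training jobs for a set of target procedures.

    Shared scenarios (Phase-All, Time-All, Step-RPY) contribute one job
    each; within-scenarios contribute one per target. For 3 targets and the
    five standard weak scenarios this is exactly 9 jobs.
    """
    targets = list(target_procedures)
    jobs: list[PretrainJob] = []
    for sc in scenarios:
        spec = scenario(sc) if isinstance(sc, str) else sc
        if spec.is_baseline:
            continue  # the baseline has no pre-training stage
        assert spec.label_type is not None
        if spec.source == "within":
            for t in targets:
                jobs.append(PretrainJob(spec.name, spec.label_type, (t,), target=t))
        elif spec.source == "all":
            jobs.append(PretrainJob(spec.name, spec.label_type, tuple(targets)))
        elif spec.source == "donor":
            jobs.append(PretrainJob(spec.name, spec.label_type, (donor_procedure,)))
        else:  # pragma: no cover - scenario() already validates
            raise ValueError(f"unknown source {spec.source!r}")
    return jobs


def make_pretrain_size_ablation(
    target_procedures: Sequence[str],
    fractions: Iterable[float] = DEFAULT_ALPHAS,
    alpha_fixed: float = 0.25,
    strategies: Iterable[str] = ("Phase-Within", "Phase-All"),
) -> list[PretrainJob]:
    """Pre-training-size ablation: vary the phase-labeled source fraction.

    For each target procedure and fraction, one Phase-Within and one
    Phase-All job on a nested random subset of pre-training videos, each
    paired with fine-tuning at a fixed low-resource alpha (default 0.25).
    """
    fractions = tuple(sorted(float(f) for f in fractions))
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {f}")
    jobs: list[PretrainJob] = []
    targets = list(target_procedures)
    for target in targets:
        for strat in strategies:
            spec = scenario(strat)
            assert spec.label_type is not None
            sources = (target,) if spec.source == "within" else tuple(targets)
            for f in fractions:
                jobs.append(
                    PretrainJob(spec.name, spec.label_type, sources,
                                target=target, source_fraction=f,
                                finetune_alpha=alpha_fixed)
                )
    return jobs
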