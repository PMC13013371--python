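"""End-to-end benchmark driver.

From one config and one master seed: generate the synthetic corpus, derive
weak label tracks, plan the annotation-scarcity splits, run every
pre-train/fine-tune job, score weighted F1 on the shared test holdout, and
emit the evaluation, paired-delta, NNL and ablation reports.

Jobs are cached in the run directory under content keys, so an interrupted
run resumes where it stopped and a completed run re-executed is a no-op.
Two complete runs from the same config and seed produce identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import design, stats
from .nnl import nnl_from_table, render_nnl_markdown, select_best_weak_label
from .design import (
    BASELINE,
    DEFAULT_ALPHAS,
    WEAK_SCENARIOS,
    PretrainJob,
    SplitPlan,
    enumerate_pretrain_jobs,
    make_split_plan,
    scenario,
)
from .ontology import UNLABELED, derive_phase_track, derive_step_track, derive_time_track
from .random_utils import substream, substream_seed
from .synthetic import Corpus, CorpusSpec, default_corpus_spec, generate_corpus, render_video
from .trainer import ModelRef, TrainConfig, init_model, predict, train_stage

__all__ = [
    "BenchmarkConfig",
    "RunManifest",
    "FrameStore",
    "frame_dataset",
    "run_pretrain_job",
    "finetune_and_score",
    "run_scenarios",
    "run_benchmark",
    "render_reports",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Everything a full benchmark run depends on, hash-identified."""

    master_seed: int = 0
    targets: tuple[str, ...] = ("slg", "hys", "cho")
    donor: str = "rpy"
    scenarios: tuple[str, ...] = WEAK_SCENARIOS
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    n_seeds: int = 5
    alpha0: float = 0.25
    time_bins: int = 10
    train: TrainConfig = field(default_factory=TrainConfig)
    minutes_per_case: float = 40.0
    run_ablation: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    corpus_fingerprint: str
    jobs: dict[str, dict] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)


class FrameStore:
    """Lazily rendered, flattened, centered frame features per video.

    Pixels are rendered in [0, 1] and centered at the nominal background
    level 0.5 — zero-mean inputs keep ReLU units alive through the
    pre-training stage (all-positive inputs let an easy first stage kill
    most of the trunk, destroying transfer).
    """

    def __init__(self, corpus: Corpus):
        self.corpus = corpus
        self._cache: dict[str, np.ndarray] = {}
        self._by_id = {v.video_id: v for v in corpus.videos}

    def features(self, video_id: str) -> np.ndarray:
        if video_id not in self._cache:
            video = self._by_id[video_id]
            frames = render_video(self.corpus, video) - 0.5
            self._cache[video_id] = frames.reshape(frames.shape[0], -1).astype(np.float32)
        return self._cache[video_id]

    def video(self, video_id: str):
        return self._by_id[video_id]


def _track_for(store: FrameStore, video_id: str, label_type: str, time_bins: int):
    video = store.video(video_id)
    spec = store.corpus.spec
    if label_type == "step":
        return derive_step_track(video.segments, video.duration_s, spec.fps, video_id)
    if label_type == "phase":
        return derive_phase_track(video.segments, store.corpus.ontology,
                                  video.procedure, video.duration_s, spec.fps, video_id)
    if label_type == "time":
        return derive_time_track(video.duration_s, spec.fps, time_bins, video_id)
    raise ValueError(f"unknown label type {label_type!r}")


def frame_dataset(
    store: FrameStore,
    video_ids,
    label_type: str,
    time_bins: int = 10,
    prefix_labels: bool = False,
):
    """Stack labeled frames of the given videos into (X, y) arrays.

    Frames whose track label is UNLABELED are excluded. With
    ``prefix_labels`` the video's procedure name is prefixed to each label,
    which keeps label spaces disjoint when sources from several procedures
    are pooled for pre-training (time-bin labels, by contrast, are shared
    across procedures by design).
    """
    xs, ys = [], []
    for vid in video_ids:
        X = store.features(vid)
        track = _track_for(store, vid, label_type, time_bins)
        labels = np.asarray(track.labels)
        keep = labels != UNLABELED
        if not keep.any():
            continue
        lab = labels[keep]
        if prefix_labels:
            proc = store.video(vid).procedure
            lab = np.array([f"{proc}:{x}" for x in lab])
        xs.append(X[keep])
        ys.append(lab)
    if not xs:
        raise ValueError(f"no labeled frames in videos {list(video_ids)!r}")
    return np.concatenate(xs), np.concatenate(ys)


def _video_level_split(video_ids, master_seed: int, *names, train_frac: float = 0.7):
    rng = substream(master_seed, *names)
    order = list(rng.permutation(list(video_ids)))
    k = len(order)
    n_tr = min(max(round(train_frac * k), 1), k - 1) if k >= 2 else k
    return order[:n_tr], order[n_tr:]


def run_pretrain_job(
    store: FrameStore,
    job: PretrainJob,
    config: BenchmarkConfig,
    exclude_ids: set[str] | frozenset[str] = frozenset(),
) -> ModelRef:
    """Pre-train one weak model on its full (or ablation-fraction) source.

    Weak labels are available for every non-held-out video of the source
    procedures; only target step labels are scarce in this benchmark.
    ``exclude_ids`` carries the evaluation procedures' test holdouts: no
    training stage may see an evaluation video, so weak pre-training draws
    on the non-test pool (a donor procedure that is never evaluated has no
    holdout and contributes all its videos). For fractional sources
    (ablation), a nested random subset of videos per procedure is used.
    Step labels are procedure-prefixed when sources are pooled, and phase
    labels always are (phases are procedure-specific).
    """
    corpus = store.corpus
    vids: list[str] = []
    for proc in job.source_procedures:
        ids = [v.video_id for v in corpus.videos_of(proc)
               if v.video_id not in exclude_ids]
        if job.source_fraction < 1.0:
            rng = substream(config.master_seed, "pretrain-subset", job.scenario, proc)
            perm = list(rng.permutation(ids))
            k = max(2, round(job.source_fraction * len(ids)))
            ids = perm[:k]
        vids.extend(ids)
    # phases/steps are procedure-specific vocabularies; time bins are shared
    prefix = job.label_type in ("phase", "step")
    train_ids, val_ids = _video_level_split(
        vids, config.master_seed, "pretrain-val", job.scenario,
        job.target or "shared", job.source_fraction,
    )
    Xtr, ytr = frame_dataset(store, train_ids, job.label_type,
                             config.time_bins, prefix_labels=prefix)
    Xva, yva = frame_dataset(store, val_ids, job.label_type,
                             config.time_bins, prefix_labels=prefix)
    classes = sorted(np.unique(ytr).tolist())
    tc = _stage_config(config, "pretrain", job.scenario, job.target,
                       job.source_fraction)
    model = init_model(config.train.backbone, Xtr.shape[1], classes, tc.seed)
    model, _ = train_stage(model, Xtr, ytr, Xva, yva, tc, stage="pretrain")
    return model


def _stage_config(config: BenchmarkConfig, *names) -> TrainConfig:
    """Per-stage TrainConfig whose seed is a named substream of the master."""
    return dataclasses.replace(
        config.train, seed=substream_seed(config.master_seed, "train", *names)
    )


def finetune_and_score(
    store: FrameStore,
    plan: SplitPlan,
    target: str,
    alpha: float,
    seed: int,
    config: BenchmarkConfig,
    pretrained: ModelRef | None,
    scenario_name: str,
) -> float:
    """Fine-tune on the alpha-limited step labels and score test weighted F1.

    The baseline passes ``pretrained=None``: a fresh (seeded) initialization
    is fine-tuned directly. Pre-trained models keep their trunk and get a
    re-initialized step head; all weights train.
    """
    split = plan.seeds[seed]
    Xtr, ytr = frame_dataset(store, split.train[alpha], "step", config.time_bins)
    Xva, yva = frame_dataset(store, split.val[alpha], "step", config.time_bins)
    tc = _stage_config(config, "finetune", scenario_name, target, alpha, seed)
    if pretrained is None:
        classes = sorted(np.unique(ytr).tolist())
        model = init_model(config.train.backbone, Xtr.shape[1], classes, tc.seed)
    else:
        model = pretrained
    model, _ = train_stage(model, Xtr, ytr, Xva, yva, tc, stage="finetune")
    Xte, yte = frame_dataset(store, plan.test_ids, "step", config.time_bins)
    pred, _ = predict(model, Xte)
    return stats.weighted_f1(yte, pred)


def run_scenarios(
    store: FrameStore,
    config: BenchmarkConfig,
    targets=None,
    scenarios=None,
    alphas=None,
    cache: dict | None = None,
) -> stats.EvalTable:
    """Run Baseline + requested scenarios over the alpha x seed grid.

    ``cache`` maps row keys to already-computed F1s (resume support); it is
    updated in place.
    """
    targets = list(targets if targets is not None else config.targets)
    scenario_names = list(scenarios if scenarios is not None else
                          (BASELINE,) + tuple(config.scenarios))
    alphas = tuple(alphas if alphas is not None else config.alphas)
    cache = cache if cache is not None else {}

    plans = {
        t: make_split_plan(
            [v.video_id for v in store.corpus.videos_of(t)], t,
            config.master_seed, seed_count=config.n_seeds, alphas=alphas,
        )
        for t in targets
    }
    jobs = enumerate_pretrain_jobs(
        targets, [s for s in scenario_names if s != BASELINE], config.donor
    )
    held_out = frozenset(
        vid for plan in plans.values() for vid in plan.test_ids
    )
    models: dict[tuple[str, str | None], ModelRef] = {}
    records = []
    for target in targets:
        for name in scenario_names:
            spec = scenario(name)
            pretrained = None
            if not spec.is_baseline:
                key = (name, None if spec.is_shared else target)
                if key not in models:
                    job = next(
                        j for j in jobs
                        if j.scenario == name and (j.target == key[1])
                    )
                    models[key] = run_pretrain_job(store, job, config,
                                                   exclude_ids=held_out)
                pretrained = models[key]
            for alpha in alphas:
                for seed in range(config.n_seeds):
                    row_key = (target, name, float(alpha), seed)
                    if row_key not in cache:
                        cache[row_key] = finetune_and_score(
                            store, plans[target], target, float(alpha), seed,
                            config, pretrained, name,
                        )
                    records.append({
                        "procedure": target, "scenario": name,
                        "alpha": float(alpha), "seed": seed,
                        "weighted_f1": cache[row_key],
                    })
    return stats.EvalTable(pd.DataFrame.from_records(records))


def run_ablation(
    store: FrameStore,
    config: BenchmarkConfig,
    fractions=(0.25, 0.5, 0.75, 1.0),
    strategies=("Phase-Within", "Phase-All"),
) -> pd.DataFrame:
    """Pre-training-size ablation at a fixed low-resource fine-tune point.

    For each target and phase strategy, pre-train on a nested fraction of
    the phase-labeled source videos and fine-tune at alpha = alpha0 over
    all seeds; returns mean test F1 per (target, strategy, fraction).
    """
    targets = list(config.targets)
    jobs = design.make_pretrain_size_ablation(
        targets, fractions, config.alpha0, strategies
    )
    plans = {
        t: make_split_plan(
            [v.video_id for v in store.corpus.videos_of(t)], t,
            config.master_seed, seed_count=config.n_seeds, alphas=config.alphas,
        )
        for t in targets
    }
    held_out = frozenset(v for p in plans.values() for v in p.test_ids)
    rows = []
    shared_models: dict[tuple, ModelRef] = {}
    for job in jobs:
        key = (job.scenario, job.source_procedures, job.source_fraction)
        if key not in shared_models:
            shared_models[key] = run_pretrain_job(store, job, config,
                                                  exclude_ids=held_out)
        model = shared_models[key]
        assert job.target is not None and job.finetune_alpha is not None
        for seed in range(config.n_seeds):
            f1 = finetune_and_score(
                store, plans[job.target], job.target, job.finetune_alpha,
                seed, config, model, f"{job.scenario}@{job.source_fraction}",
            )
            rows.append({
                "procedure": job.target, "strategy": job.scenario,
                "source_fraction": job.source_fraction, "seed": seed,
                "weighted_f1": f1,
            })
    return pd.DataFrame(rows)


def _corpus_fingerprint(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for v in corpus.videos:
        h.update(v.video_id.encode())
        for s in v.segments:
            h.update(f"{s.start_s:.6f},{s.end_s:.6f},{s.step_label}".encode())
    return h.hexdigest()[:16]


def _row_key_str(key: tuple) -> str:
    return "|".join(str(k) for k in key)


def run_benchmark(
    config: BenchmarkConfig,
    out_dir,
    corpus_spec: CorpusSpec | None = None,
    dry_run: bool = False,
) -> RunManifest:
    """Execute (or resume) the full benchmark and write all reports.

    With ``dry_run`` the job plan is recorded in the manifest and nothing
    trains. Completed fine-tune cells are read back from the run directory
    and never recomputed.
    """
    os.makedirs(out_dir, exist_ok=True)
    spec = corpus_spec if corpus_spec is not None else default_corpus_spec(config.master_seed)
    corpus = generate_corpus(spec)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        master_seed=config.master_seed,
        corpus_fingerprint=_corpus_fingerprint(corpus),
    )
    jobs = enumerate_pretrain_jobs(list(config.targets), list(config.scenarios),
                                   config.donor)
    n_cells = (len(config.targets) * (len(config.scenarios) + 1)
               * len(config.alphas) * config.n_seeds)
    for j in jobs:
        manifest.jobs[f"pretrain:{j.scenario}:{j.target or 'shared'}"] = {
            "status": "planned", "label_type": j.label_type,
            "sources": list(j.source_procedures),
        }
    manifest.jobs["finetune-grid"] = {"status": "planned", "cells": n_cells}
    manifest_path = os.path.join(out_dir, "manifest.json")
    if dry_run:
        manifest.save(manifest_path)
        return manifest

    cache_path = os.path.join(out_dir, "cells.json")
    cache: dict[tuple, float] = {}
    if os.path.exists(cache_path):
        with open(cache_path, encoding="utf-8") as fh:
            raw = json.load(fh)
        for k, v in raw.items():
            t, s, a, sd = k.split("|")
            cache[(t, s, float(a), int(sd))] = v

    store = FrameStore(corpus)
    table = run_scenarios(store, config, cache=cache)
    with open(cache_path, "w", encoding="utf-8") as fh:
        json.dump({_row_key_str(k): v for k, v in cache.items()}, fh, indent=0)
    for key in manifest.jobs:
        manifest.jobs[key]["status"] = "done"

    table.to_csv(os.path.join(out_dir, "eval_table.csv"))
    manifest.artifacts["eval_table"] = "eval_table.csv"
    if config.run_ablation:
        ablation = run_ablation(store, config)
        ablation.to_csv(os.path.join(out_dir, "ablation_table.csv"), index=False)
        manifest.artifacts["ablation_table"] = "ablation_table.csv"
    n_train_by_proc = {
        t: make_split_plan(
            [v.video_id for v in corpus.videos_of(t)], t,
            config.master_seed, seed_count=config.n_seeds,
            alphas=config.alphas,
        ).n_train
        for t in config.targets
    }
    render_reports(table, config, out_dir, n_train_by_proc, manifest)
    manifest.save(manifest_path)
    return manifest


def render_reports(
    table: stats.EvalTable,
    config: BenchmarkConfig,
    out_dir,
    n_train_by_proc: dict[str, int],
    manifest: RunManifest | None = None,
) -> dict[str, pd.DataFrame]:
    """Write the delta, NNL and learning-curve reports from an EvalTable."""
    if table.df.empty:
        raise ValueError("empty evaluation table; nothing to report")
    targets = list(dict.fromkeys(table.df["procedure"]))
    scen_present = [s for s in table.df["scenario"].unique() if s != BASELINE]

    deltas = stats.delta_table(table, targets, scen_present, config.alpha0)
    deltas.to_csv(os.path.join(out_dir, "delta_table.csv"), index=False)
    with open(os.path.join(out_dir, "delta_table.md"), "w") as fh:
        fh.write(stats.render_delta_markdown(deltas) + "\n")

    # learning-curve data: mean F1 per (procedure, scenario, alpha) with the
    # Hypothetical-Max reference per procedure, and the y=0 baseline implied
    # in the delta panel
    curve = (table.df.groupby(["procedure", "scenario", "alpha"])["weighted_f1"]
             .mean().reset_index())
    curve["hypothetical_max"] = curve["procedure"].map(
        {t: stats.hypothetical_max(table, t) for t in targets}
    )
    curve.to_csv(os.path.join(out_dir, "learning_curves.csv"), index=False)

    nnl_rows = []
    for t in targets:
        per_scenario = {
            s: stats.paired_delta(table, t, s, config.alpha0)
            for s in scen_present
        }
        best = select_best_weak_label(per_scenario)
        res = nnl_from_table(
            table, t, best,
            n_train=n_train_by_proc[t],
            alpha0=config.alpha0,
        )
        nnl_rows.append(res)
    nnl_df = pd.DataFrame([{
        "procedure": r.procedure, "best_weak_label": r.scenario,
        "delta_f1": r.delta_f1, "n_train": r.n_train,
        "delta_alpha": r.delta_alpha, "nnl": r.nnl,
        "nnl_exact": r.nnl_exact, "estimable": r.estimable,
        "person_hours": r.hours(config.minutes_per_case) if r.estimable else None,
    } for r in nnl_rows])
    nnl_df.to_csv(os.path.join(out_dir, "nnl_table.csv"), index=False)
    with open(os.path.join(out_dir, "nnl_table.md"), "w") as fh:
        fh.write(render_nnl_markdown(nnl_rows) + "\n")

    if manifest is not None:
        manifest.artifacts.update({
            "delta_table": "delta_table.csv",
            "learning_curves": "learning_curves.csv",
            "nnl_table": "nnl_table.csv",
        })
    return {"deltas": deltas, "curves": curve, "nnl": nnl_df}
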