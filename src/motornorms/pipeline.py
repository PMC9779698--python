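"""End-to-end pipeline: simulate -> extract -> QC/aggregate -> normative ->
confounds -> score, with a manifest for reproducibility.

Identical config + seed produces identical outputs; every output file is
traceable to the manifest's config hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (QCRules, average_repetitions, build_normative_table,
                     features_to_frame, run_qc)
from .confounds import screen_parameters
from .features import FeatureConfig, extract_features
from .scoring import NormativeResource, render_report, score_subject
from .skeleton_io import PreprocessConfig, preprocess
from .synthetic import CohortSpec, render_subject_recordings
from .types import Task


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-cohort pipeline run."""

    out_dir: str = "motornorms_run"
    seed: int = 0
    n_per_study: dict[str, int] = field(
        default_factory=lambda: {"studyA": 10, "studyB": 10, "studyC": 10}
    )
    tasks: tuple[str, ...] = tuple(t.value for t in Task)
    repetitions: int = 1
    noise_sd: float = 0.0
    cv_repeats: int = 25
    cv_folds: int = 5
    gate_threshold: float = 0.1
    render_score_report: bool = True
    stages: tuple[str, ...] = (
        "simulate", "extract", "normative", "confounds", "score",
    )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    tasks = tuple(Task(t) for t in config.tasks)
    fcfg = FeatureConfig()
    pcfg = PreprocessConfig()
    rules = QCRules()

    state: dict = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                spec = CohortSpec(studies=dict(config.n_per_study),
                                  seed=config.seed)
                subjects, truths = _simulate(spec)
                state["subjects"], state["truths"] = subjects, truths
                info = {"n_subjects": len(subjects),
                        "n_parameters": truths.shape[1]}
            elif stage == "extract":
                subjects, truths = state["subjects"], state["truths"]
                per_subject, n_rec, n_discard = {}, 0, 0
                for s in subjects:
                    recs = render_subject_recordings(
                        s, truths.loc[s.subject_id], seed=config.seed,
                        tasks=tasks, repetitions=config.repetitions,
                    )
                    by_task: dict[Task, list] = {}
                    for rec in recs:
                        n_rec += 1
                        prep = preprocess(rec, pcfg)
                        verdict = run_qc(prep, rules,
                                         f"{s.subject_id}:{rec.task.value}")
                        if not verdict.passed:
                            n_discard += 1
                            continue
                        by_task.setdefault(rec.task, []).append(
                            extract_features(prep, fcfg))
                    fvs = [average_repetitions(v) for v in by_task.values()]
                    merged = {}
                    for fv in fvs:
                        merged.update(fv)
                    per_subject[s.subject_id] = type(fvs[0])(merged) if fvs else {}
                frame = features_to_frame(
                    {k: v for k, v in per_subject.items() if len(v)})
                frame.to_csv(out / "features.csv")
                state["features"] = frame
                info = {"n_recordings": n_rec, "n_discarded": n_discard,
                        "n_subjects_with_features": len(frame)}
            elif stage == "normative":
                table = build_normative_table(state["features"])
                table.to_csv(out / "normative_table.csv")
                state["normative"] = table
                info = {"n_parameters": int(table["n"].ge(2).sum())}
            elif stage == "confounds":
                report, models = screen_parameters(
                    state["subjects"], state["features"],
                    repeats=config.cv_repeats, folds=config.cv_folds,
                    seed=config.seed, threshold=config.gate_threshold,
                )
                report.to_csv(out / "cv_report.csv")
                state["models"] = models
                resource = _build_resource(state["normative"], report, models)
                resource.save(out / "normative_resource.json")
                state["resource"] = resource
                info = {"n_gated": len(models)}
            elif stage == "score":
                subjects = state["subjects"]
                features = state["features"]
                sid = features.index[0]
                subject = next(s for s in subjects if s.subject_id == sid)
                profile = score_subject(features.loc[sid].dropna().to_dict(),
                                        subject, state["resource"])
                rows = [{
                    "parameter": k, "value": z.value, "z_raw": z.z_raw,
                    "z_res": z.z_res, "preferred": z.preferred,
                } for k, z in profile.entries.items()]
                pd.DataFrame(rows).to_csv(out / "z_profile.csv", index=False)
                if config.render_score_report:
                    render_report(profile, out / "z_profile.png")
                info = {"subject": sid, "n_scored": len(profile)}
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, exc) from exc
        info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = info

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _simulate(spec: CohortSpec):
    from .synthetic import gen_cohort

    return gen_cohort(spec)


def _build_resource(normative: pd.DataFrame, report: pd.DataFrame, models) -> NormativeResource:
    from .cohort import NormativeEntry

    entries = {}
    for key, row in normative.iterrows():
        if not np.isfinite(row.get("mean", np.nan)) or row["n"] < 2:
            continue
        r2 = None
        if key in report.index and np.isfinite(report.loc[key, "mean_rtest2"]):
            r2 = float(report.loc[key, "mean_rtest2"])
        entries[key] = NormativeEntry(
            parameter=key, n=int(row["n"]), mean=float(row["mean"]),
            sd=float(row["sd"]), cov=float(row["cov"]),
            q1=float(row["q1"]), q3=float(row["q3"]), rtest2=r2,
        )
    models = {k: m for k, m in models.items() if k in entries}
    return NormativeResource(entries=entries, models=models,
                             provenance="synthetic-cohort-build")
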