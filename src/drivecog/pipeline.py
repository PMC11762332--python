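"""End-to-end orchestration: simulate -> extract -> evaluate -> contribute.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage; one
master seed governs all randomness through derived child seeds, so a run
directory is exactly reproducible from its config.  Artifacts written:

    roster.csv                subject roster
    sessions/                 per-session IMU/GPS CSVs + manifest.csv
    features.csv              26-feature table, one row per subject
    results/                  summary, per-fold detail, per-class accuracy
    contributions.csv         ranked feature contributions
    contributions.png         bar chart of the ranking
    run_log.yaml              config echo, seeds, package version
    report.md                 human-readable summary (via make_report)
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contribution import (
    aggregate_contributions,
    loading_contribution,
    plot_contributions,
    write_contributions,
)
from .model_eval import MODEL_NAMES, cross_validate, write_results
from .sensor_io import write_roster, write_session_dir
from .synthetic import (
    CircuitConfig,
    CohortConfig,
    NoiseParams,
    StyleParams,
    default_styles,
    generate_cohort,
)
from .turn_features import (
    DetectionParams,
    extract_features,
    feature_table,
    write_feature_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one full run."""

    out_dir: str = "runs/default"
    seed: int = 17
    cohort: CohortConfig = field(default_factory=CohortConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    k: int = 4
    models: tuple[str, ...] = MODEL_NAMES
    n_components: int = 5
    write_sessions: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cohort_raw = dict(raw.get("cohort", {}))
        circuit = CircuitConfig(**cohort_raw.pop("circuit", {}))
        styles_raw = cohort_raw.pop("styles", None)
        styles = (
            {k: StyleParams(**v) for k, v in styles_raw.items()}
            if styles_raw
            else default_styles()
        )
        noise = NoiseParams(**cohort_raw.pop("noise", {}))
        if "conditions" in cohort_raw:
            cohort_raw["conditions"] = tuple(cohort_raw["conditions"])
        cohort = CohortConfig(
            circuit=circuit, styles=styles, noise=noise, **cohort_raw
        )
        detection = DetectionParams(**raw.get("detection", {}))
        cv = raw.get("cv", {})
        return cls(
            out_dir=raw.get("out_dir", "runs/default"),
            seed=int(raw.get("seed", 17)),
            cohort=cohort,
            detection=detection,
            k=int(cv.get("k", 4)),
            models=tuple(cv.get("models", MODEL_NAMES)),
            n_components=int(cv.get("n_components", 5)),
            write_sessions=bool(raw.get("write_sessions", True)),
        )

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "cohort": {
                "n_healthy": self.cohort.n_healthy,
                "n_mci": self.cohort.n_mci,
                "conditions": list(self.cohort.conditions),
                "effect_size": self.cohort.effect_size,
                "between_subject_cv": self.cohort.between_subject_cv,
                "circuit": asdict(self.cohort.circuit),
                "styles": {k: asdict(v) for k, v in self.cohort.styles.items()},
                "noise": asdict(self.cohort.noise),
            },
            "detection": asdict(self.detection),
            "cv": {
                "k": self.k,
                "models": list(self.models),
                "n_components": self.n_components,
            },
            "write_sessions": self.write_sessions,
        }


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full chain and return the run directory.

    Idempotent for fixed seeds: rerunning with the same config rewrites
    byte-identical feature and result CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    roster, sessions = _stage("simulate")(generate_cohort)(
        config.cohort, config.seed
    )
    write_roster(roster, out / "roster.csv")
    if config.write_sessions:
        _stage("simulate")(write_session_dir)(sessions, out / "sessions")
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()

    @_stage("extract")
    def _extract():
        by_subject: dict[str, list] = {}
        for s in sessions:
            by_subject.setdefault(s.subject_id, []).append(s)
        vectors = [
            extract_features(subj_sessions, params=config.detection)
            for subj_sessions in by_subject.values()
        ]
        return feature_table(vectors, roster)

    features = _extract()
    write_feature_table(features, out / "features.csv")
    timings["extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = _stage("evaluate")(cross_validate)(
        features,
        roster,
        model_names=config.models,
        k=config.k,
        seed=config.seed,
        n_components=config.n_components,
    )
    write_results(result, out / "results")
    timings["evaluate"] = time.perf_counter() - t0

    t0 = time.perf_counter()

    @_stage("contrib")
    def _contrib():
        scores = [
            loading_contribution(result.pca_models[i])
            for i in sorted(result.pca_models)
        ]
        return aggregate_contributions(scores)

    contrib = _contrib()
    write_contributions(contrib, out / "contributions.csv")
    plot_contributions(contrib, out / "contributions.png")
    timings["contrib"] = time.perf_counter() - t0

    log = {
        "package_version": __version__,
        "config": config.to_dict(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_subjects": int(len(roster)),
        "n_sessions": len(sessions),
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)

    make_report(out)
    return out


REQUIRED_ARTIFACTS = [
    "roster.csv",
    "features.csv",
    "results/results_full.csv",
    "results/folds.csv",
    "results/per_class_accuracy.csv",
    "contributions.csv",
]


def make_report(run_dir: str | Path) -> Path:
    """Render ``report.md`` summarizing a completed run.

    Raises :class:`PipelineError` listing missing artifacts for an
    incomplete run, or naming the offending column for tampered files.
    """
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise PipelineError(
            f"incomplete run at {run_dir}: missing artifacts {missing}"
        )
    summary = pd.read_csv(run_dir / "results" / "results_full.csv")
    needed = ["model"] + [
        f"{m}_{s}"
        for m in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
        for s in ("mean", "std")
    ]
    bad = [c for c in needed if c not in summary.columns]
    if bad:
        raise PipelineError(
            f"results_full.csv is missing column(s) {bad}"
        )
    per_class = pd.read_csv(run_dir / "results" / "per_class_accuracy.csv")
    contrib = pd.read_csv(run_dir / "contributions.csv")
    roster = pd.read_csv(run_dir / "roster.csv")

    def pct(mu, sd):
        if not np.isfinite(mu):
            return "undefined"
        return f"{mu * 100:.0f} ± {sd * 100:.0f}%"

    lines = [
        "# Driving-performance MCI classification report",
        "",
        f"Cohort: {len(roster)} subjects "
        f"({(roster.status == 'Healthy').sum()} healthy, "
        f"{(roster.status == 'MCI').sum()} MCI).",
        "",
        "## Cross-validated diagnostic metrics (mean ± std over folds)",
        "",
        "| Model | Accuracy | Sensitivity | Specificity | PPV | NPV |",
        "|---|---|---|---|---|---|",
    ]
    for r in summary.itertuples(index=False):
        cells = [
            pct(getattr(r, f"{m}_mean"), getattr(r, f"{m}_std"))
            for m in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
        ]
        lines.append(f"| {r.model} | " + " | ".join(cells) + " |")
    lines += [
        "",
        "## Per-class accuracy (pooled over folds)",
        "",
        "| Model | Healthy | MCI | All |",
        "|---|---|---|---|",
    ]
    for r in per_class.itertuples(index=False):
        lines.append(
            f"| {r.model} | {r.healthy * 100:.0f}% | {r.mci * 100:.0f}% "
            f"| {r.all * 100:.0f}% |"
        )
    top = contrib.sort_values("rank").head(5)
    lines += ["", "## Top-5 feature contributions", ""]
    for r in top.itertuples(index=False):
        lines.append(
            f"{r.rank}. {r.feature_name} (score {r.score:.3f})"
        )
    lines.append("")
    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
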