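"""Run configuration and the end-to-end pipeline driver.

A :class:`RunConfig` (usually loaded from YAML) fixes every stochastic
stage's seed, the cohort composition, detector and classifier settings, and
the output directory.  :func:`run_pipeline` executes
simulate -> detect -> features -> families -> aggregates -> classify ->
report, writes all stage outputs as plain CSV/JSON (optionally WAV), and
serializes the resolved configuration and a manifest into the output
directory.  Re-running an identical configuration reproduces identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .classification_eval import cross_validate
from .detection import DetectorConfig
from .pipeline import build_cohort
from .profiles import ChannelGeometry, builtin_profile, builtin_profile_names, \
    default_geometry
from .stats_report import compare_groups, comparison_table
from .synth import SynthConfig

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    out_dir: Path
    seed: int = 0
    geometry: Path | None = None        # YAML; None = packaged default array
    profiles: dict[str, int] = Field(
        default_factory=lambda: {"IPF": 10, "CHF": 10, "PN": 10})
    duration: float = 20.0
    n_breaths: int = 3
    detector: dict = Field(default_factory=dict)
    synth: dict = Field(default_factory=dict)
    tasks: list[str] = Field(
        default_factory=lambda: ["IPF_vs_CHF", "IPF_vs_PN"])
    classifiers: list[str] = Field(default_factory=lambda: ["svm", "nn"])
    folds: int = 5
    mode: str = "crackle_plus_aggregate"
    reference_group: str = "IPF"
    write_audio: bool = False

    @field_validator("geometry")
    @classmethod
    def _geometry_exists(cls, v):
        if v is not None and not Path(v).is_file():
            raise ValueError(f"geometry file not found: {v}")
        return v

    @field_validator("profiles")
    @classmethod
    def _profiles_known(cls, v):
        known = set(builtin_profile_names())
        for name, n in v.items():
            if name.upper() not in known:
                raise ValueError(
                    f"unknown profile {name!r}; built-ins: {sorted(known)}")
            if n < 1:
                raise ValueError(f"profile {name!r} needs >= 1 patient")
        return v

    @field_validator("mode")
    @classmethod
    def _mode_known(cls, v):
        if v not in ("crackle_only", "crackle_plus_aggregate"):
            raise ValueError("mode must be crackle_only or crackle_plus_aggregate")
        return v

    @field_validator("classifiers")
    @classmethod
    def _clf_known(cls, v):
        for kind in v:
            if kind not in ("svm", "nn"):
                raise ValueError(f"classifier must be svm or nn, got {kind!r}")
        return v


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(**yaml.safe_load(fh))


def _metrics_markdown(results: dict) -> str:
    lines = ["| Task | Classifier | Level | Sensitivity | Specificity | Accuracy |",
             "|---|---|---|---|---|---|"]
    for task, per_kind in results.items():
        for kind, levels in per_kind.items():
            for level, m in levels.items():
                lines.append(
                    f"| {task} | {kind} | {level} | {m['sensitivity']:.2f} "
                    f"| {m['specificity']:.2f} | {m['accuracy']:.2f} |")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline described by ``config``.

    Returns a dict of the main in-memory artifacts and writes all stage
    outputs under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = (ChannelGeometry.from_yaml(config.geometry)
                if config.geometry else default_geometry())
    detector = DetectorConfig(**config.detector)
    synth = SynthConfig(**config.synth)
    groups = {name.upper(): (builtin_profile(name), int(n))
              for name, n in config.profiles.items()}

    cohort = build_cohort(
        groups, geometry, seed=config.seed, duration=config.duration,
        n_breaths=config.n_breaths, synth=synth, detector=detector,
        audio_dir=out / "recordings" if config.write_audio else None,
    )
    cohort["crackles"].to_csv(out / "crackle_features.csv", index=False)
    cohort["breaths"].to_csv(out / "breath_aggregates.csv", index=False)
    cohort["summaries"].to_csv(out / "patient_summaries.csv", index=False)

    report = None
    counts = cohort["summaries"].groupby("group")["patient"].nunique()
    if len(counts) >= 2 and (counts >= 2).all() and \
            config.reference_group in counts.index:
        rows = compare_groups(cohort["summaries"],
                              reference=config.reference_group)
        report = comparison_table(rows)
        report.to_csv(out / "group_comparison.csv", index=False)

    results: dict = {}
    for task in config.tasks:
        a, b = task.replace("-", "_").upper().split("_VS_")
        if a not in groups or b not in groups:
            continue
        results[task] = {}
        for kind in config.classifiers:
            res = cross_validate(
                cohort["crackles"], task=task, k=config.folds,
                seed=config.seed, kind=kind, mode=config.mode,
                breaths=cohort["breaths"])
            results[task][kind] = {
                lvl: m.as_dict() for lvl, m in res.metrics.items()}
    if results:
        with open(out / "evaluation.json", "w") as fh:
            json.dump(results, fh, indent=2)
        (out / "evaluation.md").write_text(_metrics_markdown(results))

    with open(out / "config.yaml", "w") as fh:
        cfg = json.loads(config.model_dump_json())
        yaml.safe_dump(cfg, fh, sort_keys=False)
    import numpy, pandas, scipy, sklearn  # noqa
    manifest = {
        "package": "cracklekit 0.1.0",
        "versions": {
            "numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__, "scikit-learn": sklearn.__version__,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"cohort": cohort, "evaluation": results, "group_comparison": report}
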