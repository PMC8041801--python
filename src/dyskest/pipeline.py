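"""End-to-end orchestration: simulate -> preprocess -> featurize -> train -> evaluate.

A single YAML/JSON run configuration drives the whole pipeline and every
artifact (cohort manifest, feature table, report) embeds the package
version and master seed, so a run is reproducible from its config alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from . import __version__
from .evaluate import run_experiment
from .features import feature_table, featurize_dataset
from .io import assemble_dataset, write_cohort
from .models import ModelConfig, default_grid, full_grid
from .synth import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A run configuration violated the documented schema."""


@dataclass
class RunConfig:
    out_dir: str = "dyskest_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    grid: str | list = "default"         # "default" (2 points), "full" (15), or explicit pairs
    epochs: int = 30
    dropout: float = 0.7
    learning_rate: float = 1e-3
    batch_size: int = 32

    def resolve_grid(self) -> list[tuple[int, int]]:
        if self.grid == "default":
            return default_grid()
        if self.grid == "full":
            return full_grid()
        return [(int(nl), int(nh)) for nl, nh in self.grid]

    def base_model_config(self) -> ModelConfig:
        return ModelConfig(
            dropout=self.dropout, learning_rate=self.learning_rate,
            batch_size=self.batch_size, epochs=self.epochs, seed=self.seed,
        )


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    cohort_raw = raw.pop("cohort", {})
    cohort_known = {f.name for f in fields(CohortConfig)}
    bad = set(cohort_raw) - cohort_known
    if bad:
        raise ConfigError(f"unknown cohort field(s): {sorted(bad)}")
    for k, v in cohort_raw.items():
        if isinstance(v, list):
            cohort_raw[k] = tuple(v)
    try:
        cohort = replace(CohortConfig(), **cohort_raw)
        cohort.validate()
        cfg = RunConfig(cohort=cohort, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def run_all(config: RunConfig | str | Path) -> Path:
    """Run the whole pipeline; returns the report path."""
    if not isinstance(config, RunConfig):
        config = load_run_config(config)
    out = Path(config.out_dir)
    meta = {"dyskest_version": __version__, "master_seed": config.seed}

    cohort_cfg = replace(config.cohort, seed=config.seed)
    data_dir = out / "data"
    recordings, annotations = generate_cohort(cohort_cfg)
    write_cohort(recordings, annotations, data_dir, extra_meta=meta)
    logger.info("cohort written to %s", data_dir)

    dataset = assemble_dataset(recordings, annotations)
    sequences = featurize_dataset(dataset)
    feat_dir = out / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    feature_table(sequences).to_csv(feat_dir / "windows.csv", index=False)

    lstm_report, linear_report = run_experiment(
        sequences,
        seed=config.seed,
        grid=config.resolve_grid(),
        base_config=config.base_model_config(),
    )
    report_dir = out / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    report = {
        **meta,
        "cohort": dataset.summary(),
        "lstm": lstm_report.to_dict(),
        "linear_regression": linear_report.to_dict(),
    }
    report_path = report_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    _write_summary(report, report_dir / "summary.md")
    return report_path


def _fmt(v) -> str:
    return "n/a" if v is None else f"{v:.3f}"


def _write_summary(report: dict, path: Path) -> None:
    lines = [
        "# Evaluation summary",
        "",
        f"version {report['dyskest_version']}, master seed {report['master_seed']}",
        f"cohort: {report['cohort']}",
        "",
        "| model | window r | window MAE | round r | round MAE | AUC |",
        "|---|---|---|---|---|---|",
    ]
    for key in ("lstm", "linear_regression"):
        r = report[key]
        roc = r["roc"]
        lines.append(
            "| {} | {} | {} | {} | {} | {} |".format(
                r["model"],
                _fmt(r["window_level"]["pearson_r"]),
                _fmt(r["window_level"]["mae"]),
                _fmt(r["round_level"]["pearson_r"]),
                _fmt(r["round_level"]["mae"]),
                _fmt(None if roc is None else roc["auc"]),
            )
        )
    path.write_text("\n".join(lines) + "\n")
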