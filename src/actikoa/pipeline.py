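"""End-to-end orchestration: simulate -> build cohorts -> cross-validate -> report.

A run is fully specified by a :class:`RunConfig`; the config is copied
verbatim into the output directory, per-stage seeds are derived
deterministically from the single global seed, and every stage logs counts
and timings. Rerunning an identical config reproduces the cohort, the
splits and the metric files.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .cohort import (
    DEFAULT_ANOMALY_MAX,
    DEFAULT_BMI_MIN,
    DEFAULT_EARLY_WINDOW,
    DEFAULT_PRODROMAL_WINDOW,
    ScenarioDataset,
    build_scenario,
    filter_valid,
)
from .evaluate import CVSummary, cross_validate
from .model import ModelConfig
from .records import write_cohort
from .simulate import SyntheticConfig, generate_population

logger = logging.getLogger(__name__)

SCENARIO_NAMES = {
    1: "healthy_vs_koa",
    2: "prodromal_vs_diagnosed",
    3: "healthy_vs_prodromal_5y",
}

_STAGE_INDEX = {"simulate": 1, "build": 2, "evaluate": 3}


def stage_seed(global_seed: int, stage: str, scenario: int = 0) -> int:
    """Deterministic per-stage seed: SeedSequence keyed on (seed, stage, scenario)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_INDEX[stage], int(scenario)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CohortParams:
    bmi_min: float = DEFAULT_BMI_MIN
    anomaly_max: float = DEFAULT_ANOMALY_MAX
    prodromal_window: float = DEFAULT_PRODROMAL_WINDOW
    early_window: float = DEFAULT_EARLY_WINDOW


@dataclass(frozen=True)
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cohort: CohortParams = field(default_factory=CohortParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    scenarios: tuple[int, ...] = (1, 2, 3)
    k_folds: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict(),
            "cohort": asdict(self.cohort),
            "model": self.model.to_dict(),
            "scenarios": list(self.scenarios),
            "k_folds": self.k_folds,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            synthetic=SyntheticConfig.from_dict(d.get("synthetic", {})),
            cohort=CohortParams(**d.get("cohort", {})),
            model=ModelConfig.from_dict(d.get("model", {})),
            scenarios=tuple(d.get("scenarios", (1, 2, 3))),
            k_folds=int(d.get("k_folds", 5)),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunArtifacts:
    config: RunConfig
    out_dir: Path
    flow_counts: dict
    datasets: dict[int, ScenarioDataset]
    summaries: dict[int, CVSummary]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunArtifacts:
    """Execute every stage for each selected scenario, writing all artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "INCOMPLETE").write_text("run in progress\n")
    config.save(out_dir / "run_config.yaml")
    log_path = out_dir / "run.log"

    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("actikoa")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def _stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            logger.error("stage %s failed: %s", name, exc)
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
        return result

    try:
        sim_cfg = SyntheticConfig.from_dict(
            {**config.synthetic.to_dict(), "seed": stage_seed(config.seed, "simulate")}
        )
        records = _stage("simulate", lambda: generate_population(sim_cfg))
        write_cohort(records, out_dir / "cohort.csv")
        sim_cfg.save(out_dir / "cohort.config.yaml")

        kept, rejections = _stage(
            "filter",
            lambda: filter_valid(records, config.cohort.bmi_min, config.cohort.anomaly_max),
        )
        flow = {
            "generated": len(records),
            "eligible": len(kept),
            "rejected": len(rejections),
            "rejection_reasons": _count_reasons(rejections),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        }
        logger.info("filter: %d generated, %d eligible", len(records), len(kept))

        datasets: dict[int, ScenarioDataset] = {}
        summaries: dict[int, CVSummary] = {}
        for scenario in config.scenarios:
            name = SCENARIO_NAMES[scenario]
            ds = _stage(
                f"build_scenario_{scenario}",
                lambda s=scenario: build_scenario(
                    kept, s, stage_seed(config.seed, "build", s),
                    prodromal_window=config.cohort.prodromal_window,
                    early_window=config.cohort.early_window,
                ),
            )
            ds.provenance["config_hash"] = config.config_hash()
            ds.write(out_dir / f"scenario{scenario}_{name}.csv")
            datasets[scenario] = ds
            summary = _stage(
                f"evaluate_scenario_{scenario}",
                lambda d=ds, s=scenario: cross_validate(
                    d, config.model, k=config.k_folds,
                    seed=stage_seed(config.seed, "evaluate", s),
                ),
            )
            summary.write(out_dir, prefix=f"scenario{scenario}")
            summaries[scenario] = summary
            flow[f"scenario{scenario}_class_sizes"] = ds.provenance["class_sizes"]

        (out_dir / "flow_counts.yaml").write_text(yaml.safe_dump(flow, sort_keys=False))
        artifacts = RunArtifacts(config, out_dir, flow, datasets, summaries)
        make_report(artifacts)
        (out_dir / "INCOMPLETE").unlink()
        return artifacts
    finally:
        root.removeHandler(handler)
        handler.close()


def _count_reasons(rejections) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, reason in rejections:
        counts[reason] = counts.get(reason, 0) + 1
    return counts


def group_diurnal_means(dataset: ScenarioDataset) -> dict[str, np.ndarray]:
    """Mean 24-hour profile per class, for the group-curve figure."""
    arrays = dataset.to_arrays()
    return {
        "class0": arrays["profile"][arrays["y"] == 0].mean(axis=0),
        "class1": arrays["profile"][arrays["y"] == 1].mean(axis=0),
    }


def make_report(artifacts: RunArtifacts, with_figures: bool = True) -> Path:
    """One human-readable summary per run: flow, metric table, confusions."""
    out_dir = artifacts.out_dir
    lines = ["# Run report", "", f"Config hash: `{artifacts.config.config_hash()}`",
             f"Global seed: {artifacts.config.seed}", "", "## Participant flow", ""]
    for key, value in artifacts.flow_counts.items():
        lines.append(f"- {key}: {value}")

    lines += ["", "## Cross-validation metrics (mean ± SD over folds)", "",
              "| Scenario | Accuracy | F1 (macro) | Sensitivity (macro) | AUC (macro) | p (proportion z) |",
              "|---|---|---|---|---|---|"]
    for scenario in (1, 2, 3):
        name = SCENARIO_NAMES[scenario]
        if scenario not in artifacts.summaries:
            lines.append(f"| {name} | not run | | | | |")
            continue
        s = artifacts.summaries[scenario]
        lines.append(
            f"| {name} | {s.mean['accuracy']:.3f} ± {s.sd['accuracy']:.3f} "
            f"| {s.mean['f1_macro']:.3f} ± {s.sd['f1_macro']:.3f} "
            f"| {s.mean['sensitivity_macro']:.3f} ± {s.sd['sensitivity_macro']:.3f} "
            f"| {s.mean['auc_macro']:.3f} ± {s.sd['auc_macro']:.3f} "
            f"| {s.proportion_p:.2e} |"
        )

    lines += ["", "## Best-fold normalized confusion matrices", ""]
    for scenario, summary in artifacts.summaries.items():
        norm = summary.folds[summary.best_fold].normalized_confusion()
        lines.append(f"### {SCENARIO_NAMES[scenario]} (fold {summary.best_fold})")
        lines.append("")
        lines.append("| | pred 0 | pred 1 |")
        lines.append("|---|---|---|")
        for i, row in enumerate(norm):
            lines.append(f"| true {i} | {row[0]:.3f} | {row[1]:.3f} |")
        lines.append("")

    if with_figures:
        try:
            _write_figures(artifacts)
            lines += ["Figures: `scenario*_diurnal_means.png`, `scenario*_confusion.png`", ""]
        except Exception as exc:  # pragma: no cover - plotting is best-effort
            logger.warning("figure generation failed: %s", exc)

    report_path = out_dir / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path


def _write_figures(artifacts: RunArtifacts) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for scenario, ds in artifacts.datasets.items():
        means = group_diurnal_means(ds)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        hours = np.arange(24)
        ax.plot(hours, means["class0"], label="class 0", color="tab:blue")
        ax.plot(hours, means["class1"], label="class 1", color="tab:orange")
        ax.set_xlabel("hour of day")
        ax.set_ylabel("mean acceleration (a.u.)")
        ax.set_title(SCENARIO_NAMES[scenario])
        ax.legend()
        fig.tight_layout()
        fig.savefig(artifacts.out_dir / f"scenario{scenario}_diurnal_means.png", dpi=100)
        plt.close(fig)

        summary = artifacts.summaries.get(scenario)
        if summary is None:
            continue
        norm = summary.folds[summary.best_fold].normalized_confusion()
        fig, ax = plt.subplots(figsize=(3.5, 3))
        im = ax.imshow(norm, cmap="Blues", vmin=0, vmax=1)
        for i in range(2):
            for j in range(2):
                ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center")
        ax.set_xticks([0, 1], ["pred 0", "pred 1"])
        ax.set_yticks([0, 1], ["true 0", "true 1"])
        ax.set_title(SCENARIO_NAMES[scenario])
        fig.colorbar(im, fraction=0.046)
        fig.tight_layout()
        fig.savefig(artifacts.out_dir / f"scenario{scenario}_confusion.png", dpi=100)
        plt.close(fig)
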