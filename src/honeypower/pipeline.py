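"""End-to-end pipeline: samples -> indices -> network -> sensitivity -> PCA.

Deterministic for a fixed configuration: every stage derives its randomness
from the configured seeds, and all artifacts are plain CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .ann import SplitSpec, save_model, train
from .indices import score_table
from .io import read_samples, write_samples
from .ordination import PCA_VARIABLES, run_pca, summarize_groups
from .samples import samples_to_frame
from .sensitivity import sensitivity_grid
from .synthetic import GeneratorConfig, generate_table

#: Fixed float format for CSV artifacts so reruns are byte-identical.
_FLOAT_FMT = "%.10g"

MIN_TRAIN_ROWS = 20


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """Configuration of a full run."""

    input_csv: str | None = None      # None -> simulate
    out_dir: str = "honeypower_run"
    n_per_type: int = 25
    seed: int = 20180101
    split_seed: int = 7
    train_seed: int = 11
    n_hidden: int = 10
    restarts: int = 10
    max_iter: int = 400
    censored_policy: str = "impute"
    reference_policy: str = "midpoint"
    extra_generator: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage, writing artifacts under ``config.out_dir``.

    Writes samples.csv (when simulating), indices.csv, model.json,
    fit_report.json, sensitivity.csv, pca.csv, pca_scores.csv and
    run_log.txt. Any stage failure raises :class:`PipelineError` naming the
    stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"honeypower {__version__}",
        f"started {datetime.now(timezone.utc).isoformat(timespec='seconds')}",
        f"config: {json.dumps(config.__dict__, default=str, sort_keys=True)}",
    ]

    def fail(stage: str, exc: Exception):
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(f"{stage}: {exc}") from exc

    # --- data ---
    stage = "data"
    try:
        if config.input_csv:
            frame = samples_to_frame(read_samples(config.input_csv))
            log_lines.append(f"data: read {len(frame)} samples from {config.input_csv}")
        else:
            gen = GeneratorConfig(
                n_per_type=config.n_per_type, seed=config.seed,
                **config.extra_generator,
            )
            frame, _ = generate_table(gen)
            write_samples(frame, out / "samples.csv")
            log_lines.append(
                f"data: simulated {len(frame)} samples "
                f"(n_per_type={config.n_per_type}, seed={config.seed})"
            )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    # --- indices ---
    stage = "indices"
    try:
        indices = score_table(frame, censored_policy=config.censored_policy)
        indices.to_csv(out / "indices.csv", index=False, float_format=_FLOAT_FMT)
        log_lines.append(f"indices: wrote {len(indices)} rows")
    except Exception as exc:
        fail(stage, exc)

    # --- train ---
    stage = "train"
    try:
        training_table = pd.DataFrame({
            "free_acidity": frame["free_acidity"].to_numpy(),
            "colour_L": frame["colour_L"].to_numpy(),
            "colour_a": frame["colour_a"].to_numpy(),
            "power_of_honey": indices["power_of_honey"].to_numpy(),
        })
        if len(training_table) < MIN_TRAIN_ROWS:
            raise ValueError(f"too few rows: {len(training_table)} < {MIN_TRAIN_ROWS}")
        weights, norm, report = train(
            training_table, n_hidden=config.n_hidden,
            split=SplitSpec(seed=config.split_seed),
            restarts=config.restarts, max_iter=config.max_iter,
            seed=config.train_seed,
        )
        save_model(out / "model.json", weights, norm,
                   metadata={"split_seed": config.split_seed,
                             "train_seed": config.train_seed})
        (out / "fit_report.json").write_text(
            json.dumps(report.to_dict(), indent=1, sort_keys=True)
        )
        log_lines.append(
            "train: r2 " + ", ".join(f"{k}={v:.4f}" for k, v in report.r2.items())
        )
    except Exception as exc:
        fail(stage, exc)

    # --- sensitivity ---
    stage = "sensitivity"
    try:
        grid = sensitivity_grid(weights, norm, reference=config.reference_policy)
        grid.table.to_csv(out / "sensitivity.csv", index=False, float_format=_FLOAT_FMT)
        log_lines.append(f"sensitivity: {len(grid.table)} grid rows")
    except Exception as exc:
        fail(stage, exc)

    # --- pca ---
    stage = "pca"
    try:
        pca_table = training_table.copy()
        res = run_pca(pca_table, PCA_VARIABLES)
        expl = pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(len(res.eigenvalues))],
            "eigenvalue": res.eigenvalues,
            "explained_pct": res.explained_pct,
            **{
                f"contrib_{v}": res.contributions_pct[i]
                for i, v in enumerate(res.variable_names)
            },
        })
        expl.to_csv(out / "pca.csv", index=False, float_format=_FLOAT_FMT)
        scores = pd.DataFrame(
            res.scores, columns=[f"pc{i + 1}" for i in range(res.scores.shape[1])]
        )
        scores.insert(0, "sample_id", frame["sample_id"].to_numpy())
        scores.insert(1, "floral_type", frame["floral_type"].to_numpy())
        scores.to_csv(out / "pca_scores.csv", index=False, float_format=_FLOAT_FMT)
        centroids = summarize_groups(res.scores, frame["floral_type"].to_numpy())
        centroids.to_csv(out / "pca_centroids.csv", index=False, float_format=_FLOAT_FMT)
        log_lines.append(
            "pca: explained "
            + ", ".join(f"{x:.2f}%" for x in res.explained_pct)
        )
    except Exception as exc:
        fail(stage, exc)

    log_lines.append("done")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
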