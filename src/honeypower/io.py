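"""CSV and config plumbing for the pipeline."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .samples import COLUMNS, SampleValidationError, frame_to_samples, samples_to_frame


def write_samples(samples, path) -> Path:
    """Write records to CSV in the canonical column order.

    Censored MICs are written as the literal string ">37.5".
    """
    frame = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_samples(path, validate: bool = True):
    """Read and validate honey records from CSV.

    Raises :class:`SampleValidationError` naming the missing column or the
    offending row/field.
    """
    frame = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in COLUMNS if c not in frame.columns and c != "country"]
    if missing:
        raise SampleValidationError(f"{path}: missing column(s): {missing}")
    try:
        return frame_to_samples(frame, validate=validate)
    except (ValueError, TypeError) as exc:
        raise SampleValidationError(f"{path}: {exc}") from exc


def read_config(path) -> dict:
    """Flat key/value configuration from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
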