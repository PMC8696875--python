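"""Honey sample records and the tabular schema shared across the pipeline.

A sample is one honey: floral type, physicochemical panel, CIE L*a*b* colour,
antioxidant assays (TPC, TFC, TCC, DPPH IC50) and MIC values for eight
bacterial strains on the two-fold dilution grid used in broth microdilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

FLORAL_TYPES = ("acacia", "sunflower", "meadow", "forest")

#: MIC dilution grid, % w/v honey, strongest (lowest) last.
MIC_GRID = (37.5, 18.7, 9.3, 4.6, 2.3)

#: Sentinel for samples not inhibitory at the highest tested concentration.
MIC_CENSORED = ">37.5"

#: Numeric stand-in for a censored MIC (next two-fold step above the grid).
MIC_CENSORED_IMPUTED = 75.0

#: Strain column keys in fixed order, mapped to display names.
STRAINS: Mapping[str, str] = {
    "mic_e_coli_atcc": "E. coli ATCC 11229",
    "mic_e_coli_i": "E. coli I (clinical)",
    "mic_p_aeruginosa": "P. aeruginosa ATCC 35554",
    "mic_p_mirabilis_i": "P. mirabilis I (clinical)",
    "mic_s_aureus_atcc": "S. aureus ATCC 6538",
    "mic_s_aureus_i": "S. aureus I (clinical)",
    "mic_b_subtilis": "B. subtilis ATCC 6633",
    "mic_e_faecalis": "E. faecalis ATCC 19433",
}

PHYSICOCHEMICAL_FIELDS = (
    "moisture", "free_acidity", "ph", "conductivity",
    "glucose", "fructose", "hmf", "minerals_total",
)
COLOUR_FIELDS = ("colour_L", "colour_a", "colour_b")
ANTIOXIDANT_FIELDS = ("tpc", "tfc", "tcc", "dpph_ic50")

#: Continuous numeric fields (everything except the grid-valued MICs).
CONTINUOUS_FIELDS = PHYSICOCHEMICAL_FIELDS + COLOUR_FIELDS + ANTIOXIDANT_FIELDS

#: Full CSV column order.
COLUMNS = (
    ("sample_id", "floral_type", "country")
    + CONTINUOUS_FIELDS
    + tuple(STRAINS)
)

#: Fields that must be strictly positive.
_POSITIVE_FIELDS = frozenset(CONTINUOUS_FIELDS) - {"colour_a", "colour_b"}


class SampleValidationError(ValueError):
    """A honey record violates the schema invariants."""


@dataclass
class HoneySample:
    """One honey record.

    ``mic`` maps strain column keys (see :data:`STRAINS`) to a grid value
    (% w/v) or the censored sentinel ``">37.5"``.
    """

    sample_id: str
    floral_type: str
    moisture: float
    free_acidity: float
    ph: float
    conductivity: float
    glucose: float
    fructose: float
    hmf: float
    minerals_total: float
    colour_L: float
    colour_a: float
    colour_b: float
    tpc: float
    tfc: float
    tcc: float
    dpph_ic50: float
    mic: dict = field(default_factory=dict)
    country: str = ""

    def validate(self) -> "HoneySample":
        if self.floral_type not in FLORAL_TYPES:
            raise SampleValidationError(
                f"sample {self.sample_id}: floral_type {self.floral_type!r} "
                f"not in {FLORAL_TYPES}"
            )
        if not 0.0 <= self.colour_L <= 100.0:
            raise SampleValidationError(
                f"sample {self.sample_id}: colour_L {self.colour_L} outside [0, 100]"
            )
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise SampleValidationError(
                    f"sample {self.sample_id}: {name} = {v} must be finite and > 0"
                )
        missing = set(STRAINS) - set(self.mic)
        if missing:
            raise SampleValidationError(
                f"sample {self.sample_id}: missing MIC for {sorted(missing)}"
            )
        for strain, v in self.mic.items():
            if v != MIC_CENSORED and float(v) not in MIC_GRID:
                raise SampleValidationError(
                    f"sample {self.sample_id}: MIC {v!r} for {strain} not on the "
                    f"dilution grid {MIC_GRID} and not {MIC_CENSORED!r}"
                )
        return self


def mic_numeric(value, censored_policy: str = "impute") -> float:
    """Numeric MIC for scoring.

    censored_policy: 'impute' -> 75.0 (next two-fold step), 'grid_max' -> 37.5,
    'nan' -> NaN (caller excludes).
    """
    if value == MIC_CENSORED:
        if censored_policy == "impute":
            return MIC_CENSORED_IMPUTED
        if censored_policy == "grid_max":
            return max(MIC_GRID)
        if censored_policy == "nan":
            return float("nan")
        raise ValueError(f"unknown censored_policy {censored_policy!r}")
    return float(value)


def samples_to_frame(samples) -> pd.DataFrame:
    """Tabulate records in the canonical column order (MICs as objects)."""
    rows = []
    for s in samples:
        row = {c: getattr(s, c) for c in ("sample_id", "floral_type", "country")}
        row.update({c: getattr(s, c) for c in CONTINUOUS_FIELDS})
        row.update({k: s.mic[k] for k in STRAINS})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COLUMNS))


def frame_to_samples(frame: pd.DataFrame, validate: bool = True):
    """Inverse of :func:`samples_to_frame`; validates each record."""
    missing = [c for c in COLUMNS if c not in frame.columns and c != "country"]
    if missing:
        raise SampleValidationError(f"missing column(s): {missing}")
    out = []
    for _, row in frame.iterrows():
        mic = {}
        for k in STRAINS:
            v = row[k]
            mic[k] = MIC_CENSORED if str(v).strip() == MIC_CENSORED else float(v)
        s = HoneySample(
            sample_id=str(row["sample_id"]),
            floral_type=str(row["floral_type"]),
            country=str(row.get("country", "") or ""),
            mic=mic,
            **{c: float(row[c]) for c in CONTINUOUS_FIELDS},
        )
        out.append(s.validate() if validate else s)
    return out


def mic_columns_numeric(frame: pd.DataFrame, censored_policy: str = "impute") -> pd.DataFrame:
    """MIC columns of a sample table converted to floats for scoring."""
    out = {}
    for k in STRAINS:
        out[k] = np.array([mic_numeric(v, censored_policy) for v in frame[k]])
    return pd.DataFrame(out, index=frame.index)
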