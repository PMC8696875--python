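"""Composite health-potential indices: RACI, RAI and the Power of Honey.

Each assay is mapped to a unitless standard score by min-max normalisation
over the analysed table, oriented so that 1 is always "best":

    higher-better:  s = (x - min) / (max - min)   (TPC, TFC, TCC)
    lower-better:   s = (max - x) / (max - min)   (DPPH IC50, MIC)

The relative antioxidant capacity index (RACI) is the mean of the four
antioxidant-panel scores, the relative antibacterial index (RAI) the mean
of the eight per-strain MIC scores, and the Power of Honey the average of
RACI and RAI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import DegenerateRangeError
from .samples import STRAINS, mic_columns_numeric, samples_to_frame

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"

#: Antioxidant panel entering RACI, with score orientation.
RACI_CRITERIA = (
    ("tpc", HIGHER_BETTER),
    ("tfc", HIGHER_BETTER),
    ("tcc", HIGHER_BETTER),
    ("dpph_ic50", LOWER_BETTER),
)


@dataclass(frozen=True)
class ScoreCriterion:
    variable_name: str
    direction: str

    def __post_init__(self):
        if self.direction not in (HIGHER_BETTER, LOWER_BETTER):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class IndexResult:
    sample_id: str
    raci: float
    rai: float
    power_of_honey: float


def minmax_score(values, direction: str, name: str = "variable") -> np.ndarray:
    """Min-max standard score in [0, 1], oriented by ``direction``."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError(f"{name}: need at least 2 values")
    if np.isnan(x).any():
        raise ValueError(f"{name}: missing values are not allowed")
    lo, hi = x.min(), x.max()
    if not hi > lo:
        raise DegenerateRangeError(f"{name}: all values equal ({lo}); min-max score undefined")
    if direction == HIGHER_BETTER:
        return (x - lo) / (hi - lo)
    if direction == LOWER_BETTER:
        return (hi - x) / (hi - lo)
    raise ValueError(f"unknown direction {direction!r}")


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    return samples_to_frame(samples)


def compute_raci(samples) -> np.ndarray:
    """RACI per sample: mean of the four oriented antioxidant scores.

    Extreme values are taken over the whole input table (all floral types
    pooled).
    """
    frame = _as_frame(samples)
    scores = [
        minmax_score(frame[v], direction, name=v) for v, direction in RACI_CRITERIA
    ]
    return np.mean(scores, axis=0)


def compute_rai(samples, censored_policy: str = "impute") -> np.ndarray:
    """RAI per sample: mean of eight lower-better MIC scores.

    Censored MICs (">37.5") are imputed at the next two-fold step (75.0)
    before scoring under the default policy.
    """
    frame = _as_frame(samples)
    mic = mic_columns_numeric(frame, censored_policy=censored_policy)
    scores = [minmax_score(mic[k], LOWER_BETTER, name=k) for k in STRAINS]
    return np.mean(scores, axis=0)


def compute_power_of_honey(raci, rai) -> np.ndarray:
    """Elementwise average of RACI and RAI."""
    a = np.asarray(raci, float)
    b = np.asarray(rai, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: raci {a.shape} vs rai {b.shape}")
    return (a + b) / 2.0


def score_table(samples, censored_policy: str = "impute") -> pd.DataFrame:
    """Index table: sample_id, floral_type, raci, rai, power_of_honey."""
    frame = _as_frame(samples)
    raci = compute_raci(frame)
    rai = compute_rai(frame, censored_policy=censored_policy)
    return pd.DataFrame({
        "sample_id": frame["sample_id"].to_numpy(),
        "floral_type": frame["floral_type"].to_numpy(),
        "raci": raci,
        "rai": rai,
        "power_of_honey": compute_power_of_honey(raci, rai),
    })
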