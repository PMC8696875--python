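"""Target Pearson correlation structure for the synthetic honey cohort.

The reported pairwise correlations between assay, colour and physicochemical
variables are embedded as a fixed table. Unreported pairs are treated as
free: a positive-semidefinite completion adjusts only those cells, keeping
every reported coefficient exactly pinned. A plain eigenvalue-clipping
repair is also provided as the final safety net (and for matrices with no
pinned cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .samples import CONTINUOUS_FIELDS, STRAINS

#: Ordered variables of the correlation model: all continuous assay fields
#: plus one latent continuous "resistance" variable per strain (whose
#: monotone discretisation yields the grid MIC).
CORRELATION_VARIABLES = tuple(CONTINUOUS_FIELDS) + tuple(STRAINS)

#: Reported pairwise Pearson r values. MIC entries refer to the latent
#: continuous resistance variable (higher = more resistant = higher MIC).
PRINTED_CORRELATIONS = (
    ("tpc", "tfc", 0.7135),
    ("tpc", "dpph_ic50", -0.3187),
    ("tfc", "dpph_ic50", -0.3863),
    ("tpc", "mic_e_coli_atcc", -0.5278),
    ("tpc", "mic_e_coli_i", -0.3815),
    ("tpc", "mic_s_aureus_i", -0.3408),
    ("tpc", "mic_b_subtilis", -0.4367),
    ("tpc", "mic_e_faecalis", -0.2113),
    ("tfc", "mic_p_aeruginosa", -0.3925),
    ("tcc", "mic_p_aeruginosa", -0.6175),
    ("tcc", "mic_p_mirabilis_i", -0.5491),
    ("dpph_ic50", "mic_e_coli_i", 0.6021),
    ("dpph_ic50", "mic_s_aureus_i", 0.6156),
    ("free_acidity", "tpc", 0.7068),
    ("free_acidity", "tfc", 0.7864),
    ("free_acidity", "dpph_ic50", -0.4752),
    ("free_acidity", "mic_b_subtilis", -0.4890),
    ("free_acidity", "mic_s_aureus_atcc", -0.4979),
    ("free_acidity", "mic_e_coli_atcc", -0.4705),
    ("free_acidity", "mic_e_coli_i", -0.4119),
    ("tpc", "colour_L", -0.4534),
    ("tpc", "colour_b", 0.4952),
    ("tfc", "colour_L", -0.8305),
    ("tfc", "colour_b", 0.7395),
    ("dpph_ic50", "colour_a", -0.7153),
    ("dpph_ic50", "colour_b", -0.5708),
    ("conductivity", "minerals_total", 0.6285),
    ("conductivity", "free_acidity", 0.6694),
    ("tpc", "minerals_total", 0.5178),
    ("glucose", "mic_e_faecalis", 0.2235),
    ("glucose", "mic_e_coli_i", 0.2026),
    ("fructose", "mic_p_aeruginosa", 0.3464),
)


def nearest_psd_clip(corr: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at zero followed by rescaling to unit diagonal."""
    c = np.asarray(corr, float)
    w, v = np.linalg.eigh((c + c.T) / 2)
    w = np.clip(w, 0.0, None)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    d[d == 0] = 1.0
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return (c2 + c2.T) / 2


def psd_complete(
    corr: np.ndarray,
    pinned: np.ndarray,
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> np.ndarray:
    """PSD completion keeping cells where ``pinned`` is True fixed.

    Alternating projections: clip negative eigenvalues, restore pinned
    cells and the unit diagonal, repeat. Finishes with a clip-and-rescale
    pass so the result is PSD even if pinned values are jointly infeasible
    (then pinned cells may move slightly; the caller can measure the drift).
    """
    c = np.asarray(corr, float).copy()
    target = c.copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh((c + c.T) / 2)
        if w.min() >= -tol:
            break
        c = (v * np.clip(w, 0.0, None)) @ v.T
        c[pinned] = target[pinned]
        np.fill_diagonal(c, 1.0)
        c = (c + c.T) / 2
    return nearest_psd_clip(c)


@dataclass
class CorrelationTargetMatrix:
    """Symmetric target Pearson matrix assembled from the reported values.

    ``entries`` holds the raw assembly (reported cells exact, zeros
    elsewhere); ``pinned`` marks the reported cells; ``repaired`` is the PSD
    completion actually used by the sampler.
    """

    variable_names: tuple
    entries: np.ndarray
    pinned: np.ndarray
    repaired: np.ndarray = field(init=False)

    def __post_init__(self):
        self.repaired = psd_complete(self.entries, self.pinned)

    @property
    def index(self) -> dict:
        return {v: i for i, v in enumerate(self.variable_names)}

    def entry(self, a: str, b: str) -> float:
        """Raw target cell (reported value, 0 if unreported, 1 on diagonal)."""
        return float(self.entries[self.index[a], self.index[b]])


def build_correlation_targets() -> CorrelationTargetMatrix:
    """Assemble the target matrix from the embedded reported values."""
    names = CORRELATION_VARIABLES
    idx = {v: i for i, v in enumerate(names)}
    p = len(names)
    entries = np.eye(p)
    pinned = np.zeros((p, p), dtype=bool)
    for a, b, r in PRINTED_CORRELATIONS:
        i, j = idx[a], idx[b]
        entries[i, j] = entries[j, i] = r
        pinned[i, j] = pinned[j, i] = True
    return CorrelationTargetMatrix(names, entries, pinned)
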