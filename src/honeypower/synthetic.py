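"""Synthetic honey-sample generator.

Emulates a 100-sample study (25 each of acacia, sunflower, meadow and
forest honey) whose pooled pairwise Pearson correlations match the embedded
reported values, and whose floral types show the qualitative contrasts the
study observed: forest honey dark (low L*, high a*), acid and bioactive;
acacia and meadow honey light.

Sampling is a Gaussian copula. A latent multivariate normal carries the
correlation structure; each continuous variable is then mapped through a
floral-type-specific truncated-normal marginal, and the eight MIC variables
are produced by cutting a latent continuous "resistance" score at pooled
quantiles onto the two-fold dilution grid (monotone, so latent correlations
carry over in rank).

Because floral-type mean shifts add between-group covariance, the
within-type latent correlation matrix is compensated so that the POOLED
correlations — which is how the reported coefficients are read — hit the
targets:

    C_w[ij] = R[ij] * sqrt((1 + B[ii]) (1 + B[jj])) - B[ij],

where B is the covariance of the standardized type offsets; C_w is then
PSD-completed with the reported-pair cells pinned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ann import (
    DEFAULT_NORMALIZATION,
    INPUT_ORDER,
    OUTPUT_NAME,
    MLPWeights,
    NormalizationSpec,
    forward,
)
from .correlations import (
    CORRELATION_VARIABLES,
    CorrelationTargetMatrix,
    build_correlation_targets,
    psd_complete,
)
from .samples import (
    CONTINUOUS_FIELDS,
    FLORAL_TYPES,
    MIC_CENSORED,
    MIC_GRID,
    STRAINS,
    HoneySample,
    frame_to_samples,
)

#: Standardized floral-type mean offsets (within-type SD units), ordered as
#: FLORAL_TYPES = (acacia, sunflower, meadow, forest). They encode the
#: reported qualitative contrasts: forest highest free acidity / a* /
#: bioactivity and darkest; acacia and meadow lightest.
TYPE_OFFSETS = {
    "free_acidity": (-0.8, 0.0, -0.1, 0.9),
    "ph": (-0.2, 0.0, 0.0, 0.2),
    "conductivity": (-0.6, 0.0, -0.1, 0.7),
    "minerals_total": (-0.6, 0.0, -0.1, 0.7),
    "colour_L": (0.8, -0.1, 0.6, -1.0),
    "colour_a": (-0.8, 0.1, -0.2, 0.9),
    "colour_b": (-0.4, 0.3, -0.1, 0.2),
    "tpc": (-0.7, 0.0, -0.1, 0.8),
    "tfc": (-0.7, 0.0, -0.1, 0.8),
    "tcc": (-0.6, 0.4, -0.2, 0.4),
    "dpph_ic50": (0.7, 0.0, 0.1, -0.8),
    **{m: (0.6, 0.0, 0.1, -0.7) for m in STRAINS},
}

#: Per-variable truncated-normal marginals: (base location, scale, lower
#: bound, upper bound), on the variable's natural unit. Locations sit inside
#: legal honey ranges; bounds are physical limits kept >= ~3 SD away so
#: truncation barely distorts the copula correlations.
MARGINAL_DEFAULTS = {
    "moisture": (17.5, 1.3, 12.0, 23.0),        # % w/w
    "free_acidity": (22.0, 7.0, 1.0, 60.0),     # meq/kg
    "ph": (4.2, 0.4, 3.2, 6.5),
    "conductivity": (0.55, 0.12, 0.10, 1.50),   # mS/cm
    "glucose": (30.0, 3.0, 18.0, 42.0),         # g/100 g
    "fructose": (38.0, 3.2, 24.0, 52.0),        # g/100 g
    "hmf": (15.0, 4.0, 0.1, 40.0),              # mg/kg
    "minerals_total": (600.0, 140.0, 40.0, 2000.0),  # mg/kg
    "colour_L": (55.0, 11.0, 0.0, 100.0),       # CIE L*
    "colour_a": (2.5, 2.8, -12.0, 30.0),        # CIE a*
    "colour_b": (28.0, 7.0, 1.0, 75.0),         # CIE b*
    "tpc": (80.0, 20.0, 1.0, 250.0),            # mg GAE/100 g
    "tfc": (15.0, 3.5, 0.5, 60.0),              # mg CAE/100 g
    "tcc": (3.3, 0.75, 0.05, 12.0),             # mg BCE/kg
    "dpph_ic50": (60.0, 12.0, 1.0, 160.0),      # mg/mL
}

#: Pooled probability mass per MIC level, strongest (2.3 % w/v) first, with
#: the last share censored above the grid (">37.5").
MIC_LEVEL_PROBS = (0.05, 0.10, 0.20, 0.30, 0.25, 0.10)

_COUNTRIES = (
    "Serbia", "Albania", "Croatia", "Montenegro", "Romania",
    "Bulgaria", "Bosnia and Herzegovina", "North Macedonia", "Hungary",
)


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic cohort."""

    n_per_type: int = 25
    seed: int = 20180101
    marginal_params: dict = field(default_factory=dict)  # overrides of MARGINAL_DEFAULTS
    type_offsets: dict = field(default_factory=dict)     # overrides of TYPE_OFFSETS
    noise_sd: float = 0.02  # noise for network-derived targets

    def __post_init__(self):
        if self.n_per_type < 1:
            raise ValueError("n_per_type must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for v, (_, scale, lo, hi) in self.merged_marginals().items():
            if scale <= 0 or not hi > lo:
                raise ValueError(f"invalid marginal for {v}: scale {scale}, bounds ({lo}, {hi})")

    def merged_marginals(self) -> dict:
        return {**MARGINAL_DEFAULTS, **self.marginal_params}

    def merged_offsets(self) -> dict:
        return {**TYPE_OFFSETS, **self.type_offsets}


def _offset_matrix(offsets: dict) -> np.ndarray:
    """(4 types x p variables) standardized offsets, centred per variable."""
    p = len(CORRELATION_VARIABLES)
    m = np.zeros((len(FLORAL_TYPES), p))
    idx = {v: i for i, v in enumerate(CORRELATION_VARIABLES)}
    for v, off in offsets.items():
        m[:, idx[v]] = np.asarray(off, float)
    return m - m.mean(axis=0)


def within_type_correlation(
    targets: CorrelationTargetMatrix, offsets: dict
) -> np.ndarray:
    """Within-type latent matrix whose pooled correlation hits the targets."""
    m = _offset_matrix(offsets)
    b = (m.T @ m) / m.shape[0]
    d = np.sqrt(1.0 + np.diag(b))
    cw = targets.repaired * np.outer(d, d) - b
    np.fill_diagonal(cw, 1.0)
    cw = np.clip(cw, -0.99, 0.99)
    np.fill_diagonal(cw, 1.0)
    # keep the compensated reported-pair cells pinned while restoring PSD
    return psd_complete(cw, targets.pinned)


def _discretise_mic(latent: np.ndarray) -> np.ndarray:
    """Cut a latent resistance score at pooled quantiles onto the MIC grid."""
    cum = np.cumsum(MIC_LEVEL_PROBS[:-1])
    cuts = np.quantile(latent, cum)
    levels = list(MIC_GRID[::-1]) + [MIC_CENSORED]  # 2.3 ... 37.5, censored
    out = np.empty(latent.shape, dtype=object)
    bins = np.searchsorted(cuts, latent, side="right")
    for k, lev in enumerate(levels):
        out[bins == k] = lev
    return out


def generate_table(config: GeneratorConfig | None = None):
    """Draw the synthetic cohort.

    Returns ``(samples, latent)``: a sample DataFrame in the canonical
    schema (MICs grid-valued, censoring as ">37.5") and a DataFrame of the
    latent continuous variables (including the pre-discretisation MIC
    resistance scores) for correlation checks.
    """
    config = config or GeneratorConfig()
    targets = build_correlation_targets()
    offsets = config.merged_offsets()
    marginals = config.merged_marginals()
    cw = within_type_correlation(targets, offsets)
    m = _offset_matrix(offsets)

    rng = np.random.default_rng(config.seed)
    p = len(CORRELATION_VARIABLES)
    n_t = config.n_per_type
    root = np.linalg.cholesky(cw + 1e-10 * np.eye(p))
    blocks, types = [], []
    for t, ftype in enumerate(FLORAL_TYPES):
        z = rng.standard_normal((n_t, p)) @ root.T + m[t]
        blocks.append(z)
        types += [ftype] * n_t
    z = np.vstack(blocks)
    type_idx = np.repeat(np.arange(len(FLORAL_TYPES)), n_t)

    idx = {v: i for i, v in enumerate(CORRELATION_VARIABLES)}
    latent = pd.DataFrame(z, columns=list(CORRELATION_VARIABLES))
    data = {}
    for v in CONTINUOUS_FIELDS:
        j = idx[v]
        loc0, scale, lo, hi = marginals[v]
        zw = z[:, j] - m[type_idx, j]           # within-type standard normal
        locs = loc0 + m[type_idx, j] * scale    # type-shifted location
        a = (lo - locs) / scale
        b = (hi - locs) / scale
        u = np.clip(stats.norm.cdf(zw), 1e-12, 1 - 1e-12)
        data[v] = stats.truncnorm.ppf(u, a, b, loc=locs, scale=scale)
    for k in STRAINS:
        data[k] = _discretise_mic(z[:, idx[k]])

    n = len(types)
    samples = pd.DataFrame({
        "sample_id": [f"H{i + 1:04d}" for i in range(n)],
        "floral_type": types,
        "country": rng.choice(_COUNTRIES, size=n),
        **data,
    })
    return samples, latent


def generate_samples(config: GeneratorConfig | None = None):
    """Validated :class:`HoneySample` records for the synthetic cohort."""
    frame, _ = generate_table(config)
    return frame_to_samples(frame)


def generate_from_network(
    weights: MLPWeights | None = None,
    norm: NormalizationSpec | None = None,
    n: int = 500,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Inputs uniform in the normalisation ranges, targets from the network.

    The target column is the network forward pass plus Gaussian noise of
    standard deviation ``noise_sd`` on the normalised output scale, then
    mapped back to the raw output scale. With ``noise_sd=0`` the targets
    equal the forward pass exactly. Supports training-recovery experiments.
    """
    from .ann import load_published_weights  # default lazily

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    weights = weights or load_published_weights()
    norm = norm or DEFAULT_NORMALIZATION
    rng = np.random.default_rng(seed)
    x_norm = rng.uniform(0.0, 1.0, (n, len(INPUT_ORDER)))
    y = forward(x_norm, weights)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    out = {}
    for i, v in enumerate(INPUT_ORDER):
        out[v] = norm.denormalize(x_norm[:, i], v)
    out[OUTPUT_NAME] = norm.denormalize(y, OUTPUT_NAME)
    return pd.DataFrame(out)[["free_acidity", "colour_L", "colour_a", OUTPUT_NAME]]
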