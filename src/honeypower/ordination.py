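"""Correlation-matrix PCA over the four analysis variables.

The study's ordination uses free acidity, the colour coordinates L* and a*,
and the Power of Honey. Variables carry incommensurate units, so the PCA is
run on the correlation matrix (standardised variables); per-component
variable contributions are the squared elements of the unit eigenvectors,
in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

PCA_VARIABLES = ("free_acidity", "colour_L", "colour_a", "power_of_honey")


@dataclass
class PCAResult:
    variable_names: tuple
    eigenvalues: np.ndarray        # descending
    explained_pct: np.ndarray      # sums to 100
    loadings: np.ndarray           # variable x component, eigvec * sqrt(eigval)
    contributions_pct: np.ndarray  # variable x component, columns sum to 100
    components: np.ndarray         # variable x component, orthonormal
    scores: np.ndarray | None = None  # sample x component


def pca_from_correlation(corr: np.ndarray, variable_names=None) -> PCAResult:
    """Eigen-decomposition of a correlation matrix, descending components.

    Sign convention: within each component the largest-magnitude loading is
    made positive.
    """
    c = np.asarray(corr, float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    names = tuple(variable_names) if variable_names is not None else tuple(
        f"v{i + 1}" for i in range(c.shape[0])
    )
    w, v = np.linalg.eigh((c + c.T) / 2)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    for j in range(v.shape[1]):
        k = np.argmax(np.abs(v[:, j]))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    explained = 100.0 * w / w.sum()
    loadings = v * np.sqrt(np.clip(w, 0.0, None))
    contributions = 100.0 * v ** 2
    return PCAResult(names, w, explained, loadings, contributions, v)


def run_pca(table: pd.DataFrame, variables=PCA_VARIABLES, standardize: bool = True) -> PCAResult:
    """PCA of a sample table over ``variables`` (correlation-based).

    Requires at least as many rows as variables and no constant column.
    With ``standardize=False`` the covariance matrix of the raw columns is
    decomposed instead (not the study's convention).
    """
    x = np.column_stack([np.asarray(table[v], float) for v in variables])
    n, p = x.shape
    if n < max(5, p):
        raise ValueError(f"too few rows for PCA: {n}")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed in PCA input")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant column(s): {bad}")
    centred = x - x.mean(axis=0)
    if standardize:
        z = centred / sd
        mat = (z.T @ z) / (n - 1)
    else:
        z = centred
        mat = np.cov(x.T, ddof=1)
    res = pca_from_correlation(mat, variables) if standardize else _pca_cov(mat, variables)
    res.scores = z @ res.components
    return res


def _pca_cov(cov, names):
    w, v = np.linalg.eigh(np.asarray(cov, float))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for j in range(v.shape[1]):
        k = np.argmax(np.abs(v[:, j]))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    return PCAResult(tuple(names), w, 100.0 * w / w.sum(),
                     v * np.sqrt(np.clip(w, 0, None)), 100.0 * v ** 2, v)


def summarize_groups(scores: np.ndarray, labels) -> pd.DataFrame:
    """Per-group centroid of PCA scores plus pairwise centroid distances.

    Returns a table with one row per group: label, n, pc1..pck centroids;
    the pairwise Euclidean centroid distances are attached as
    ``frame.attrs["pairwise_distances"]``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if len(labels) != scores.shape[0]:
        raise ValueError("labels must align with score rows")
    groups = list(dict.fromkeys(labels))
    rows = []
    cent = {}
    for g in groups:
        sub = scores[labels == g]
        cent[g] = sub.mean(axis=0)
        rows.append({"floral_type": g, "n": len(sub),
                     **{f"pc{j + 1}": c for j, c in enumerate(cent[g])}})
    frame = pd.DataFrame(rows)
    dists = {
        (a, b): float(np.linalg.norm(cent[a] - cent[b]))
        for a, b in combinations(groups, 2)
    }
    frame.attrs["pairwise_distances"] = dists
    return frame
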