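"""Logistic multilayer perceptron for predicting the Power of Honey.

The model is a 3-10-1 feed-forward network,

    y = f(W2 . f(W1' x + B1) + B2),      f(z) = 1 / (1 + exp(-z)),

with logistic activation in both the hidden and output layer, mapping
min-max normalised free acidity and CIE L*, a* colour coordinates to the
normalised composite health index. The exact published weight tables are
embedded and loadable bit-for-bit; alternatively the network can be
retrained on any table by quasi-Newton (BFGS) minimisation of the
sum-of-squares error with a 60/20/20 train/validation/test split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

#: Input variables in network order (weight-matrix row order).
INPUT_ORDER = ("colour_L", "colour_a", "free_acidity")
OUTPUT_NAME = "power_of_honey"

# Published hidden-layer weights, one row per input (L*, a*, free acidity),
# one column per hidden neuron, and the hidden bias vector.
_W1_PUBLISHED = [
    [-5.138, 13.497, 4.866, 21.350, 7.121, 6.577, 2.363, 3.858, 22.490, 6.662],
    [-3.305, 8.452, 2.709, 13.619, 4.459, 4.378, -0.368, 3.155, 14.139, 4.294],
    [0.015, -0.248, 0.105, -0.531, -0.236, -0.139, -0.312, -0.225, -0.741, -0.243],
]
_B1_PUBLISHED = [0.038, -0.032, 0.251, -0.054, -0.253, 0.176, 1.099, -0.564, -0.196, 0.045]
# Published output-layer weights (one per hidden neuron) and output bias.
_W2_PUBLISHED = [1.716, -12.843, -29.156, -28.476, -15.307, 43.337, -3.580, 10.276, 28.519, 12.963]
_B2_PUBLISHED = -4.963


class DegenerateRangeError(ValueError):
    """A variable has max == min, so a min-max map is undefined."""


@dataclass
class MLPWeights:
    """Weights of an n_in -> n_hidden -> 1 logistic network."""

    w1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    input_names: tuple = INPUT_ORDER

    def __post_init__(self):
        self.w1 = np.atleast_2d(np.asarray(self.w1, float))
        self.b1 = np.asarray(self.b1, float).ravel()
        self.w2 = np.asarray(self.w2, float).ravel()
        self.b2 = float(self.b2)
        n_in, n_hidden = self.w1.shape
        if self.b1.shape != (n_hidden,) or self.w2.shape != (n_hidden,):
            raise ValueError(
                f"inconsistent shapes: w1 {self.w1.shape}, b1 {self.b1.shape}, "
                f"w2 {self.w2.shape}"
            )
        if not (np.isfinite(self.w1).all() and np.isfinite(self.b1).all()
                and np.isfinite(self.w2).all() and np.isfinite(self.b2)):
            raise ValueError("weights must be finite")

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[1]


def load_published_weights() -> MLPWeights:
    """The 3-10-1 network exactly as printed (51 parameters)."""
    return MLPWeights(_W1_PUBLISHED, _B1_PUBLISHED, _W2_PUBLISHED, _B2_PUBLISHED)


def count_parameters(weights: MLPWeights) -> int:
    """Total weight-and-bias count: |W1| + |B1| + |W2| + |B2|."""
    return weights.w1.size + weights.b1.size + weights.w2.size + 1


@dataclass
class NormalizationSpec:
    """Per-variable raw min/max defining the min-max map onto [0, 1]."""

    bounds: dict  # name -> (min, max)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise DegenerateRangeError(f"{name}: max ({hi}) must exceed min ({lo})")

    @classmethod
    def from_table(cls, table: pd.DataFrame, variables) -> "NormalizationSpec":
        bounds = {}
        for v in variables:
            lo, hi = float(table[v].min()), float(table[v].max())
            if not hi > lo:
                raise DegenerateRangeError(f"{v}: max ({hi}) must exceed min ({lo})")
            bounds[v] = (lo, hi)
        return cls(bounds)

    def normalize(self, values, name: str):
        lo, hi = self.bounds[name]
        return (np.asarray(values, float) - lo) / (hi - lo)

    def denormalize(self, values, name: str):
        lo, hi = self.bounds[name]
        return lo + np.asarray(values, float) * (hi - lo)

    def span(self, name: str) -> float:
        lo, hi = self.bounds[name]
        return hi - lo


#: Default normalisation for the published network. The original study's
#: normalisation ranges were not published, so these are the synthetic
#: generator's nominal ranges -- NON-canonical: predictions made with the
#: published weights through this spec are on a plausible but arbitrary
#: absolute scale.
DEFAULT_NORMALIZATION = NormalizationSpec({
    "colour_L": (15.0, 95.0),
    "colour_a": (-8.0, 15.0),
    "free_acidity": (1.0, 55.0),
    OUTPUT_NAME: (0.0, 1.0),
})


def logistic(z):
    """Overflow-safe elementwise logistic."""
    z = np.asarray(z, float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def forward_hidden(x_norm, weights: MLPWeights):
    """(output, hidden activations) for one normalised input or a batch."""
    x = np.asarray(x_norm, float)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    if xb.shape[1] != weights.n_inputs:
        raise ValueError(f"expected {weights.n_inputs} inputs, got {xb.shape[1]}")
    h = logistic(xb @ weights.w1 + weights.b1)
    y = logistic(h @ weights.w2 + weights.b2)
    if single:
        return float(y[0]), h[0]
    return y, h


def forward(x_norm, weights: MLPWeights):
    """Normalised network output, strictly inside (0, 1) for finite inputs."""
    y, _ = forward_hidden(x_norm, weights)
    return y


@dataclass
class SplitSpec:
    """Random 60/20/20 train/validation/test partition."""

    fractions: tuple = (0.60, 0.20, 0.20)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("split fractions must sum to 1")


def _largest_remainder_sizes(n: int, fractions) -> list:
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    for i in sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True):
        if sum(sizes) == n:
            break
        sizes[i] += 1
    return sizes


def split_data(table: pd.DataFrame, spec: SplitSpec):
    """Disjoint exhaustive (train, validation, test) row partition."""
    n = len(table)
    if n < 5:
        raise ValueError(f"too few rows to split: {n} < 5")
    sizes = _largest_remainder_sizes(n, spec.fractions)
    perm = np.random.default_rng(spec.seed).permutation(n)
    parts = []
    start = 0
    for s in sizes:
        parts.append(table.iloc[perm[start:start + s]])
        start += s
    return tuple(parts)


def evaluate(predictions, observations):
    """(r2, sos): coefficient of determination and raw sum of squares."""
    p = np.asarray(predictions, float)
    o = np.asarray(observations, float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("predictions/observations must be equal-length, n >= 2")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise DegenerateRangeError("observations have zero variance")
    sos = float(((p - o) ** 2).sum())
    return 1.0 - sos / ss_tot, sos


@dataclass
class FitReport:
    """Per-split fit quality of a trained network (normalised scale)."""

    r2: dict          # split name -> r^2
    sos: dict         # split name -> sum of squares
    n_iterations: int
    converged: bool
    n_restarts: int = 1

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "sos": self.sos,
            "n_iterations": self.n_iterations,
            "converged": self.converged, "n_restarts": self.n_restarts,
        }


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta, n_in, n_hidden):
    i = n_in * n_hidden
    w1 = theta[:i].reshape(n_in, n_hidden)
    b1 = theta[i:i + n_hidden]
    w2 = theta[i + n_hidden:i + 2 * n_hidden]
    return w1, b1, w2, theta[i + 2 * n_hidden]


def _sos_and_grad(theta, X, y, n_in, n_hidden):
    w1, b1, w2, b2 = _unpack(theta, n_in, n_hidden)
    h = logistic(X @ w1 + b1)
    yhat = logistic(h @ w2 + b2)
    r = yhat - y
    dz2 = 2.0 * r * yhat * (1.0 - yhat)
    dh = np.outer(dz2, w2) * h * (1.0 - h)
    grad = _pack(X.T @ dh, dh.sum(axis=0), h.T @ dz2, dz2.sum())
    return float(r @ r), grad


def train(
    table: pd.DataFrame,
    n_hidden: int = 10,
    split: SplitSpec | None = None,
    restarts: int = 10,
    max_iter: int = 400,
    gtol: float = 1e-8,
    init_scale: float = 0.5,
    seed: int = 0,
    early_stopping: bool = True,
):
    """Fit the logistic MLP by BFGS sum-of-squares minimisation.

    The table must carry free_acidity, colour_L, colour_a and
    power_of_honey columns. Variables are min-max normalised over the full
    table; the best of ``restarts`` seeded random initialisations (uniform
    in [-init_scale, init_scale]) is selected by validation SOS.

    With ``early_stopping`` (default) the returned weights are the iterate
    along each BFGS trajectory with the lowest validation SOS, not
    necessarily the final one — with 51 parameters and a small table the
    fully converged network badly overfits the training split.

    Returns (MLPWeights, NormalizationSpec, FitReport).
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if len(table) < 20:
        raise ValueError(f"too few rows to train: {len(table)} < 20")
    if split is None:
        split = SplitSpec(seed=seed)
    cols = list(INPUT_ORDER) + [OUTPUT_NAME]
    norm = NormalizationSpec.from_table(table, cols)
    if float(table[OUTPUT_NAME].std()) == 0.0:
        raise DegenerateRangeError("target has zero variance")

    parts = split_data(table[cols].reset_index(drop=True), split)
    mats = []
    for part in parts:
        X = np.column_stack([norm.normalize(part[v], v) for v in INPUT_ORDER])
        y = np.asarray(norm.normalize(part[OUTPUT_NAME], OUTPUT_NAME))
        mats.append((X, y))
    (Xtr, ytr), (Xva, yva), (Xte, yte) = mats

    rng = np.random.default_rng(seed)
    n_par = 3 * n_hidden + 2 * n_hidden + 1
    def val_sos_of(theta):
        w = MLPWeights(*_unpack(theta, 3, n_hidden))
        return float(((forward(Xva, w) - yva) ** 2).sum()), w

    best = None  # (val_sos, weights, res, n_iter_selected)
    for _ in range(max(1, restarts)):
        theta0 = rng.uniform(-init_scale, init_scale, n_par)
        trajectory = []
        res = minimize(
            _sos_and_grad, theta0, args=(Xtr, ytr, 3, n_hidden),
            jac=True, method="BFGS", options={"maxiter": max_iter, "gtol": gtol},
            callback=(trajectory.append if early_stopping else None),
        )
        candidates = trajectory + [res.x] if early_stopping else [res.x]
        for k, theta in enumerate(candidates, start=1):
            val_sos, w = val_sos_of(theta)
            if best is None or val_sos < best[0]:
                best = (val_sos, w, res, k)
    _, weights, res, n_iter_sel = best
    if not early_stopping and not res.success:
        warnings.warn(
            f"BFGS did not converge within {max_iter} iterations "
            f"(status {res.status}); best iterate returned", RuntimeWarning,
        )

    r2s, soss = {}, {}
    for name, (X, y) in zip(("train", "validation", "test"), mats):
        r2s[name], soss[name] = evaluate(forward(X, weights), y)
    report = FitReport(r2s, soss, int(n_iter_sel), bool(res.success), max(1, restarts))
    return weights, norm, report


def predict_power(rows, weights: MLPWeights, norm: NormalizationSpec):
    """Raw-scale Power of Honey predictions for raw-scale input rows.

    ``rows``: DataFrame with free_acidity/colour_L/colour_a columns, or an
    array in network input order. Inputs outside the normalisation range
    trigger an extrapolation warning, not an error.
    """
    if isinstance(rows, pd.DataFrame):
        X = np.column_stack([np.asarray(rows[v], float) for v in INPUT_ORDER])
    else:
        X = np.atleast_2d(np.asarray(rows, float))
    Xn = np.column_stack([norm.normalize(X[:, i], v) for i, v in enumerate(INPUT_ORDER)])
    if ((Xn < 0) | (Xn > 1)).any():
        warnings.warn(
            "inputs outside the normalisation range; predictions are "
            "extrapolations", UserWarning,
        )
    y = forward(Xn, weights)
    return norm.denormalize(y, OUTPUT_NAME)


def save_model(path, weights: MLPWeights, norm: NormalizationSpec, metadata: dict | None = None):
    """Serialise weights + normalisation as a JSON document."""
    doc = {
        "input_order": list(weights.input_names),
        "w1": weights.w1.tolist(),
        "b1": weights.b1.tolist(),
        "w2": weights.w2.tolist(),
        "b2": weights.b2,
        "normalization": {k: list(v) for k, v in norm.bounds.items()},
        "n_parameters": count_parameters(weights),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path):
    """Load a model JSON document; validates shapes and parameter count."""
    doc = json.loads(Path(path).read_text())
    weights = MLPWeights(
        doc["w1"], doc["b1"], doc["w2"], doc["b2"],
        input_names=tuple(doc["input_order"]),
    )
    if count_parameters(weights) != doc["n_parameters"]:
        raise ValueError(
            f"parameter count mismatch: file says {doc['n_parameters']}, "
            f"weights have {count_parameters(weights)}"
        )
    norm = NormalizationSpec({k: tuple(v) for k, v in doc["normalization"].items()})
    return weights, norm
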