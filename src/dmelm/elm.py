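"""Extreme learning machine: random hidden layer, closed-form output weights.

A single-hidden-layer feedforward network f(x) = Σ_i v_i h(w_i·x + β_i)
whose hidden parameters (w, β) are drawn at random and never trained; the
output weights v are the least-squares solution of M v = Y, where M is the
hidden-layer activation matrix and Y the one-hot class targets.  Ten
activation functions are supported, split by dialect:

* projection family (argument is w_i·x + β_i): sine, tanh, tribas,
  inv_tribas, sigmoid, hardlim, softlim;
* distance family (argument is ‖x − c_i‖/σ_i, a radial-basis construct):
  gaussian, multiquadric, inv_multiquadric.

The API follows the statsmodels convention: ``ELM(X, y, **config).fit()``
returns an :class:`ELMResults` carrying the learned weights, diagnostics
and prediction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "PROJECTION_KINDS",
    "DISTANCE_KINDS",
    "ACTIVATION_KINDS",
    "ActivationSpec",
    "ELMConfig",
    "HiddenLayer",
    "activation_value",
    "init_hidden",
    "hidden_matrix",
    "solve_output_weights",
    "ELM",
    "ELMResults",
]

PROJECTION_KINDS: tuple[str, ...] = (
    "sine",
    "tanh",
    "tribas",
    "inv_tribas",
    "sigmoid",
    "hardlim",
    "softlim",
)
DISTANCE_KINDS: tuple[str, ...] = ("gaussian", "multiquadric", "inv_multiquadric")
ACTIVATION_KINDS: tuple[str, ...] = PROJECTION_KINDS + DISTANCE_KINDS


@dataclass(frozen=True)
class ActivationSpec:
    """An activation function and, for the distance family, its shape c > 0."""

    kind: str = "multiquadric"
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ACTIVATION_KINDS:
            raise ValueError(
                f"unknown activation {self.kind!r}; expected one of {ACTIVATION_KINDS}"
            )
        if not self.c > 0:
            raise ValueError("shape constant c must be > 0")

    @property
    def family(self) -> str:
        return "distance" if self.kind in DISTANCE_KINDS else "projection"


def _activation_fn(spec: ActivationSpec) -> Callable[[np.ndarray], np.ndarray]:
    c = spec.c
    table: dict[str, Callable[[np.ndarray], np.ndarray]] = {
        "sine": np.sin,
        "tanh": np.tanh,
        "tribas": lambda a: np.maximum(0.0, 1.0 - np.abs(a)),
        "inv_tribas": lambda a: 1.0 - np.maximum(0.0, 1.0 - np.abs(a)),
        "sigmoid": lambda a: 1.0 / (1.0 + np.exp(-a)),
        "hardlim": lambda a: (a > 0).astype(float),
        "softlim": lambda a: np.clip(a, 0.0, 1.0),
        "gaussian": lambda d: np.exp(-(d**2)),
        "multiquadric": lambda d: np.sqrt(d**2 + c**2),
        "inv_multiquadric": lambda d: 1.0 / np.sqrt(d**2 + c**2),
    }
    return table[spec.kind]


def activation_value(spec: ActivationSpec | str, a: float | np.ndarray):
    """Evaluate the activation at ``a`` (a projection value or a distance)."""
    if isinstance(spec, str):
        spec = ActivationSpec(spec)
    return _activation_fn(spec)(np.asarray(a, dtype=float))


@dataclass
class ELMConfig:
    """ELM hyperparameters.

    ``n_hidden`` defaults to 500 hidden units in a single hidden layer;
    ``ridge`` = 0 selects the minimum-norm pseudoinverse solution,
    otherwise Tikhonov-regularized normal equations are solved.
    """

    n_hidden: int = 500
    activation: ActivationSpec = field(default_factory=ActivationSpec)
    weight_scale: float = 1.0
    ridge: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.activation, str):
            self.activation = ActivationSpec(self.activation)
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if not self.weight_scale >= 0:
            raise ValueError("weight_scale must be >= 0")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass
class HiddenLayer:
    """Frozen random hidden parameters.

    Projection family: ``weights`` (H x d) and ``biases`` (H).  Distance
    family: ``centers`` (H x d) and per-unit ``widths`` (H).
    """

    activation: ActivationSpec
    weights: np.ndarray | None = None
    biases: np.ndarray | None = None
    centers: np.ndarray | None = None
    widths: np.ndarray | None = None

    @property
    def n_hidden(self) -> int:
        p = self.weights if self.weights is not None else self.centers
        return 0 if p is None else p.shape[0]

    @property
    def n_features(self) -> int:
        p = self.weights if self.weights is not None else self.centers
        return 0 if p is None else p.shape[1]


def init_hidden(
    config: ELMConfig,
    n_features: int,
    data_ranges: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> HiddenLayer:
    """Draw the random hidden parameters.

    Projection family: weights and biases ~ U(−weight_scale, +weight_scale).
    Distance family: centers uniform inside the per-feature (min, max) box
    of the training data, widths set to the median pairwise distance among
    the centers so normalized distances are O(1); a degenerate box (all
    features constant) falls back to width 1.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    act = config.activation
    H = config.n_hidden
    if act.family == "projection":
        s = config.weight_scale
        weights = rng.uniform(-s, s, size=(H, n_features))
        biases = rng.uniform(-s, s, size=H)
        return HiddenLayer(activation=act, weights=weights, biases=biases)
    if data_ranges is None:
        lo = -np.ones(n_features)
        hi = np.ones(n_features)
    else:
        lo = np.asarray(data_ranges[0], dtype=float)
        hi = np.asarray(data_ranges[1], dtype=float)
    centers = rng.uniform(lo, hi, size=(H, n_features))
    m = min(H, 100)
    sub = centers[:m]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    pair = np.sqrt(d2[np.triu_indices(m, k=1)]) if m > 1 else np.array([])
    scale = float(np.median(pair)) if pair.size else 0.0
    if scale <= 0:
        scale = 1.0
    widths = np.full(H, scale)
    return HiddenLayer(activation=act, centers=centers, widths=widths)


def hidden_matrix(hidden: HiddenLayer, X: np.ndarray) -> np.ndarray:
    """N x H matrix of hidden-unit outputs, M[j, i] = h(unit_i applied to x_j)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != hidden.n_features:
        raise ValueError(
            f"X has shape {X.shape}; expected (*, {hidden.n_features})"
        )
    fn = _activation_fn(hidden.activation)
    if hidden.activation.family == "projection":
        return fn(X @ hidden.weights.T + hidden.biases)
    diff = X[:, None, :] - hidden.centers[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1)) / hidden.widths
    return fn(dist)


def solve_output_weights(M: np.ndarray, Y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Closed-form output weights.

    ridge = 0: minimum-norm least squares, v = pinv(M)·Y; otherwise
    v = (MᵀM + ridge·I)⁻¹ Mᵀ Y.
    """
    if ridge == 0.0:
        v, *_ = np.linalg.lstsq(M, Y, rcond=None)
        return v
    H = M.shape[1]
    return np.linalg.solve(M.T @ M + ridge * np.eye(H), M.T @ Y)


class ELM:
    """Extreme learning machine classifier model.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
        Training inputs; must be finite.
    y : sequence
        Class labels; at least two distinct values.
    config : ELMConfig, optional
        Hyperparameters; keyword arguments override individual fields.

    Examples
    --------
    >>> results = ELM(X, y, n_hidden=100, activation="sine", seed=0).fit()
    >>> results.predict(X_new)
    """

    def __init__(self, X, y, config: ELMConfig | None = None, **kwargs):
        self.exog = np.asarray(X, dtype=float)
        if self.exog.ndim != 2:
            raise ValueError("X must be two-dimensional (samples x features)")
        if not np.all(np.isfinite(self.exog)):
            raise ValueError("X contains non-finite values")
        if self.exog.shape[0] < 2:
            raise ValueError("need at least two training samples")
        self.endog = np.asarray(y)
        if len(self.endog) != self.exog.shape[0]:
            raise ValueError("X and y have different lengths")
        self.class_names = tuple(sorted(np.unique(self.endog).tolist()))
        if len(self.class_names) < 2:
            raise ValueError("need at least two distinct classes")
        if config is None:
            config = ELMConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either config or keyword overrides, not both")
        self.config = config

    def _one_hot(self) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.class_names)}
        Y = np.zeros((len(self.endog), len(self.class_names)))
        for j, label in enumerate(self.endog):
            Y[j, index[label]] = 1.0
        return Y

    def fit(self, hidden: HiddenLayer | None = None) -> "ELMResults":
        """Draw the hidden layer (unless injected) and solve for v."""
        if hidden is None:
            ranges = (self.exog.min(axis=0), self.exog.max(axis=0))
            hidden = init_hidden(
                self.config,
                self.exog.shape[1],
                data_ranges=ranges,
                rng=np.random.default_rng(self.config.seed),
            )
        M = hidden_matrix(hidden, self.exog)
        v = solve_output_weights(M, self._one_hot(), self.config.ridge)
        if not np.all(np.isfinite(v)):
            raise ValueError("output weights are non-finite; check the inputs")
        return ELMResults(model=self, hidden=hidden, output_weights=v)


@dataclass
class ELMResults:
    """A fitted ELM: hidden layer, output weights, prediction, diagnostics."""

    model: ELM
    hidden: HiddenLayer
    output_weights: np.ndarray

    @property
    def class_names(self) -> tuple:
        return self.model.class_names

    def predict_scores(self, X) -> np.ndarray:
        """Network outputs, one column per class (class order = sorted labels)."""
        return hidden_matrix(self.hidden, np.asarray(X, dtype=float)) @ self.output_weights

    def predict(self, X) -> np.ndarray:
        """Argmax class per row; ties go to the first class in sorted order."""
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.array([], dtype=object)
        idx = np.argmax(self.predict_scores(X), axis=1)
        return np.array([self.class_names[i] for i in idx], dtype=object)

    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.exog) == self.model.endog))

    def normal_equation_residual(self) -> float:
        """‖Mᵀ(Mv − Y)‖∞ on the training data; ~0 at the ridge-0 optimum."""
        M = hidden_matrix(self.hidden, self.model.exog)
        r = M.T @ (M @ self.output_weights - self.model._one_hot())
        return float(np.max(np.abs(r)))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Extreme Learning Machine Results",
            "=" * 40,
            f"n_samples:           {self.model.exog.shape[0]}",
            f"n_features:          {self.model.exog.shape[1]}",
            f"classes:             {', '.join(map(str, self.class_names))}",
            f"hidden units:        {self.hidden.n_hidden}",
            f"activation:          {self.hidden.activation.kind}"
            f" ({self.hidden.activation.family})",
            f"ridge:               {cfg.ridge:g}",
            f"training accuracy:   {self.training_accuracy():.4f}",
            f"normal-eq residual:  {self.normal_equation_residual():.3e}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Save as a self-describing .npz archive (arrays + metadata)."""
        act = self.hidden.activation
        arrays = dict(
            output_weights=self.output_weights,
            class_names=np.array([str(c) for c in self.class_names]),
            activation_kind=np.array(act.kind),
            activation_c=np.array(act.c),
        )
        if self.hidden.activation.family == "projection":
            arrays.update(weights=self.hidden.weights, biases=self.hidden.biases)
        else:
            arrays.update(centers=self.hidden.centers, widths=self.hidden.widths)
        np.savez(path, **arrays)

    @staticmethod
    def load_predictor(path: str | Path) -> "ELMPredictor":
        return ELMPredictor.load(path)


@dataclass
class ELMPredictor:
    """Prediction-only view restored from a saved archive."""

    hidden: HiddenLayer
    output_weights: np.ndarray
    class_names: tuple

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.array([], dtype=object)
        scores = hidden_matrix(self.hidden, X) @ self.output_weights
        idx = np.argmax(scores, axis=1)
        return np.array([self.class_names[i] for i in idx], dtype=object)

    @staticmethod
    def load(path: str | Path) -> "ELMPredictor":
        with np.load(path, allow_pickle=False) as z:
            act = ActivationSpec(str(z["activation_kind"]), float(z["activation_c"]))
            if act.family == "projection":
                hidden = HiddenLayer(
                    activation=act, weights=z["weights"], biases=z["biases"]
                )
            else:
                hidden = HiddenLayer(
                    activation=act, centers=z["centers"], widths=z["widths"]
                )
            return ELMPredictor(
                hidden=hidden,
                output_weights=z["output_weights"],
                class_names=tuple(z["class_names"].tolist()),
            )
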