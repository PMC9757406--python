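"""The DM-ELM hybrid: moth-flame search over ELM parameters.

The optimizer minimizes 1 − (mean stratified k-fold CV accuracy) of the
ELM induced by a candidate parameter vector.  Fold assignment and the
ELM's random hidden layer are frozen when the objective is created, so
the objective is a deterministic function of the position and the search
is reproducible from its seed.

Two readings of "the parameters of the classifier" are implemented:

* ``feature_scaling`` (default) — one multiplicative weight per input
  feature (30 features -> a 30-dimensional search space).  The identity
  vector (all ones) reproduces the plain ELM exactly, and one moth is
  seeded there, so by elitism the hybrid's frozen-fold objective can
  never be worse than the plain ELM's.
* ``input_weights`` — the position encodes the hidden weights and biases
  of a reduced network of ``n_hidden_search`` units directly, replacing
  the random draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .elm import ELM, ELMConfig, ELMResults, HiddenLayer, init_hidden
from .evaluation import confusion, metrics, split_table, stratified_folds
from .mfo import MFOConfig, OptimizationResult, optimize

__all__ = ["DMELMConfig", "DMELM", "DMELMResults", "apply_parameters", "make_objective"]

SEARCH_MODES = ("feature_scaling", "input_weights")


@dataclass
class DMELMConfig:
    """Hybrid settings: an MFO search wrapped around a cross-validated ELM."""

    mfo: MFOConfig = None  # dimension is derived from the data if omitted
    elm: ELMConfig = field(default_factory=ELMConfig)
    cv_folds: int = 10
    search_mode: str = "feature_scaling"
    n_hidden_search: int = 16  # reduced hidden size for input_weights mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.search_mode not in SEARCH_MODES:
            raise ValueError(f"search_mode must be one of {SEARCH_MODES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_hidden_search < 1:
            raise ValueError("n_hidden_search must be >= 1")

    def search_dimension(self, n_features: int) -> int:
        if self.search_mode == "feature_scaling":
            return n_features
        return self.n_hidden_search * (n_features + 1)

    def resolved_mfo(self, n_features: int) -> MFOConfig:
        """The MFO config with the dimension the search mode requires."""
        D = self.search_dimension(n_features)
        if self.mfo is None:
            return MFOConfig(
                n_agents=50,
                dimension=D,
                lower_bound=-1.0,
                upper_bound=1.0,
                max_iterations=1000,
                seed=self.seed,
            )
        if self.mfo.dimension != D:
            raise ValueError(
                f"mfo.dimension={self.mfo.dimension} inconsistent with "
                f"{self.search_mode} mode ({D} expected for {n_features} features)"
            )
        return self.mfo


def apply_parameters(
    position: np.ndarray, X: np.ndarray, config: DMELMConfig
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Interpret a search position.

    feature_scaling: returns X with column j multiplied by position[j].
    input_weights: returns the (H' x d weights, H' biases) the position
    encodes; the reshape is the exact inverse of flattening.
    """
    position = np.asarray(position, dtype=float)
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if config.search_mode == "feature_scaling":
        if position.shape != (d,):
            raise ValueError(f"position has shape {position.shape}; expected ({d},)")
        return X * position
    H = config.n_hidden_search
    if position.shape != (H * (d + 1),):
        raise ValueError(
            f"position has length {position.size}; expected {H * (d + 1)}"
        )
    weights = position[: H * d].reshape(H, d)
    biases = position[H * d :]
    return weights, biases


def _fit_under_position(
    position: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: DMELMConfig,
) -> ELMResults:
    if config.search_mode == "feature_scaling":
        Xt = apply_parameters(position, X, config)
        return ELM(Xt, y, config=config.elm).fit()
    weights, biases = apply_parameters(position, X, config)
    cfg = ELMConfig(
        n_hidden=config.n_hidden_search,
        activation=config.elm.activation,
        weight_scale=config.elm.weight_scale,
        ridge=config.elm.ridge,
        seed=config.elm.seed,
    )
    hidden = HiddenLayer(activation=cfg.activation, weights=weights, biases=biases)
    if cfg.activation.family == "distance":
        # positions encode projections; distance activations keep their
        # random centers and only make sense in feature_scaling mode
        raise ValueError("input_weights mode requires a projection activation")
    return ELM(X, y, config=cfg).fit(hidden=hidden)


def make_objective(
    table: pd.DataFrame, config: DMELMConfig
) -> Callable[[np.ndarray], float]:
    """Build the frozen-fold CV objective: position -> 1 − mean accuracy."""
    X, y, _ = split_table(table)
    folds = stratified_folds(y, config.cv_folds, config.seed)
    class_names = tuple(sorted(np.unique(y).tolist()))

    def objective(position: np.ndarray) -> float:
        accs = []
        for train_idx, test_idx in folds:
            res = _fit_under_position(position, X[train_idx], y[train_idx], config)
            if config.search_mode == "feature_scaling":
                Xt_test = apply_parameters(position, X[test_idx], config)
            else:
                Xt_test = X[test_idx]
            pred = res.predict(Xt_test)
            accs.append(metrics(confusion(y[test_idx], pred, class_names)).accuracy)
        return 1.0 - float(np.mean(accs))

    return objective


class DMELM:
    """Moth-flame-optimized ELM classifier model.

    Built from a feature table (sample x feature DataFrame with a
    ``label`` column); ``fit()`` runs the MFO search and refits a final
    ELM on the full table under the best parameters.

    Examples
    --------
    >>> model = DMELM(table, cv_folds=5, seed=0,
    ...               mfo=MFOConfig(n_agents=10, dimension=30,
    ...                             lower_bound=-1, upper_bound=1,
    ...                             max_iterations=20))
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(self, table: pd.DataFrame, config: DMELMConfig | None = None, **kwargs):
        if config is None:
            config = DMELMConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either config or keyword overrides, not both")
        self.table = table
        self.config = config
        X, y, feature_cols = split_table(table)
        self.exog = X
        self.endog = y
        self.feature_names = feature_cols
        self.objective = make_objective(table, config)

    def identity_position(self) -> np.ndarray:
        """The position reproducing the plain ELM (feature_scaling only)."""
        if self.config.search_mode != "feature_scaling":
            raise ValueError("identity position exists only in feature_scaling mode")
        return np.ones(self.exog.shape[1])

    def baseline_objective(self) -> float:
        """Plain-ELM frozen-fold objective (identity scaling)."""
        return self.objective(self.identity_position())

    def fit(self) -> "DMELMResults":
        cfg = self.config
        mfo_cfg = cfg.resolved_mfo(self.exog.shape[1])
        seeds = (
            [self.identity_position()] if cfg.search_mode == "feature_scaling" else None
        )
        opt = optimize(self.objective, mfo_cfg, initial_positions=seeds)
        final = _fit_under_position(opt.best_position, self.exog, self.endog, cfg)
        return DMELMResults(model=self, optimization=opt, fitted_elm=final)


@dataclass
class DMELMResults:
    """Search outcome plus the final ELM refit under the best parameters."""

    model: DMELM
    optimization: OptimizationResult
    fitted_elm: ELMResults

    @property
    def best_parameters(self) -> np.ndarray:
        return self.optimization.best_position

    @property
    def trace(self) -> np.ndarray:
        return self.optimization.trace

    def cv_accuracy(self) -> float:
        """Mean frozen-fold CV accuracy under the best parameters."""
        return 1.0 - self.optimization.best_fitness

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.array([], dtype=object)
        if self.model.config.search_mode == "feature_scaling":
            X = apply_parameters(self.best_parameters, X, self.model.config)
        return self.fitted_elm.predict(X)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "DM-ELM Results (moth-flame-optimized ELM)",
            "=" * 45,
            f"search mode:            {cfg.search_mode}",
            f"search dimension:       {len(self.best_parameters)}",
            f"cv folds:               {cfg.cv_folds}",
            f"activation:             {cfg.elm.activation.kind}",
            f"hidden units:           {cfg.elm.n_hidden}",
            f"objective evaluations:  {self.optimization.evaluations}",
            f"plain-ELM CV accuracy:  {1.0 - self.model.baseline_objective():.4f}"
            if cfg.search_mode == "feature_scaling"
            else "plain-ELM CV accuracy:  n/a",
            f"DM-ELM CV accuracy:     {self.cv_accuracy():.4f}",
        ]
        return "\n".join(lines)
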