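"""Hybrid decision heads on deep features: ELM plus shallow classifiers.

The extreme learning machine (ELM) is a single-hidden-layer feedforward
network whose hidden projection is drawn once at random and never trained;
only the linear output weights are fitted, in closed form, by ridge
regression against one-hot targets:

    H = act(X W^T + b),   beta = (H^T H + lambda I)^{-1} H^T Y .

That closed form is the whole appeal — no gradient descent, a single
linear solve.  The ELM here is implemented from scratch; the other decision
heads (k-NN, SVM, random forest, gradient-boosted trees) are thin adapters
over scikit-learn and xgboost behind one fit/predict contract, with a grid
search for hyperparameter selection on a stratified validation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np

__all__ = [
    "ELMModel",
    "elm_fit",
    "elm_predict",
    "fit_shallow",
    "predict_shallow",
    "GridSearchSpec",
    "GridSearchResult",
    "grid_search",
    "HEAD_KINDS",
]

HEAD_KINDS = ("elm", "knn", "svm", "rf", "xgb")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": _sigmoid,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class ELMModel:
    """A fitted ELM: frozen random projection plus ridge output weights."""

    input_weights: np.ndarray  # (L, D)
    biases: np.ndarray  # (L,)
    beta: np.ndarray  # (L, K)
    activation: str
    ridge: float
    n_classes: int
    seed: int

    @property
    def hidden_width(self) -> int:
        return self.input_weights.shape[0]


def _hidden(x: np.ndarray, w: np.ndarray, b: np.ndarray, activation: str):
    return _ACTIVATIONS[activation](x @ w.T + b)


def elm_fit(
    features: np.ndarray,
    labels: np.ndarray,
    hidden_width: int = 1000,
    ridge: float = 1e-3,
    activation: str = "sigmoid",
    seed: int = 0,
    n_classes: int | None = None,
) -> ELMModel:
    """Fit an ELM by the regularized closed form.

    Input weights and biases are drawn once from uniform(-1, 1) under
    ``seed``; ``beta`` solves the ridge normal equations
    ``(H^T H + lambda I) beta = H^T Y`` with one-hot ``Y``.  With
    ``ridge=0`` an ill-conditioned system falls back to the Moore-Penrose
    pseudoinverse with a warning.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    if hidden_width < 1:
        raise ValueError("hidden width must be >= 1")
    if ridge < 0:
        raise ValueError("ridge strength must be >= 0")
    k = int(n_classes if n_classes is not None else y.max() + 1)
    n, d = x.shape
    if n < k:
        raise ValueError(f"need at least as many samples ({n}) as classes ({k})")
    if k < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(hidden_width, d))
    b = rng.uniform(-1.0, 1.0, size=hidden_width)
    h = _hidden(x, w, b, activation)
    onehot = np.eye(k)[y]
    gram = h.T @ h + ridge * np.eye(hidden_width)
    rhs = h.T @ onehot
    if ridge == 0 and (
        not np.all(np.isfinite(gram)) or np.linalg.cond(gram) > 1e12
    ):
        warnings.warn(
            "unregularized ELM system is ill-conditioned; "
            "falling back to the pseudoinverse",
            RuntimeWarning,
        )
        beta = np.linalg.pinv(h) @ onehot
    else:
        try:
            beta = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular ELM normal equations; falling back to the "
                "pseudoinverse",
                RuntimeWarning,
            )
            beta = np.linalg.pinv(h) @ onehot
    return ELMModel(w, b, beta, activation, float(ridge), k, seed)


def elm_predict(model: ELMModel, features: np.ndarray):
    """Predict labels and raw class scores: ``act(X W^T + b) beta``.

    Ties in the score argmax resolve to the lowest class index.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != model.input_weights.shape[1]:
        raise ValueError(
            f"expected features of dim {model.input_weights.shape[1]}, "
            f"got shape {x.shape}"
        )
    scores = _hidden(x, model.input_weights, model.biases, model.activation) @ model.beta
    return scores.argmax(axis=1), scores


class _ELMAdapter:
    """fit/predict wrapper so the ELM joins the uniform head contract."""

    def __init__(self, **params):
        self.params = params
        self.model: ELMModel | None = None

    def fit(self, x, y):
        self.model = elm_fit(x, y, **self.params)
        return self

    def predict(self, x):
        labels, _ = elm_predict(self.model, x)
        return labels


def _make_head(kind: str, params: dict[str, Any], seed: int):
    if kind == "elm":
        return _ELMAdapter(seed=seed, **params)
    if kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(**{"n_neighbors": 5, **params})
    if kind == "svm":
        from sklearn.svm import SVC

        return SVC(**{"kernel": "rbf", "C": 1.0, **params, "random_state": seed})
    if kind == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            **{"n_estimators": 100, **params, "random_state": seed}
        )
    if kind == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            **{
                "n_estimators": 100,
                "max_depth": 6,
                "learning_rate": 0.3,
                "verbosity": 0,
                **params,
                "random_state": seed,
            }
        )
    raise ValueError(f"unknown head kind {kind!r}; expected one of {HEAD_KINDS}")


def fit_shallow(kind: str, features, labels, params: dict | None = None,
                seed: int = 0):
    """Fit a decision head of the given kind behind the uniform contract."""
    head = _make_head(kind, params or {}, seed)
    head.fit(np.asarray(features), np.asarray(labels))
    return head


def predict_shallow(model, features) -> np.ndarray:
    return np.asarray(model.predict(np.asarray(features)))


@dataclass
class GridSearchSpec:
    head_kind: str
    grid: dict[str, Sequence[Any]]
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_kind not in HEAD_KINDS:
            raise ValueError(f"unknown head kind {self.head_kind!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation fraction must lie in (0, 1)")

    def cells(self) -> list[dict[str, Any]]:
        """All grid cells in declaration order (first key varies slowest)."""
        from itertools import product

        keys = list(self.grid)
        return [
            dict(zip(keys, combo)) for combo in product(*(self.grid[k] for k in keys))
        ]


@dataclass
class GridSearchResult:
    best_params: dict[str, Any]
    best_score: float
    table: list[tuple[dict[str, Any], float | None]]


def grid_search(spec: GridSearchSpec, features, labels) -> GridSearchResult:
    """Exhaustive grid search on a seeded stratified train/validation split.

    The best cell is the highest validation accuracy; ties resolve to the
    earliest cell in declaration order.  A cell whose fit raises records a
    ``None`` score and the search continues.
    """
    from sklearn.model_selection import train_test_split

    x = np.asarray(features)
    y = np.asarray(labels)
    xtr, xval, ytr, yval = train_test_split(
        x, y, test_size=spec.validation_fraction, stratify=y,
        random_state=spec.seed % (2**32),
    )
    table: list[tuple[dict[str, Any], float | None]] = []
    best: tuple[float, dict] | None = None
    for cell in spec.cells():
        try:
            head = fit_shallow(spec.head_kind, xtr, ytr, cell, seed=spec.seed)
            score = float((predict_shallow(head, xval) == yval).mean())
        except Exception:
            table.append((cell, None))
            continue
        table.append((cell, score))
        if best is None or score > best[0]:
            best = (score, cell)
    if best is None:
        raise RuntimeError("every grid cell failed to fit")
    return GridSearchResult(best_params=best[1], best_score=best[0], table=table)
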