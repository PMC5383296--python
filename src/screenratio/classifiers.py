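"""Classifiers behind a uniform fit/predict contract.

Two reference classifiers are implemented natively because they are
simple enough to serve as desk-checkable oracles:

* ``nb`` — Bernoulli naive Bayes with add-one (Laplace) smoothing and
  hard labels from the posterior; a posterior tie goes to the negative
  class (screening conservatism).
* ``knn1`` — 1-nearest-neighbor under Euclidean distance. On binary
  vectors, Euclidean and Hamming orderings coincide; distance ties are
  broken toward the lowest training-row index.

Three further algorithms are adapters over scikit-learn, configured to
match the conventional WEKA-default settings used in screening
benchmarks: an SVM with a normalized polynomial kernel (complexity
parameter 1, training-data normalization is a no-op on 0/1 features), a
pruned decision tree, and a random forest of 10 unlimited-depth trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

ALGORITHMS = ("nb", "knn1", "svm-poly", "tree-c45", "rf")

# per-algorithm parameter schemas: name -> default
_PARAM_SCHEMAS: dict[str, dict[str, Any]] = {
    "nb": {"alpha": 1.0},
    "knn1": {},
    "svm-poly": {
        "complexity": 1.0,     # SVM cost parameter C
        "degree": 2,           # normalized polynomial kernel degree
        "epsilon": 1.0e-12,    # round-off epsilon
    },
    "tree-c45": {"pruning": True},
    "rf": {"n_trees": 10, "max_depth": None, "seed": 1},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """An algorithm name plus validated parameters.

    Unknown algorithms and unknown parameter keys are rejected; omitted
    parameters take their schema defaults.
    """

    algorithm: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        schema = _PARAM_SCHEMAS[self.algorithm]
        unknown = set(self.params) - set(schema)
        if unknown:
            raise ValueError(
                f"unknown parameters for {self.algorithm}: {sorted(unknown)}"
            )
        merged = {**schema, **self.params}
        object.__setattr__(self, "params", merged)


@dataclass
class FitState:
    """Opaque trained-model handle plus immutable training metadata."""

    spec: ClassifierSpec
    model: Any
    n_pos: int
    n_neg: int
    n_features: int
    seed: int
    fingerprint_kind: str | None = None


# --- native Bernoulli naive Bayes ----------------------------------------


class _NaiveBayes:
    """Bernoulli NB with Laplace smoothing on binary features."""

    def __init__(self, X: np.ndarray, y: np.ndarray, alpha: float = 1.0):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        n = len(y)
        self.log_prior = np.empty(2)
        self.theta = np.empty((2, X.shape[1]))
        for c in (0, 1):
            mask = y == c
            nc = int(mask.sum())
            self.log_prior[c] = np.log(nc / n)
            # add-one smoothing: (count + alpha) / (n_c + 2 alpha)
            self.theta[c] = (X[mask].sum(axis=0) + alpha) / (nc + 2.0 * alpha)

    def joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        log_t = np.log(self.theta)
        log_1mt = np.log1p(-self.theta)
        # n x 2 matrix of log prior + sum_j [x log t + (1-x) log(1-t)]
        jll = X @ log_t.T + (1.0 - X) @ log_1mt.T + self.log_prior
        return jll

    def posterior(self, X: np.ndarray) -> np.ndarray:
        jll = self.joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        post = self.posterior(X)
        # strict >: a tie at 0.5 goes to the negative class
        return (post[:, 1] > post[:, 0]).astype(np.uint8)


# --- native 1-nearest-neighbor -------------------------------------------


class _OneNN:
    """1-NN on binary vectors; Euclidean == Hamming ordering.

    Distances are computed via the identity ||x - t||^2 = |x| + |t| - 2 x.t
    with a float32 matrix product; all quantities are integers below 2^24
    so float32 arithmetic is exact and the first-minimum tie-break is
    deterministic.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.train = np.asarray(X, dtype=np.float32)
        self.labels = np.asarray(y, dtype=np.uint8)
        self.train_norms = self.train.sum(axis=1)

    def predict(self, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = np.empty(X.shape[0], dtype=np.uint8)
        for start in range(0, X.shape[0], chunk):
            block = X[start : start + chunk]
            d2 = block.sum(axis=1)[:, None] + self.train_norms[None, :]
            d2 -= 2.0 * (block @ self.train.T)
            nearest = np.argmin(d2, axis=1)  # first occurrence wins ties
            out[start : start + len(block)] = self.labels[nearest]
        return out


def knn1_predict(
    train_bits: np.ndarray, train_labels: np.ndarray, x: np.ndarray
) -> int:
    """Label of the training row nearest to x (ties: lowest row index)."""
    train_bits = np.asarray(train_bits)
    if train_bits.shape[0] < 1:
        raise ValueError("need at least one training row")
    model = _OneNN(train_bits, train_labels)
    return int(model.predict(np.asarray(x)[None, :])[0])


# --- scikit-learn adapters ------------------------------------------------


def _normalized_poly_kernel(degree: int):
    """Normalized polynomial kernel K(x,y) = k(x,y)/sqrt(k(x,x) k(y,y)),
    k(x,y) = (x.y + 1)^degree."""

    def kernel(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=np.float64)
        B = np.asarray(B, dtype=np.float64)
        raw = (A @ B.T + 1.0) ** degree
        da = (np.einsum("ij,ij->i", A, A) + 1.0) ** degree
        db = (np.einsum("ij,ij->i", B, B) + 1.0) ** degree
        return raw / np.sqrt(da[:, None] * db[None, :])

    return kernel


def fit(
    spec: ClassifierSpec,
    train_bits: np.ndarray,
    train_labels: np.ndarray,
    seed: int = 0,
    fingerprint_kind: str | None = None,
) -> FitState:
    """Train a classifier; deterministic under a fixed seed.

    Requires at least one example of each class.
    """
    X = np.asarray(train_bits)
    y = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training matrix must be non-empty and 2-D")
    if X.shape[0] != len(y):
        raise ValueError("label count does not match training rows")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"training set must contain both classes (got {n_pos} pos, {n_neg} neg)"
        )

    alg, p = spec.algorithm, spec.params
    if alg == "nb":
        model = _NaiveBayes(X, y, alpha=p["alpha"])
    elif alg == "knn1":
        model = _OneNN(X, y)
    elif alg == "svm-poly":
        from sklearn.svm import SVC

        model = SVC(
            C=p["complexity"],
            kernel=_normalized_poly_kernel(p["degree"]),
            tol=max(p["epsilon"], 1e-12),
            random_state=seed,
        )
        model.fit(X.astype(np.float64), y)
    elif alg == "tree-c45":
        from sklearn.tree import DecisionTreeClassifier

        model = DecisionTreeClassifier(
            criterion="entropy",
            ccp_alpha=0.001 if p["pruning"] else 0.0,
            random_state=seed,
        )
        model.fit(X, y)
    elif alg == "rf":
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(
            n_estimators=p["n_trees"],
            max_depth=p["max_depth"],
            random_state=p["seed"] if p["seed"] is not None else seed,
        )
        model.fit(X, y)
    else:  # pragma: no cover
        raise ValueError(alg)

    return FitState(
        spec=spec,
        model=model,
        n_pos=n_pos,
        n_neg=n_neg,
        n_features=X.shape[1],
        seed=seed,
        fingerprint_kind=fingerprint_kind,
    )


def predict(state: FitState, test_bits: np.ndarray) -> np.ndarray:
    """Hard 0/1 labels, one per test row."""
    X = np.asarray(test_bits)
    if X.ndim != 2:
        raise ValueError("test matrix must be 2-D")
    if X.shape[0] == 0:
        return np.zeros(0, dtype=np.uint8)
    if X.shape[1] != state.n_features:
        raise ValueError(
            f"test bit-width {X.shape[1]} != training bit-width {state.n_features}"
        )
    if state.spec.algorithm in ("nb", "knn1"):
        return state.model.predict(X)
    if state.spec.algorithm == "svm-poly":
        return state.model.predict(X.astype(np.float64)).astype(np.uint8)
    return state.model.predict(X).astype(np.uint8)


def nb_posterior(state: FitState, x: np.ndarray) -> tuple[float, float]:
    """(p_active, p_inactive) for one binary vector under a trained NB."""
    if state.spec.algorithm != "nb":
        raise ValueError("nb_posterior requires a state trained by nb")
    x = np.asarray(x)
    if x.ndim != 1 or x.shape[0] != state.n_features:
        raise ValueError("x must be a vector of the training bit-width")
    if np.any((x != 0) & (x != 1)):
        raise ValueError("x must be binary")
    post = state.model.posterior(x[None, :])[0]
    return float(post[1]), float(post[0])
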