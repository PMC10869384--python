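"""The three 2D-QSAR model families: MLR, PLSR (NIPALS) and epsilon-SVR.

Models are fit on descriptor-encoded peptides (see :mod:`pepqsar.dataio`).
Column subsets are always named by 1-based X-indices into the flat encoding.

The SVR dual problem is solved by libsvm (via scikit-learn), the solver
family whose parameter conventions the hyperparameters here follow; in
particular a requested ``gamma`` of 0 or ``None`` means the "auto" value
1/p where p is the number of feature columns.  :func:`kkt_audit` verifies
any fitted SVR against the first-order optimality conditions of the
epsilon-insensitive dual, independently of the solver.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.svm import SVR as _SklearnSVR

from . import validation
from .dataio import FeatureMatrix

__all__ = [
    "MLRModel",
    "PLSRModel",
    "SVRModel",
    "SVRParams",
    "fit_mlr",
    "select_descriptors",
    "fit_plsr",
    "choose_plsr_components",
    "fit_svr",
    "predict",
    "kkt_audit",
    "save_model",
    "load_model",
]

KERNELS = ("linear", "rbf", "sigmoid", "polynomial")

EXHAUSTIVE_BUDGET = 10**6


def _as_values(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _select(X: FeatureMatrix | np.ndarray, columns: Sequence[int] | None) -> np.ndarray:
    V = _as_values(X)
    if columns is None:
        return V
    idx = np.asarray(list(columns), dtype=int)
    if idx.size == 0:
        raise ValueError("empty column selection")
    if idx.min() < 1 or idx.max() > V.shape[1]:
        raise ValueError(f"X-index outside 1..{V.shape[1]}")
    return V[:, idx - 1]


# ---------------------------------------------------------------------------
# MLR


@dataclass(frozen=True)
class MLRModel:
    """Ordinary least squares on a named descriptor subset."""

    intercept: float
    coefficients: np.ndarray
    selected_columns: tuple[int, ...]

    def predict(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        Xs = _select(X, self.selected_columns)
        return self.intercept + Xs @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "family": "mlr",
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "selected_columns": list(self.selected_columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            selected_columns=tuple(int(c) for c in d["selected_columns"]),
        )


def fit_mlr(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float],
    columns: Sequence[int] | None = None,
) -> MLRModel:
    """OLS fit of pIC50 on the selected descriptor columns.

    ``columns`` are 1-based X-indices; ``None`` uses every column.  Raises on
    duplicate columns, on n <= k+1, and on a singular design.
    """
    y = np.asarray(y, dtype=float)
    V = _as_values(X)
    if columns is None:
        columns = tuple(range(1, V.shape[1] + 1))
    columns = tuple(int(c) for c in columns)
    if len(set(columns)) != len(columns):
        raise ValueError("duplicate columns in selection")
    Xs = _select(X, columns)
    n, k = Xs.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 samples (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Xs])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        # name a collinear column: one whose removal restores full rank
        for j, col in enumerate(columns):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise np.linalg.LinAlgError(
                    f"singular design: column X{col} is collinear with the others"
                )
        raise np.linalg.LinAlgError("singular design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MLRModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        selected_columns=columns,
    )


def _loo_press_ols(Xs: np.ndarray, y: np.ndarray) -> float:
    """Exact OLS LOO PRESS via the hat-matrix shortcut."""
    n = Xs.shape[0]
    design = np.column_stack([np.ones(n), Xs])
    # pinv handles the well-conditioned case exactly; singular designs are
    # rejected upstream by fit_mlr when used directly
    pinv = np.linalg.pinv(design)
    beta = pinv @ y
    resid = y - design @ beta
    h = np.einsum("ij,ji->i", design, pinv)
    denom = 1.0 - h
    if np.any(denom < 1e-12):
        return float("inf")
    return float(np.sum((resid / denom) ** 2))


def _subset_score(Xs: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(LOO Q^2, SEE) of an OLS fit on Xs; used as the selection criterion."""
    n, k = Xs.shape
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    press = _loo_press_ols(Xs, y)
    q2 = 1.0 - press / ss_tot
    design = np.column_stack([np.ones(n), Xs])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    ss_res = float(np.sum((y - design @ beta) ** 2))
    dof = n - k - 1
    see = math.sqrt(ss_res / dof) if dof > 0 else float("inf")
    return q2, see


def select_descriptors(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float],
    k: int,
    method: Literal["exhaustive", "forward"] = "forward",
) -> tuple[int, ...]:
    """Choose the k-column subset maximising LOO Q^2 of an OLS fit.

    Ties break by lower SEE, then by lexicographic column order.  Exhaustive
    search is allowed only when C(p, k) <= 10^6; forward selection greedily
    adds one column at a time under the same criterion.
    """
    y = np.asarray(y, dtype=float)
    V = _as_values(X)
    p = V.shape[1]
    if not 1 <= k <= min(10, p):
        raise ValueError(f"k must be in 1..min(10, p={p})")
    if method == "exhaustive":
        if math.comb(p, k) > EXHAUSTIVE_BUDGET:
            raise ValueError(
                f"exhaustive search over C({p},{k}) subsets exceeds the "
                f"{EXHAUSTIVE_BUDGET} budget; use method='forward'"
            )
        best = None
        for combo in itertools.combinations(range(1, p + 1), k):
            q2, see = _subset_score(V[:, np.array(combo) - 1], y)
            key = (-q2, see, combo)
            if best is None or key < best[0]:
                best = (key, combo)
        return best[1]
    if method != "forward":
        raise ValueError(f"unknown method {method!r}")
    chosen: list[int] = []
    for _ in range(k):
        best = None
        for col in range(1, p + 1):
            if col in chosen:
                continue
            trial = sorted(chosen + [col])
            q2, see = _subset_score(V[:, np.array(trial) - 1], y)
            key = (-q2, see, col)
            if best is None or key < best[0]:
                best = (key, col)
        chosen.append(best[1])
    return tuple(sorted(chosen))


# ---------------------------------------------------------------------------
# PLSR (NIPALS)


@dataclass(frozen=True)
class PLSRModel:
    """Partial least squares regression extracted by NIPALS.

    Components are extracted sequentially: each weight vector maximises the
    covariance of the X-scores with the (deflated) response, X is deflated by
    the rank-one score/loading product, and successive score vectors are
    mutually orthogonal.  Predictions project centred X through the weights
    ``W (P^T W)^-1 q`` and add back the response mean.
    """

    n_components: int
    x_weights: np.ndarray  # p x Nc
    x_loadings: np.ndarray  # p x Nc
    y_loadings: np.ndarray  # Nc
    x_mean: np.ndarray
    y_mean: float
    selected_columns: tuple[int, ...] | None = None

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector on the original (centred) X scale."""
        W, P, q = self.x_weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        Xs = _select(X, self.selected_columns)
        return self.y_mean + (Xs - self.x_mean) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "family": "plsr",
            "n_components": self.n_components,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "selected_columns": (
                None if self.selected_columns is None else list(self.selected_columns)
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSRModel":
        return cls(
            n_components=int(d["n_components"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            selected_columns=(
                None
                if d.get("selected_columns") is None
                else tuple(int(c) for c in d["selected_columns"])
            ),
        )


def fit_plsr(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float],
    n_components: int,
    columns: Sequence[int] | None = None,
) -> PLSRModel:
    """NIPALS PLS1 fit with ``n_components`` latent components."""
    y = np.asarray(y, dtype=float)
    Xs = _select(X, columns)
    n, p = Xs.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x_mean = Xs.mean(axis=0)
    y_mean = float(y.mean())
    E = Xs - x_mean
    rank = np.linalg.matrix_rank(E)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank} of centred X")
    f = y - y_mean
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ValueError(
                f"response deflated to zero covariance at component {a + 1}"
            )
        w /= norm
        t = E @ w
        tt = float(t @ t)
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
    return PLSRModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_mean=x_mean,
        y_mean=y_mean,
        selected_columns=None if columns is None else tuple(int(c) for c in columns),
    )


def choose_plsr_components(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float],
    max_nc: int,
    columns: Sequence[int] | None = None,
) -> tuple[int, list[dict]]:
    """Scan Nc = 1..max_nc by LOO Q^2; ties favour the smaller Nc.

    Returns the chosen Nc and a per-Nc table of (nc, q2, sep, r2, see) rows,
    the trend users plot to pick the model size by eye.
    """
    if max_nc < 1:
        raise ValueError("max_nc must be >= 1")
    y = np.asarray(y, dtype=float)
    Xs = _select(X, columns)
    rank = np.linalg.matrix_rank(Xs - Xs.mean(axis=0))
    table = []
    for nc in range(1, min(max_nc, rank) + 1):
        q2, sep = validation.loo_q2(
            lambda Xa, ya, nc=nc: fit_plsr(Xa, ya, nc).predict, Xs, y
        )
        model = fit_plsr(Xs, y, nc)
        r2, see, _ = validation.regression_stats(y, model.predict(Xs), nc)
        table.append({"nc": nc, "q2": q2, "sep": sep, "r2": r2, "see": see})
    best = max(table, key=lambda row: (row["q2"], -row["nc"]))
    return best["nc"], table


# ---------------------------------------------------------------------------
# SVR


@dataclass(frozen=True)
class SVRParams:
    """epsilon-SVR hyperparameters (libsvm conventions)."""

    kernel: str = "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float | None = None  # None or 0 -> 1/p ("auto")
    coef0: float = 0.0
    degree: int = 3
    tol: float = 1e-3
    shrinking: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


def _resolve_gamma(gamma: float | None, p: int) -> float:
    if gamma is None or gamma == 0:
        return 1.0 / p
    return float(gamma)


def kernel_matrix(params: SVRParams, A: np.ndarray, B: np.ndarray, p: int) -> np.ndarray:
    """Gram matrix K(A, B) for the four supported kernels."""
    g = _resolve_gamma(params.gamma, p)
    if params.kernel == "linear":
        K = A @ B.T
    elif params.kernel == "rbf":
        sq = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        K = np.exp(-g * np.maximum(sq, 0.0))
    elif params.kernel == "sigmoid":
        K = np.tanh(g * (A @ B.T) + params.coef0)
    elif params.kernel == "polynomial":
        K = (g * (A @ B.T) + params.coef0) ** params.degree
    else:  # pragma: no cover - guarded by SVRParams
        raise ValueError(params.kernel)
    if not np.all(np.isfinite(K)):
        raise FloatingPointError(f"non-finite kernel values ({params.kernel})")
    return K


@dataclass(frozen=True)
class SVRModel:
    """Fitted epsilon-SVR: f(x) = sum_i alpha_i K(x_i, x) + b."""

    params: SVRParams
    support_vectors: np.ndarray  # n_sv x k
    dual_coef: np.ndarray  # n_sv, signed alpha_i - alpha_i^*
    intercept: float
    n_features: int
    selected_columns: tuple[int, ...] | None = None
    support_indices: np.ndarray | None = None
    training_X: np.ndarray | None = None
    training_y: np.ndarray | None = None

    def predict(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        return self._predict_selected(_select(X, self.selected_columns))

    def _predict_selected(self, Xs: np.ndarray) -> np.ndarray:
        """Predict on rows already restricted to the model's columns."""
        if Xs.shape[0] == 0:
            return np.empty(0)
        if Xs.shape[1] != self.n_features:
            raise ValueError(
                f"feature count mismatch: model has {self.n_features}, got {Xs.shape[1]}"
            )
        K = kernel_matrix(self.params, Xs, self.support_vectors, self.n_features)
        return K @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "family": "svr",
            "params": {
                "kernel": self.params.kernel,
                "C": self.params.C,
                "epsilon": self.params.epsilon,
                "gamma": self.params.gamma,
                "coef0": self.params.coef0,
                "degree": self.params.degree,
                "tol": self.params.tol,
                "shrinking": self.params.shrinking,
            },
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "n_features": self.n_features,
            "selected_columns": (
                None if self.selected_columns is None else list(self.selected_columns)
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        return cls(
            params=SVRParams(**d["params"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            n_features=int(d["n_features"]),
            selected_columns=(
                None
                if d.get("selected_columns") is None
                else tuple(int(c) for c in d["selected_columns"])
            ),
        )


def fit_svr(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float],
    params: SVRParams | None = None,
    columns: Sequence[int] | None = None,
) -> SVRModel:
    """Solve the epsilon-insensitive dual on the selected columns."""
    params = params or SVRParams()
    y = np.asarray(y, dtype=float)
    Xs = _select(X, columns)
    n, k = Xs.shape
    # validate kernel values up front so sigmoid/polynomial overflow surfaces
    kernel_matrix(params, Xs, Xs, k)
    est = _SklearnSVR(
        kernel={"polynomial": "poly"}.get(params.kernel, params.kernel),
        C=params.C,
        epsilon=params.epsilon,
        gamma=_resolve_gamma(params.gamma, k),
        coef0=params.coef0,
        degree=params.degree,
        tol=params.tol,
        shrinking=params.shrinking,
    )
    est.fit(Xs, y)
    return SVRModel(
        params=params,
        support_vectors=np.asarray(est.support_vectors_, dtype=float),
        dual_coef=np.asarray(est.dual_coef_, dtype=float).ravel(),
        intercept=float(est.intercept_[0]),
        n_features=k,
        selected_columns=None if columns is None else tuple(int(c) for c in columns),
        support_indices=np.asarray(est.support_, dtype=int),
        training_X=Xs,
        training_y=y,
    )


def kkt_audit(model: SVRModel, tol: float = 1e-3) -> dict:
    """Audit an SVR fit against the dual optimality conditions.

    Checks, for every training point i with signed dual coefficient beta_i
    (alpha_i - alpha_i*) and residual r_i = y_i - f(x_i):

    * |beta_i| <= C (box constraint);
    * beta_i = 0 implies |r_i| <= epsilon + tol (inside the tube);
    * 0 < beta_i < C implies r_i ~= +epsilon (on the upper margin), and
      symmetrically for negative beta_i;
    * beta_i = +/-C implies r_i beyond the corresponding margin.

    Returns a dict with the worst violation and a pass flag at ``tol``.
    """
    if model.training_X is None or model.support_indices is None:
        raise ValueError("model was not fitted in-session; training data unavailable")
    X, y = model.training_X, model.training_y
    n = X.shape[0]
    beta = np.zeros(n)
    beta[model.support_indices] = model.dual_coef
    resid = y - model._predict_selected(X)
    eps, C = model.params.epsilon, model.params.C
    worst = 0.0
    for b, r in zip(beta, resid):
        if abs(b) > C + tol:
            worst = max(worst, abs(b) - C)
        if abs(b) <= tol:  # inside tube
            worst = max(worst, abs(r) - eps)
        elif b > 0 and b < C - tol:
            worst = max(worst, abs(r - eps))
        elif b < 0 and abs(b) < C - tol:
            worst = max(worst, abs(r + eps))
        elif b >= C - tol:
            worst = max(worst, eps - r)
        elif b <= -(C - tol):
            worst = max(worst, eps + r)
    worst = max(worst, abs(float(np.sum(beta))))  # equality constraint sum beta = 0
    return {"max_violation": float(worst), "passed": bool(worst <= tol)}


# ---------------------------------------------------------------------------
# prediction + serialization


def predict(model, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Deterministic predictions from any fitted model family."""
    V = _as_values(X)
    if V.shape[0] == 0:
        return np.empty(0)
    return model.predict(X)


_FAMILIES = {"mlr": MLRModel, "plsr": PLSRModel, "svr": SVRModel}


def save_model(model, path: str | Path, metadata: dict | None = None) -> None:
    d = model.to_dict()
    if metadata:
        d["metadata"] = metadata
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    family = d.get("family")
    if family not in _FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    return _FAMILIES[family].from_dict(d)
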