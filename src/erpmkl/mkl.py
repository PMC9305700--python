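"""Multiple-kernel soft-margin SVM.

Base kernels (linear, polynomial, Gaussian) are computed per feature group,
trace-normalized, and combined as ``Σ β_m K_m`` with ``β ≥ 0`` and
``‖β‖_p = 1``. Training alternates two steps: with β fixed, the soft-margin
SVM dual is solved on the combined Gram matrix; with the dual coefficients
fixed, β gets a closed-form lp-norm update from the per-kernel margin terms
``f_m = Σ_ij α_i α_j y_i y_j K_m(i, j)``.

The dual itself is a standard convex QP and is delegated to libsvm via
scikit-learn; the contract is the KKT feasibility of the returned
coefficients, which the tests check against an independent QP solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

__all__ = [
    "KernelSpec",
    "KernelGrouping",
    "MklModel",
    "compute_kernel",
    "combine",
    "train_mkl",
    "decision_function",
    "predict",
]


@dataclass(frozen=True)
class KernelSpec:
    """One base kernel: linear, polynomial (degree q) or gaussian (width s)."""

    kind: str
    degree: int = 2
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and (
            self.degree < 1 or int(self.degree) != self.degree
        ):
            raise ValueError("polynomial degree must be a positive integer")
        if self.kind == "gaussian" and self.width <= 0:
            raise ValueError("gaussian width must be positive")


@dataclass(frozen=True)
class KernelGrouping:
    """Ordered, disjoint, named feature-column groups (one kernel each)."""

    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("need at least one group")
        seen: set[str] = set()
        for name, cols in self.groups:
            if not cols:
                raise ValueError(f"group {name!r} is empty")
            overlap = seen.intersection(cols)
            if overlap:
                raise ValueError(f"columns appear in several groups: {sorted(overlap)[:3]}")
            seen.update(cols)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def all_columns(self) -> list[str]:
        return [c for _, cols in self.groups for c in cols]

    def dimensionalities(self) -> tuple[int, ...]:
        return tuple(len(cols) for _, cols in self.groups)


def compute_kernel(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix between two row blocks under one kernel."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("row blocks have mismatched column counts")
    if spec.kind == "linear":
        return A @ B.T
    if spec.kind == "polynomial":
        return (A @ B.T + 1.0) ** spec.degree
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-sq / spec.width**2)


def trace_factor(K: np.ndarray) -> float:
    """Normalizer ``N / trace(K)`` making base kernels comparable in scale."""
    tr = float(np.trace(K))
    if tr <= 0:
        raise ValueError("kernel has non-positive trace; cannot normalize")
    return K.shape[0] / tr


def combine(
    kernels: list[np.ndarray],
    beta: np.ndarray,
    factors: list[float] | None = None,
) -> np.ndarray:
    """Weighted sum ``Σ β_m K_m`` of trace-normalized base kernels.

    ``factors`` carries training-time normalizers when scoring test blocks;
    if omitted the kernels must be square and are normalized in place.
    """
    beta = np.asarray(beta, dtype=float)
    if len(kernels) != beta.size:
        raise ValueError("number of kernels and weights differ")
    if np.any(beta < 0) or not np.any(beta > 0):
        raise ValueError("weights must be non-negative with at least one positive")
    if factors is None:
        factors = [trace_factor(K) for K in kernels]
    out = np.zeros_like(kernels[0], dtype=float)
    for K, b, c in zip(kernels, beta, factors):
        if K.shape != kernels[0].shape:
            raise ValueError("kernels are not conformable")
        out += b * c * K
    return out


@dataclass
class MklModel:
    """Trained multiple-kernel SVM."""

    alpha: np.ndarray  # dual coefficients, 0 <= alpha_i <= C
    y: np.ndarray  # training labels in {-1, +1}
    b: float
    beta: np.ndarray
    p_norm: float
    C: float
    specs: tuple[KernelSpec, ...]
    grouping: KernelGrouping
    X_train: pd.DataFrame = field(repr=False)
    trace_factors: tuple[float, ...] = ()
    converged: bool = True
    n_iter: int = 0
    objective_history: list[float] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "y": self.y.tolist(),
            "b": float(self.b),
            "beta": self.beta.tolist(),
            "p_norm": float(self.p_norm),
            "C": float(self.C),
            "specs": [
                {"kind": s.kind, "degree": s.degree, "width": s.width}
                for s in self.specs
            ],
            "grouping": [[name, list(cols)] for name, cols in self.grouping.groups],
            "trace_factors": list(self.trace_factors),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "train_rows": {
                idx: row for idx, row in zip(
                    self.X_train.index.astype(str),
                    self.X_train.to_numpy().tolist(),
                )
            },
            "train_columns": list(self.X_train.columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MklModel":
        grouping = KernelGrouping(
            groups=tuple((name, tuple(cols)) for name, cols in d["grouping"])
        )
        X = pd.DataFrame.from_dict(d["train_rows"], orient="index")
        X.columns = d["train_columns"]
        return cls(
            alpha=np.array(d["alpha"], dtype=float),
            y=np.array(d["y"], dtype=float),
            b=float(d["b"]),
            beta=np.array(d["beta"], dtype=float),
            p_norm=float(d["p_norm"]),
            C=float(d["C"]),
            specs=tuple(
                KernelSpec(s["kind"], s["degree"], s["width"]) for s in d["specs"]
            ),
            grouping=grouping,
            X_train=X,
            trace_factors=tuple(d["trace_factors"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
        )


def _group_blocks(X: pd.DataFrame, grouping: KernelGrouping) -> list[np.ndarray]:
    missing = [c for c in grouping.all_columns() if c not in X.columns]
    if missing:
        raise ValueError(f"rows lack grouped columns: {missing[:3]}...")
    return [X[list(cols)].to_numpy(dtype=float) for _, cols in grouping.groups]


def _resolve_specs(
    specs: KernelSpec | list[KernelSpec] | tuple[KernelSpec, ...], m: int
) -> tuple[KernelSpec, ...]:
    if isinstance(specs, KernelSpec):
        return (specs,) * m
    if len(specs) != m:
        raise ValueError("one kernel spec per group required")
    return tuple(specs)


def train_mkl(
    X: pd.DataFrame,
    y,
    grouping: KernelGrouping,
    specs: KernelSpec | list[KernelSpec],
    C: float = 1.0,
    p_norm: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> MklModel:
    """Two-step alternating optimization of dual coefficients and β."""
    yv = np.asarray(pd.Series(y).map({-1: -1.0, 1: 1.0, -1.0: -1.0, 1.0: 1.0}))
    if np.any(pd.isna(yv)):
        raise ValueError("labels must be ±1")
    yv = yv.astype(float)
    if X.shape[0] < 4 or len(set(yv)) < 2:
        raise ValueError("need at least 4 rows and both classes")
    specs_t = _resolve_specs(specs, grouping.n_groups)
    blocks = _group_blocks(X, grouping)
    M, N = grouping.n_groups, X.shape[0]

    Ks, factors = [], []
    for block, spec in zip(blocks, specs_t):
        K = compute_kernel(block, block, spec)
        c = trace_factor(K)
        Ks.append(c * K)
        factors.append(c)

    beta = np.full(M, M ** (-1.0 / p_norm))  # uniform, ||beta||_p = 1
    alpha = np.zeros(N)
    b = 0.0
    objective: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Kc = sum(bm * K for bm, K in zip(beta, Ks))
        svc = SVC(C=C, kernel="precomputed", tol=1e-8)
        svc.fit(Kc, yv)
        alpha = np.zeros(N)
        alpha[svc.support_] = np.abs(svc.dual_coef_[0])
        b = float(svc.intercept_[0])
        v = alpha * yv
        objective.append(float(alpha.sum() - 0.5 * v @ Kc @ v))

        # squared per-kernel margin norms ||w_m||^2 = beta_m^2 f_m, where
        # f_m is the raw margin term; the beta^2 factor makes the closed-form
        # step the exact minimizer over {beta >= 0, ||beta||_p = 1}, which in
        # turn keeps the monitored objective non-increasing
        f = beta**2 * np.array([v @ K @ v for K in Ks])
        if not np.any(f > 0):
            converged = True
            break
        num = f ** (1.0 / (p_norm + 1.0))
        den = float(np.sum(f ** (p_norm / (p_norm + 1.0)))) ** (1.0 / p_norm)
        new_beta = num / den
        delta = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if delta < tol:
            converged = True
            break

    return MklModel(
        alpha=alpha,
        y=yv,
        b=b,
        beta=beta,
        p_norm=p_norm,
        C=C,
        specs=specs_t,
        grouping=grouping,
        X_train=X.copy(),
        trace_factors=tuple(factors),
        converged=converged,
        n_iter=it,
        objective_history=objective,
    )


def decision_function(model: MklModel, rows: pd.DataFrame) -> np.ndarray:
    """Evaluate ``f(x) = Σ_i α_i y_i Σ_m β_m k_m(x_i, x) + b`` on new rows."""
    train_blocks = _group_blocks(model.X_train, model.grouping)
    test_blocks = _group_blocks(rows, model.grouping)
    Kt = [
        compute_kernel(tr, te, spec)
        for tr, te, spec in zip(train_blocks, test_blocks, model.specs)
    ]
    Kc = combine(Kt, model.beta, factors=list(model.trace_factors))
    v = model.alpha * model.y
    return v @ Kc + model.b


def predict(model: MklModel, rows: pd.DataFrame) -> np.ndarray:
    """Class predictions in {-1, +1} (0 decision values map to +1)."""
    f = decision_function(model, rows)
    return np.where(f >= 0, 1.0, -1.0)
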