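"""Least-squares SVM regression: kernels, dual solve, cross-validated search.

Training solves the (n+1)x(n+1) saddle system

    [[0, 1^T        ], [b    ]   [0]
     [1, K + I/C    ]] [alpha] = [y]

whose KKT identities (sum(alpha) = 0 and y_i - f(x_i) = alpha_i / C) are
checked after every fit.

Two RBF parameterisations are supported because toolboxes disagree:
``"width"`` (default) uses K = exp(-||u-v||^2 / g), treating g as a squared
bandwidth; ``"gamma"`` uses K = exp(-g * ||u-v||^2).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "LssvmModel",
    "CvResult",
    "rbf_kernel",
    "kernel_matrix",
    "fit_lssvm",
    "predict_lssvm",
    "cv_grid_search",
    "mse",
]

Convention = Literal["width", "gamma"]


@dataclass(frozen=True)
class KernelSpec:
    kind: Literal["rbf", "linear"] = "rbf"
    g: float | None = None
    convention: Convention = "width"

    def __post_init__(self) -> None:
        if self.kind == "rbf":
            if self.g is None or self.g <= 0:
                raise ValueError("RBF kernel requires g > 0")
        elif self.kind != "linear":
            raise ValueError(f"unknown kernel kind {self.kind!r}")


def rbf_kernel(u: Sequence[float], v: Sequence[float], g: float,
               convention: Convention = "width") -> float:
    """RBF kernel value for a single pair of vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    if g <= 0:
        raise ValueError("g must be > 0")
    d2 = float(((u - v) ** 2).sum())
    return float(np.exp(-d2 / g) if convention == "width" else np.exp(-g * d2))


def kernel_matrix(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = k(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if spec.kind == "linear":
        return X @ Z.T
    d2 = ((X[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    if spec.convention == "width":
        return np.exp(-d2 / spec.g)
    return np.exp(-spec.g * d2)


@dataclass
class LssvmModel:
    """Trained LS-SVM: training inputs, dual coefficients, bias, kernel, C."""

    X: np.ndarray
    alpha: np.ndarray
    b: float
    kernel: KernelSpec
    C: float

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.X.shape[0],):
            raise ValueError("alpha must have one entry per training row")

    def predict(self, x: Sequence[float] | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        K = kernel_matrix(np.atleast_2d(x), self.X, self.kernel)
        y = self.b + K @ self.alpha
        return float(y[0]) if single else y

    def to_json(self, path: str | Path) -> None:
        payload = {
            "X": self.X.tolist(),
            "alpha": self.alpha.tolist(),
            "b": self.b,
            "C": self.C,
            "kernel": {
                "kind": self.kernel.kind,
                "g": self.kernel.g,
                "convention": self.kernel.convention,
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LssvmModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            X=np.array(payload["X"], dtype=float),
            alpha=np.array(payload["alpha"], dtype=float),
            b=float(payload["b"]),
            C=float(payload["C"]),
            kernel=KernelSpec(**payload["kernel"]),
        )


def fit_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    g: float | None,
    C: float,
    kernel: Literal["rbf", "linear"] = "rbf",
    convention: Convention = "width",
) -> LssvmModel:
    """Solve the LS-SVM dual saddle system for (b, alpha)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("y must have one entry per row of X")
    if C <= 0:
        raise ValueError("C must be > 0")
    uniq = {tuple(row.tolist()) for row in X}
    if len(uniq) != n:
        raise ValueError(
            "duplicate input rows; average replicated responses first "
            "(see design.aggregate_replicates)"
        )
    spec = KernelSpec(kind=kernel, g=g, convention=convention)
    K = kernel_matrix(X, X, spec)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / C
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "LS-SVM system is singular; try a different g or add jitter"
        ) from exc
    rel = np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1.0)
    if rel > 1e-8:
        raise np.linalg.LinAlgError(
            f"LS-SVM solve is ill-conditioned (relative residual {rel:.2e}); "
            "try a different g or add jitter"
        )
    return LssvmModel(X=X, alpha=sol[1:], b=float(sol[0]), kernel=spec, C=C)


def predict_lssvm(model: LssvmModel, x: Sequence[float] | np.ndarray) -> float | np.ndarray:
    return model.predict(x)


def mse(pred: Sequence[float], actual: Sequence[float]) -> float:
    """Mean squared error (1/n) * sum (actual_i - pred_i)^2."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if pred.size < 1:
        raise ValueError("need at least one value")
    return float(np.mean((actual - pred) ** 2))


@dataclass
class CvResult:
    """Exhaustive grid-search record: every (g, C, cv_error) plus the winner."""

    grid: list[tuple[float, float, float]]
    best_g: float
    best_C: float
    best_error: float


def _folds(n: int, scheme: str | int, seed: int | None) -> list[np.ndarray]:
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    k = int(scheme)
    if not 2 <= k <= n:
        raise ValueError(f"fold count must be in [2, {n}], got {k}")
    idx = np.arange(n)
    rng = np.random.default_rng(seed)
    rng.shuffle(idx)
    return [np.sort(part) for part in np.array_split(idx, k)]


def cv_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    g_grid: Sequence[float],
    C_grid: Sequence[float],
    scheme: str | int = "loo",
    seed: int | None = None,
    kernel: Literal["rbf", "linear"] = "rbf",
    convention: Convention = "width",
) -> CvResult:
    """Cross-validated exhaustive search over the (g, C) parameter matrix.

    Ties are broken toward the smallest g, then the smallest C. Leave-one-out
    (``scheme="loo"``) is deterministic; k-fold shuffling is seeded.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(g_grid) == 0 or len(C_grid) == 0:
        raise ValueError("parameter grids must be non-empty")
    n = X.shape[0]
    folds = _folds(n, scheme, seed)
    grid: list[tuple[float, float, float]] = []
    best: tuple[float, float, float] | None = None
    for g in sorted(g_grid):
        for C in sorted(C_grid):
            errs = []
            for held in folds:
                train = np.setdiff1d(np.arange(n), held)
                m = fit_lssvm(X[train], y[train], g, C,
                              kernel=kernel, convention=convention)
                pred = np.atleast_1d(m.predict(X[held]))
                errs.append(((y[held] - pred) ** 2).sum())
            cv_err = float(np.sum(errs) / n)
            grid.append((float(g), float(C), cv_err))
            # strict < plus sorted grids => ties break to smallest g, then C
            if best is None or cv_err < best[2]:
                best = (float(g), float(C), cv_err)
    assert best is not None
    return CvResult(grid=grid, best_g=best[0], best_C=best[1], best_error=best[2])
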