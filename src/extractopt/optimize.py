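"""Constrained maximization of fitted surfaces and validation comparison."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize as sciopt

from .design import ExperimentTable, Factor, WeightScheme, composite_score, decode_levels
from .lssvm import LssvmModel
from .rsm import QuadraticModel

__all__ = [
    "OptimizationResult",
    "ValidationReport",
    "ComparisonSummary",
    "maximize_quadratic",
    "maximize_lssvm",
    "relative_deviation",
    "validation_report",
    "compare_models",
]

_MAX_GRID_POINTS = 10_000_000


@dataclass
class OptimizationResult:
    argmax_coded: np.ndarray
    argmax_natural: np.ndarray | None
    predicted_value: float
    method: str  # "analytic-stationary" | "grid" | "grid+polish"
    flat: bool = False

    def __post_init__(self) -> None:
        self.argmax_coded = np.asarray(self.argmax_coded, dtype=float)
        if np.any(np.abs(self.argmax_coded) > 1.0 + 1e-9):
            raise ValueError("argmax_coded must lie in [-1, 1]^k")


def _coded_grid(k: int, step: float) -> np.ndarray:
    """Lexicographically ordered grid over [-1, 1]^k at the given step."""
    axis = np.arange(-1.0, 1.0 + step / 2, step)
    axis = np.clip(axis, -1.0, 1.0)
    n_pts = len(axis) ** k
    if n_pts > _MAX_GRID_POINTS:
        raise ValueError(
            f"grid of {n_pts} points exceeds {_MAX_GRID_POINTS}; use a coarser step"
        )
    mesh = np.meshgrid(*([axis] * k), indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def maximize_quadratic(
    model: QuadraticModel,
    factors: Sequence[Factor] | None = None,
    grid_step: float = 0.1,
) -> OptimizationResult:
    """Maximize a quadratic surface over the coded cube [-1, 1]^k.

    If the stationary point -0.5 * B^-1 b is interior and B is negative
    definite it is returned analytically; otherwise a deterministic coarse
    grid seeds a bound-constrained polish.
    """
    B, b = model.quadratic_form()
    k = model.n_factors
    analytic = None
    try:
        xs = -0.5 * np.linalg.solve(B, b)
        eigs = np.linalg.eigvalsh(B)
        if np.all(eigs < -1e-12) and np.all(np.abs(xs) <= 1.0):
            analytic = xs
    except np.linalg.LinAlgError:
        analytic = None

    if analytic is not None:
        best, method = analytic, "analytic-stationary"
    else:
        grid = _coded_grid(k, grid_step)
        vals = model.predict(grid)
        x0 = grid[int(np.argmax(vals))]
        res = sciopt.minimize(
            lambda x: -model.predict(x),
            x0,
            bounds=[(-1.0, 1.0)] * k,
            method="L-BFGS-B",
        )
        best, method = np.clip(res.x, -1.0, 1.0), "grid+polish"

    return OptimizationResult(
        argmax_coded=best,
        argmax_natural=decode_levels(best, factors) if factors is not None else None,
        predicted_value=float(model.predict(best)),
        method=method,
    )


def maximize_lssvm(
    model: LssvmModel,
    factors: Sequence[Factor] | None = None,
    step: float = 0.05,
    refine_passes: int = 2,
    chunk: int = 200_000,
) -> OptimizationResult:
    """Exhaustive coded-grid maximization of an LS-SVM surface with
    coordinate-wise refinement at step/10.

    Deterministic; ties resolve to the lexicographically smallest coded
    point (first occurrence in the ordered grid).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    k = model.X.shape[1]
    grid = _coded_grid(k, step)
    best_val = -np.inf
    best_idx = 0
    vmin = np.inf
    for start in range(0, grid.shape[0], chunk):
        vals = np.asarray(model.predict(grid[start : start + chunk]))
        i = int(np.argmax(vals))
        vmin = min(vmin, float(vals.min()))
        if vals[i] > best_val:  # strict: keeps first (lexicographic) maximizer
            best_val = float(vals[i])
            best_idx = start + i
    flat = (best_val - vmin) < 1e-12
    best = grid[best_idx].copy()

    fine = step / 10.0
    for _ in range(refine_passes):
        for d in range(k):
            cand = np.clip(
                best[d] + np.arange(-10, 11) * fine, -1.0, 1.0
            )
            pts = np.tile(best, (cand.size, 1))
            pts[:, d] = cand
            vals = np.asarray(model.predict(pts))
            j = int(np.argmax(vals))
            if vals[j] > best_val:
                best_val = float(vals[j])
                best = pts[j].copy()

    return OptimizationResult(
        argmax_coded=best,
        argmax_natural=decode_levels(best, factors) if factors is not None else None,
        predicted_value=best_val,
        method="grid+polish",
        flat=flat,
    )


def relative_deviation(observed_mean: float, predicted: float) -> float:
    """|predicted - observed| / predicted * 100."""
    if predicted == 0:
        raise ZeroDivisionError("predicted value must be nonzero")
    return abs(predicted - observed_mean) / abs(predicted) * 100.0


@dataclass
class ValidationReport:
    """Replicate composites under one model's recommended conditions."""

    name: str
    replicate_composites: np.ndarray
    mean: float
    sd: float
    predicted: float
    relative_deviation_pct: float

    def __post_init__(self) -> None:
        self.replicate_composites = np.asarray(self.replicate_composites, dtype=float)
        # internal consistency: stored summaries must match the replicates
        assert abs(self.mean - self.replicate_composites.mean()) <= 5e-5
        assert abs(self.sd - self.replicate_composites.std(ddof=0)) <= 5e-5
        assert (
            abs(self.relative_deviation_pct - relative_deviation(self.mean, self.predicted))
            <= 0.01
        )


def validation_report(
    replicates: ExperimentTable,
    predicted: float,
    weights: WeightScheme,
    name: str = "model",
) -> ValidationReport:
    """Summarise verification replicates: composite mean, SD (population,
    n denominator) and relative deviation from the predicted optimum."""
    n = replicates.n_runs
    if n < 2:
        raise ValueError("need at least 2 replicates for an SD")
    comps = np.array(
        [
            composite_score(
                {a: replicates.yields[a][i] for a in replicates.analytes}, weights
            )
            for i in range(n)
        ]
    )
    return ValidationReport(
        name=name,
        replicate_composites=comps,
        mean=float(comps.mean()),
        sd=float(comps.std(ddof=0)),
        predicted=float(predicted),
        relative_deviation_pct=relative_deviation(float(comps.mean()), float(predicted)),
    )


@dataclass
class ComparisonSummary:
    ranking: list[str]  # report names, best (smallest deviation) first
    winner: str
    deviations: dict[str, float]
    margins: dict[str, float]  # deviation minus the winner's deviation
    tie: bool


def compare_models(reports: Sequence[ValidationReport]) -> ComparisonSummary:
    """Rank validation reports by relative deviation (ascending)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    ordered = sorted(reports, key=lambda r: (r.relative_deviation_pct, r.name))
    dev = {r.name: r.relative_deviation_pct for r in ordered}
    best = ordered[0]
    tie = abs(ordered[1].relative_deviation_pct - best.relative_deviation_pct) < 1e-12
    return ComparisonSummary(
        ranking=[r.name for r in ordered],
        winner=best.name,
        deviations=dev,
        margins={n: d - best.relative_deviation_pct for n, d in dev.items()},
        tie=tie,
    )
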