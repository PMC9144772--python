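"""Box-Behnken designs, factor coding, precedence weights and composite scoring.

Factors are three-level (low/mid/high in natural units, coded -1/0/+1).
The coding map is piecewise linear around the mid level so asymmetric
level spacings (mid not at the midpoint of low..high) are handled exactly.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignPoint",
    "ExperimentTable",
    "WeightScheme",
    "build_bbd",
    "code_levels",
    "decode_levels",
    "precedence_weights",
    "composite_score",
    "add_composite",
    "aggregate_replicates",
    "load_factors",
    "save_factors",
]

# Box & Behnken (1960) three-factor blocks for k = 6, 7 (for k <= 5 the
# design pairs every two factors, giving 2k(k-1) edge points).
_TRIPLE_BLOCKS = {
    6: [(0, 1, 3), (1, 2, 4), (2, 3, 5), (3, 4, 0), (4, 5, 1), (5, 0, 2)],
    7: [(0, 1, 3), (1, 2, 4), (2, 3, 5), (3, 4, 6), (4, 5, 0), (5, 6, 1), (6, 0, 2)],
}

_SUPPORTED_K = range(3, 8)


@dataclass(frozen=True)
class Factor:
    """A three-level experimental factor in natural units."""

    name: str
    unit: str
    low: float
    mid: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.mid < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < mid < high, "
                f"got ({self.low}, {self.mid}, {self.high})"
            )

    def code(self, x: float) -> float:
        """Natural -> coded. low -> -1, mid -> 0, high -> +1, linear between."""
        if x >= self.mid:
            return (x - self.mid) / (self.high - self.mid)
        return (x - self.mid) / (self.mid - self.low)

    def decode(self, z: float) -> float:
        """Coded -> natural; exact inverse of :meth:`code`."""
        if z >= 0:
            return self.mid + z * (self.high - self.mid)
        return self.mid + z * (self.mid - self.low)


@dataclass(frozen=True)
class DesignPoint:
    """One experimental setting, coded and natural representations in sync."""

    coded: np.ndarray
    natural: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "coded", np.asarray(self.coded, dtype=float))
        object.__setattr__(self, "natural", np.asarray(self.natural, dtype=float))
        if self.coded.shape != self.natural.shape:
            raise ValueError("coded and natural vectors must have equal length")

    @classmethod
    def from_coded(cls, coded: Sequence[float], factors: Sequence[Factor]) -> "DesignPoint":
        coded = np.asarray(coded, dtype=float)
        return cls(coded=coded, natural=decode_levels(coded, factors))

    @classmethod
    def from_natural(cls, natural: Sequence[float], factors: Sequence[Factor]) -> "DesignPoint":
        natural = np.asarray(natural, dtype=float)
        return cls(coded=code_levels(natural, factors), natural=natural)


def code_levels(natural: Sequence[float], factors: Sequence[Factor]) -> np.ndarray:
    """Map a natural-unit vector to coded units (one value per factor)."""
    natural = np.asarray(natural, dtype=float)
    if natural.shape[-1] != len(factors):
        raise ValueError(
            f"expected {len(factors)} values, got {natural.shape[-1]}"
        )
    for x, f in zip(np.atleast_2d(natural).T, factors):
        if np.any(x < f.low) or np.any(x > f.high):
            warnings.warn(
                f"factor {f.name!r}: value outside [{f.low}, {f.high}]; "
                "coding extrapolates (prediction-only use)",
                UserWarning,
                stacklevel=2,
            )
    if natural.ndim == 1:
        return np.array([f.code(x) for x, f in zip(natural, factors)])
    return np.column_stack(
        [np.vectorize(f.code)(natural[:, j]) for j, f in enumerate(factors)]
    )


def decode_levels(coded: Sequence[float], factors: Sequence[Factor]) -> np.ndarray:
    """Map a coded vector back to natural units (inverse of :func:`code_levels`)."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise ValueError(f"expected {len(factors)} values, got {coded.shape[-1]}")
    if coded.ndim == 1:
        return np.array([f.decode(z) for z, f in zip(coded, factors)])
    return np.column_stack(
        [np.vectorize(f.decode)(coded[:, j]) for j, f in enumerate(factors)]
    )


def build_bbd(factors: Sequence[Factor], n_center: int) -> list[DesignPoint]:
    """Construct a Box-Behnken design for 3..7 factors plus center replicates.

    For k <= 5 every factor pair contributes the four (+-1, +-1) edge points
    (2k(k-1) runs); k = 6, 7 use the catalog three-factor blocks. Center
    points are all-zero and replicated ``n_center`` times.
    """
    k = len(factors)
    if k not in _SUPPORTED_K:
        raise ValueError(
            f"Box-Behnken designs are supported for 3..7 factors, got {k}"
        )
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    rows: list[np.ndarray] = []
    if k <= 5:
        for i, j in combinations(range(k), 2):
            for a in (-1.0, 1.0):
                for b in (-1.0, 1.0):
                    row = np.zeros(k)
                    row[i], row[j] = a, b
                    rows.append(row)
    else:
        for block in _TRIPLE_BLOCKS[k]:
            for signs in np.ndindex(2, 2, 2):
                row = np.zeros(k)
                for idx, s in zip(block, signs):
                    row[idx] = -1.0 if s == 0 else 1.0
                rows.append(row)
    rows.extend(np.zeros(k) for _ in range(n_center))
    return [DesignPoint.from_coded(r, factors) for r in rows]


@dataclass(frozen=True)
class WeightScheme:
    """Analyte weights, optionally derived from a precedence (pairwise) chart."""

    weights: dict[str, float]
    pairwise: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")


def precedence_weights(
    pairwise: np.ndarray | Sequence[Sequence[float]],
    analyte_order: Sequence[str],
) -> WeightScheme:
    """Row-sum-normalised weights from a pairwise precedence matrix.

    Off-diagonal entries score 1 (row more important), 0.5 (equal) or 0;
    ``pairwise[i][j] + pairwise[j][i]`` must equal 1 for i != j.
    """
    P = np.asarray(pairwise, dtype=float)
    m = len(analyte_order)
    if P.shape != (m, m):
        raise ValueError(f"pairwise matrix must be {m}x{m}, got {P.shape}")
    for i, j in combinations(range(m), 2):
        if abs(P[i, j] + P[j, i] - 1.0) > 1e-9:
            raise ValueError(
                f"inconsistent precedence chart: entries ({i},{j}) and ({j},{i}) "
                f"must sum to 1, got {P[i, j]} + {P[j, i]}"
            )
    off = P - np.diag(np.diag(P))
    row_sums = off.sum(axis=1)
    total = row_sums.sum()
    if total <= 0:
        weights = np.full(m, 1.0 / m)
    else:
        weights = row_sums / total
    return WeightScheme(
        weights={a: float(w) for a, w in zip(analyte_order, weights)}, pairwise=P
    )


def composite_score(yields: Mapping[str, float], weights: WeightScheme) -> float:
    """Weighted linear composite of per-analyte yields."""
    missing = [a for a in yields if a not in weights.weights]
    if missing:
        raise KeyError(f"no weight defined for analyte(s): {missing}")
    return float(sum(weights.weights[a] * y for a, y in yields.items()))


@dataclass
class ExperimentTable:
    """Designed-experiment runs: coded/natural settings, yields, composite."""

    factors: list[Factor]
    run_ids: list[int]
    coded: np.ndarray
    yields: dict[str, np.ndarray]
    composite: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        n = len(self.run_ids)
        if len(set(self.run_ids)) != n:
            raise ValueError("run_ids must be unique")
        if self.coded.shape != (n, len(self.factors)):
            raise ValueError(
                f"coded matrix must be ({n}, {len(self.factors)}), got {self.coded.shape}"
            )
        self.yields = {a: np.asarray(v, dtype=float) for a, v in self.yields.items()}
        for a, v in self.yields.items():
            if v.shape != (n,):
                raise ValueError(f"yield column {a!r} has wrong length")
        if self.composite is not None:
            self.composite = np.asarray(self.composite, dtype=float)
            if self.composite.shape != (n,):
                raise ValueError("composite column has wrong length")

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    @property
    def analytes(self) -> list[str]:
        return list(self.yields)

    @property
    def natural(self) -> np.ndarray:
        return decode_levels(self.coded, self.factors)

    def points(self) -> list[DesignPoint]:
        return [DesignPoint.from_coded(row, self.factors) for row in self.coded]

    def response(self, name: str) -> np.ndarray:
        """Response column by name; ``'composite'`` selects the composite."""
        if name == "composite":
            if self.composite is None:
                raise ValueError("table has no composite column")
            return self.composite
        if name in self.yields:
            return self.yields[name]
        raise KeyError(f"unknown response {name!r}; have {self.analytes} + 'composite'")

    # -- CSV interface: natural units, header row required -------------------
    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        factors: Sequence[Factor],
        composite_col: str = "Y",
    ) -> "ExperimentTable":
        df = pd.read_csv(path)
        required = ["run_id"] + [f.name for f in factors]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"CSV is missing required column(s): {missing}")
        natural = df[[f.name for f in factors]].to_numpy(dtype=float)
        analyte_cols = [
            c for c in df.columns if c not in required and c != composite_col
        ]
        return cls(
            factors=list(factors),
            run_ids=[int(r) for r in df["run_id"]],
            coded=code_levels(natural, factors),
            yields={a: df[a].to_numpy(dtype=float) for a in analyte_cols},
            composite=(
                df[composite_col].to_numpy(dtype=float)
                if composite_col in df.columns
                else None
            ),
        )

    def to_csv(self, path: str | Path, composite_col: str = "Y") -> None:
        df = pd.DataFrame({"run_id": self.run_ids})
        nat = self.natural
        for j, f in enumerate(self.factors):
            df[f.name] = nat[:, j]
        for a, v in self.yields.items():
            df[a] = v
        if self.composite is not None:
            df[composite_col] = self.composite
        df.to_csv(path, index=False)


def add_composite(table: ExperimentTable, weights: WeightScheme) -> ExperimentTable:
    """Return a copy of ``table`` with the composite recomputed from yields."""
    comp = np.zeros(table.n_runs)
    for a in table.analytes:
        if a not in weights.weights:
            raise KeyError(f"no weight defined for analyte(s): [{a!r}]")
        comp = comp + weights.weights[a] * table.yields[a]
    return replace(table, composite=comp)


def aggregate_replicates(table: ExperimentTable) -> ExperimentTable:
    """Collapse runs with identical coded settings to their arithmetic mean.

    Matching is exact equality of the coded levels (replicates in a BBD
    share integer -1/0/+1 settings). First-occurrence order is kept and the
    collapsed run takes the first run_id of its group.
    """
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for i, row in enumerate(table.coded):
        key = tuple(row.tolist())
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)

    idx_groups = [groups[k] for k in order]
    coded = np.array([table.coded[g[0]] for g in idx_groups])
    run_ids = [table.run_ids[g[0]] for g in idx_groups]
    yields = {
        a: np.array([v[g].mean() for g in idx_groups]) for a, v in table.yields.items()
    }
    composite = (
        np.array([table.composite[g].mean() for g in idx_groups])
        if table.composite is not None
        else None
    )
    return ExperimentTable(
        factors=table.factors,
        run_ids=run_ids,
        coded=coded,
        yields=yields,
        composite=composite,
    )


def load_factors(path: str | Path) -> list[Factor]:
    """Read factor definitions from a JSON list of {name, unit, low, mid, high}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return [Factor(**entry) for entry in raw]


def save_factors(factors: Sequence[Factor], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            [
                {"name": f.name, "unit": f.unit, "low": f.low, "mid": f.mid, "high": f.high}
                for f in factors
            ],
            fh,
            indent=2,
        )
        fh.write("\n")
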