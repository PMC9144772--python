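"""Synthetic BBD experiment generation and packaged fixture loading.

Simulated tables follow the data-generating form the analysis assumes:
a full quadratic surface on the coded cube plus i.i.d. homoscedastic
Gaussian noise, with independently perturbed replicated center points.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ExperimentTable, Factor, WeightScheme, build_bbd, load_factors
from .rsm import QuadraticModel

__all__ = ["SurfaceSpec", "simulate_bbd_experiment", "load_fixture", "fixture_path"]

_CHECKSUMS = {
    "table1_factors.json": "4b4b5a88f00fb905e8402cd1d82cea1e2ef6c70a30800fc3e0891daf09976d77",
    "table2_design.csv": "ba3cfff616bbdec862ae482e42018b884ca7fb96c3bad2f3c4d84e981401acb3",
    "table4_lssvm_pred.csv": "bf418b04636db9d93765dfdb3dbcd4b34c24ebb14d4019e6f771ff782f0e9bc5",
    "table5_validation.csv": "80a742acecfc318802bf346636b31e5daade08c3972766f86242bdbfb5d57b99",
}

_FIXTURE_FILES = {
    "table1": "table1_factors.json",
    "table2": "table2_design.csv",
    "table4": "table4_lssvm_pred.csv",
    "table5": "table5_validation.csv",
}


@dataclass
class SurfaceSpec:
    """True quadratic surface + replicate noise for the generator."""

    model: QuadraticModel
    noise_sd: float
    n_center: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_center < 1:
            raise ValueError("n_center must be >= 1")


def simulate_bbd_experiment(
    factors: Sequence[Factor],
    spec: SurfaceSpec,
    analyte_models: dict[str, QuadraticModel] | None = None,
    weights: WeightScheme | None = None,
    correlation: float = 0.0,
) -> ExperimentTable:
    """Simulate a BBD experiment table under ``spec``.

    Default mode draws the composite response directly from ``spec.model``
    plus Gaussian(0, noise_sd) noise. The extended mode takes per-analyte
    surfaces (``analyte_models`` + ``weights``) with optionally correlated
    analyte noise and derives the composite by the weight scheme.
    Deterministic under ``spec.seed``.
    """
    if spec.model.n_factors != len(factors):
        raise ValueError("surface dimension does not match factor count")
    points = build_bbd(factors, spec.n_center)
    coded = np.array([p.coded for p in points])
    n = coded.shape[0]
    rng = np.random.default_rng(spec.seed)

    if analyte_models is None:
        y = np.asarray(spec.model.predict(coded)) + rng.normal(0.0, spec.noise_sd, n)
        yields = {"response": y}
        composite = y
    else:
        if weights is None:
            raise ValueError("extended mode requires a weight scheme")
        if not -1.0 <= correlation <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")
        names = list(analyte_models)
        m = len(names)
        cov = spec.noise_sd**2 * (
            np.full((m, m), correlation) + (1.0 - correlation) * np.eye(m)
        )
        noise = rng.multivariate_normal(np.zeros(m), cov, size=n)
        yields = {
            a: np.asarray(analyte_models[a].predict(coded)) + noise[:, i]
            for i, a in enumerate(names)
        }
        composite = sum(weights.weights[a] * yields[a] for a in names)

    return ExperimentTable(
        factors=list(factors),
        run_ids=list(range(1, n + 1)),
        coded=coded,
        yields=yields,
        composite=composite,
    )


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (checksum-verified)."""
    if name not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        )
    fname = _FIXTURE_FILES[name]
    path = Path(str(resources.files("extractopt").joinpath("data", fname)))
    _verify_checksum(path, _CHECKSUMS[fname])
    return path


def _verify_checksum(path: Path, expected: str) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != expected:
        raise ValueError(
            f"fixture {path.name} is corrupted: sha256 {digest} != {expected}"
        )


def load_fixture(name: str):
    """Load a packaged fixture as its natural in-memory type.

    - ``table1`` -> list[Factor]
    - ``table2`` -> ExperimentTable (30 design runs with yields + composite)
    - ``table4`` -> DataFrame (group, predicted) of 25 model predictions
    - ``table5`` -> DataFrame of 2 x 5 verification replicates
    """
    path = fixture_path(name)
    if name == "table1":
        return load_factors(path)
    if name == "table2":
        return ExperimentTable.from_csv(path, load_fixture("table1"))
    return pd.read_csv(path)
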