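"""Radical-scavenging assay arithmetic and linear calibration utilities."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayMeasurement",
    "CalibrationLine",
    "scavenging_percent",
    "fit_calibration",
    "concentration_from_signal",
    "read_assay_csv",
]


@dataclass(frozen=True)
class AssayMeasurement:
    """Absorbance triplet for a DPPH (517 nm) or ABTS (734 nm) reading.

    A0: sample + solvent blank; A1: reagent-only control; A2: sample + reagent.
    """

    A0: float
    A1: float
    A2: float
    concentration: float | None = None  # mg/mL
    assay: str | None = None  # "DPPH" | "ABTS"

    def __post_init__(self) -> None:
        if min(self.A0, self.A1, self.A2) < 0:
            raise ValueError("absorbances must be nonnegative")
        if self.A1 <= 0:
            raise ValueError("reagent control absorbance A1 must be > 0")


def scavenging_percent(m: AssayMeasurement) -> float:
    """Percent radical scavenging: (1 - (A2 - A0) / A1) * 100."""
    return (1.0 - (m.A2 - m.A0) / m.A1) * 100.0


@dataclass(frozen=True)
class CalibrationLine:
    """signal = slope * concentration + intercept, valid over a stated range."""

    slope: float
    intercept: float
    r2: float
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must be in [0, 1]")
        if not self.valid_range[0] < self.valid_range[1]:
            raise ValueError("valid_range must be (low, high) with low < high")

    def signal(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(
    concentrations: Sequence[float], signals: Sequence[float]
) -> CalibrationLine:
    """Least-squares calibration line through >= 3 standards."""
    conc = np.asarray(concentrations, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    res = stats.linregress(conc, sig)
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        valid_range=(float(conc.min()), float(conc.max())),
    )


def concentration_from_signal(line: CalibrationLine, signal: float) -> float:
    """Invert the calibration line; warns when outside the calibrated range."""
    if line.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; line is not invertible")
    conc = (signal - line.intercept) / line.slope
    lo, hi = line.valid_range
    if not lo <= conc <= hi:
        warnings.warn(
            f"concentration {conc:.4g} mg/mL is outside the calibrated "
            f"range [{lo}, {hi}]",
            UserWarning,
            stacklevel=2,
        )
    return conc


def read_assay_csv(path: str | Path) -> list[AssayMeasurement]:
    """Read an assay plate: columns concentration, A0, A1, A2, assay."""
    df = pd.read_csv(path)
    required = {"concentration", "A0", "A1", "A2", "assay"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV is missing column(s): {sorted(missing)}")
    return [
        AssayMeasurement(
            A0=float(r.A0),
            A1=float(r.A1),
            A2=float(r.A2),
            concentration=float(r.concentration),
            assay=str(r.assay),
        )
        for r in df.itertuples()
    ]
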