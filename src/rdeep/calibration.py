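"""Molecular-weight calibration of the gradient and size classification.

Sedimentation position grows with apparent complex mass; over the wide
MW span of a sucrose gradient a log-linear law ``log10(MW/kDa) =
a * fraction + b`` fitted through reference proteins of known mass maps
any peak position to an apparent molecular weight. Comparing the
apparent MW of a protein's post-RNase peak with its annotated monomer
mass classifies the RNA-free species: smaller than monomeric, roughly
monomeric, still in a complex, or precipitated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError

__all__ = [
    "ReferencePoint",
    "CalibrationModel",
    "DEFAULT_REFERENCE_MASSES",
    "fit_calibration",
    "read_calibration_config",
    "classify_size",
]

#: reference proteins conventionally run alongside the gradient, with the
#: mass of the species they form (oligomers sediment at their complex mass)
DEFAULT_REFERENCE_MASSES = {
    "RNase A": 14.0,
    "BSA": 60.0,
    "Aldolase": 160.0,  # tetramer, 4 x 40 kDa
    "Catalase": 240.0,  # tetramer, 4 x 60 kDa
    "Ferritin": 480.0,  # 24-mer, 24 x 20 kDa
}

SIZE_CLASSES = ("smaller_than_monomer", "monomeric", "in_complex", "precipitated", "unknown")


@dataclass(frozen=True)
class ReferencePoint:
    """A calibration anchor: a protein of known mass and its observed peak."""

    name: str
    mw_kda: float
    peak_fraction: float

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise InvalidParameterError(f"{self.name}: molecular weight must be > 0 kDa")
        if not (1 <= self.peak_fraction <= 25):
            raise InvalidParameterError(f"{self.name}: peak fraction outside [1, 25]")


@dataclass
class CalibrationModel:
    """log10(MW/kDa) = slope * fraction + intercept."""

    slope: float
    intercept: float
    residuals: np.ndarray
    points: list[ReferencePoint]

    def apparent_mw(self, fraction: float) -> float:
        """Apparent molecular weight (kDa) at a gradient position."""
        return float(10.0 ** (self.slope * fraction + self.intercept))

    def is_extrapolated(self, fraction: float) -> bool:
        return not (1.0 <= fraction <= 25.0)

    @property
    def doubling_interval(self) -> float:
        """Fractions per doubling of apparent MW: log10(2) / slope."""
        return float(np.log10(2.0) / self.slope)


def fit_calibration(points: list[ReferencePoint]) -> CalibrationModel:
    """Least-squares log-linear fit through the reference points.

    Requires at least two points at distinct fractions; the fitted slope
    must be positive (heavier complexes sediment farther).
    """
    if len(points) < 2:
        raise ConfigError("calibration needs at least 2 reference points")
    fr = np.array([p.peak_fraction for p in points], dtype=float)
    if len(np.unique(fr)) < 2:
        raise ConfigError("reference points must cover at least 2 distinct fractions")
    logmw = np.log10([p.mw_kda for p in points])
    slope, intercept = np.polyfit(fr, logmw, 1)
    if slope <= 0:
        raise ConfigError(
            "fitted calibration slope is not positive; check reference fractions"
        )
    resid = logmw - (slope * fr + intercept)
    return CalibrationModel(float(slope), float(intercept), resid, sorted(points, key=lambda p: p.peak_fraction))


def read_calibration_config(path: str | Path) -> list[ReferencePoint]:
    """Read a reference table (TSV: name, mw_kda, peak_fraction)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("name", "mw_kda", "peak_fraction") if c not in df.columns]
    if missing:
        raise ConfigError(f"calibration config missing columns {missing}")
    return [
        ReferencePoint(str(r["name"]), float(r["mw_kda"]), float(r["peak_fraction"]))
        for _, r in df.iterrows()
    ]


def classify_size(
    monomeric_mw_kda: float | None,
    rnase_peak_position: float,
    model: CalibrationModel,
    tol: float = 2.0,
    precipitation_fraction: float = 23.0,
) -> str:
    """Size class of a post-RNase peak.

    Peaks beyond the precipitation boundary are ``precipitated``
    regardless of mass. Otherwise the ratio r of apparent MW to monomer
    MW decides: r < 1/tol -> ``smaller_than_monomer``; r <= tol ->
    ``monomeric`` (within a factor tol of the monomer); r > tol ->
    ``in_complex``. Missing monomer mass -> ``unknown``.
    """
    if rnase_peak_position > precipitation_fraction:
        return "precipitated"
    if monomeric_mw_kda is None or (
        isinstance(monomeric_mw_kda, float) and np.isnan(monomeric_mw_kda)
    ):
        return "unknown"
    if monomeric_mw_kda <= 0:
        raise InvalidParameterError("monomeric MW must be positive")
    r = model.apparent_mw(rnase_peak_position) / monomeric_mw_kda
    if r < 1.0 / tol:
        return "smaller_than_monomer"
    if r <= tol:
        return "monomeric"
    return "in_complex"
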