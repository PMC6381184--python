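"""Dextran-unit (DE) calibration and peak annotation for capillary
electrophoresis of APTS-labelled oligosaccharides.

A ladder of standards with known DE values anchors a strictly monotone
piecewise-linear map from migration (instrument units) to DE; product
peaks are then assigned to reference species by nearest DE within a
tolerance.  Only four ladder anchors are typically available, so
piecewise-linear interpolation is used rather than a spline; the default
assignment tolerance of ±0.05 DE separates the closest reference species
(M2 at 1.87 vs G at 2.10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DE_REFERENCES",
    "DextranLadder",
    "DeCalibration",
    "AnnotatedPeak",
    "calibrate_de",
    "annotate_peaks",
]

# Reference DE values of identified hydrolysis products and ladder species.
DEFAULT_DE_REFERENCES: dict[str, float] = {
    "M1": 0.9,
    "M2": 1.87,
    "M3": 2.85,
    "MMG": 3.81,
    "G": 2.10,
    "MGG": 4.10,
}

# Ladder run with the product electropherograms: mannose to MMG.
DEFAULT_LADDER_DE = {"M1": 0.9, "M2": 1.87, "M3": 2.85, "MMG": 3.81}


@dataclass
class DextranLadder:
    """Calibration anchors: (migration, DE), jointly strictly monotone."""

    anchors: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("ladder needs >= 2 anchors")
        mig = np.array([a[0] for a in self.anchors])
        de = np.array([a[1] for a in self.anchors])
        if np.any(np.diff(mig) <= 0) or np.any(np.diff(de) <= 0):
            raise ValueError("ladder anchors must be strictly increasing in migration and DE")

    @classmethod
    def from_file(cls, path: str | Path) -> "DextranLadder":
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        rows = df.iloc[:, :2].astype(float)
        return cls(sorted((float(m), float(d)) for m, d in rows.itertuples(index=False)))


@dataclass
class DeCalibration:
    """Strictly monotone piecewise-linear migration → DE map; extrapolates
    linearly beyond the anchors with a warning."""

    migration: np.ndarray
    de: np.ndarray

    def __call__(self, migration: float | np.ndarray) -> np.ndarray:
        m = np.atleast_1d(np.asarray(migration, dtype=float))
        out = np.interp(m, self.migration, self.de)
        below = m < self.migration[0]
        above = m > self.migration[-1]
        if below.any():
            slope = (self.de[1] - self.de[0]) / (self.migration[1] - self.migration[0])
            out[below] = self.de[0] + slope * (m[below] - self.migration[0])
        if above.any():
            slope = (self.de[-1] - self.de[-2]) / (self.migration[-1] - self.migration[-2])
            out[above] = self.de[-1] + slope * (m[above] - self.migration[-1])
        if below.any() or above.any():
            warnings.warn("migration outside ladder range; DE extrapolated", stacklevel=2)
        return out if np.ndim(migration) else float(out[0])


def calibrate_de(ladder: DextranLadder) -> DeCalibration:
    """Piecewise-linear interpolant through the ladder anchors (identity on
    the anchors themselves)."""
    mig = np.array([a[0] for a in ladder.anchors], dtype=float)
    de = np.array([a[1] for a in ladder.anchors], dtype=float)
    return DeCalibration(mig, de)


@dataclass
class AnnotatedPeak:
    """One electropherogram peak with its DE and optional species call."""

    migration: float
    de: float
    species: str | None
    delta_de: float | None

    def __post_init__(self) -> None:
        if self.species is not None and self.delta_de is None:
            raise ValueError("assigned peak must record its DE distance")


def annotate_peaks(
    migrations: Sequence[float],
    calibration: DeCalibration,
    reference: Mapping[str, float] | None = None,
    tolerance: float = 0.05,
) -> list[AnnotatedPeak]:
    """Assign each peak the nearest reference species within ``tolerance``
    DE, else leave it unassigned.  Deterministic and order-independent."""
    ref = dict(DEFAULT_DE_REFERENCES if reference is None else reference)
    names = list(ref)
    ref_de = np.array([ref[n] for n in names])
    out = []
    for m in migrations:
        de = float(calibration(m))
        dist = np.abs(ref_de - de)
        i = int(np.argmin(dist))
        if dist[i] <= tolerance:
            out.append(AnnotatedPeak(float(m), de, names[i], float(dist[i])))
        else:
            out.append(AnnotatedPeak(float(m), de, None, None))
    return out
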