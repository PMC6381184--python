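"""Enzyme-kinetics estimators for endomannanase characterisation.

Three routes to the catalytic efficiency kcat/K_M:

* nonlinear Michaelis–Menten least squares on initial rates (polymeric
  substrates, mg/ml units);
* linear regression of the low-[S] (first-order) part of the rate curve,
  the fallback when saturation is not reached;
* first-order substrate depletion at [S] ≪ K_M, where
  ln(S₀/Sₜ) = (kcat/K_M)·[E]·t, regressed through the origin on points
  below 25% conversion (oligosaccharide substrates, mM units).

Plus reducing-end assay helpers: PAHBAH calibration, initial-rate window
selection, and the U/µmole ↔ s⁻¹ activity conversion (1 U = 1 µmole
reducing ends released per minute, so turnover = specific activity / 60).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "KineticSeries",
    "DepletionSeries",
    "EfficiencyFit",
    "ActivityMeasurement",
    "fit_michaelis_menten",
    "fit_linear_efficiency",
    "fit_depletion",
    "specific_activity_to_turnover",
    "pahbah_calibrate",
    "initial_rate",
]

UnitSystem = Literal["mg/ml", "mM"]


@dataclass
class KineticSeries:
    """Initial rates Vᵢ at substrate concentrations [S], with the enzyme
    concentration used (molar units matching the unit system)."""

    substrate_conc: np.ndarray
    rate: np.ndarray
    enzyme_conc: float
    units: UnitSystem = "mg/ml"

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_conc.shape != self.rate.shape:
            raise ValueError("substrate_conc and rate must have equal length")
        if np.any(self.substrate_conc < 0) or np.any(self.rate < 0):
            raise ValueError("concentrations and rates must be non-negative")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")

    @classmethod
    def from_file(cls, path: str | Path, enzyme_conc: float, units: UnitSystem = "mg/ml"):
        df = _read_numeric(path, 2)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), enzyme_conc, units)


@dataclass
class DepletionSeries:
    """Remaining substrate Sₜ over time at low initial concentration S₀."""

    time: np.ndarray
    substrate: np.ndarray
    s0: float
    enzyme_conc: float
    units: UnitSystem = "mM"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        if self.time.shape != self.substrate.shape:
            raise ValueError("time and substrate must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.substrate <= 0):
            raise ValueError("remaining substrate must be positive")
        if np.any(self.substrate > self.s0 * (1 + 1e-9)):
            raise ValueError("remaining substrate exceeds S0")
        if self.enzyme_conc <= 0 or self.s0 <= 0:
            raise ValueError("enzyme_conc and S0 must be positive")

    @classmethod
    def from_file(cls, path: str | Path, s0: float, enzyme_conc: float, units: UnitSystem = "mM"):
        df = _read_numeric(path, 2)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), s0, enzyme_conc, units)


def _read_numeric(path: str | Path, ncols: int) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return df.iloc[:, :ncols].astype(float)


@dataclass
class EfficiencyFit:
    """Kinetic parameters with uncertainties from one of the three fits."""

    efficiency: float
    efficiency_se: float | None
    method: Literal["mm_nls", "linear", "depletion"]
    units: UnitSystem
    kcat: float | None = None
    kcat_se: float | None = None
    K_M: float | None = None
    K_M_se: float | None = None
    r_squared: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kcat is not None and self.K_M is not None:
            if abs(self.efficiency - self.kcat / self.K_M) > 1e-9 * abs(self.efficiency):
                raise ValueError("efficiency must equal kcat/K_M")

    def compare_efficiency(self, other: "EfficiencyFit") -> float:
        """Efficiency ratio self/other; refuses cross-unit comparison."""
        if self.units != other.units:
            raise ValueError(
                f"cannot compare efficiencies across unit systems "
                f"({self.units} vs {other.units})"
            )
        return self.efficiency / other.efficiency

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "units": self.units,
            "efficiency": self.efficiency,
            "efficiency_se": self.efficiency_se,
            "kcat": self.kcat,
            "kcat_se": self.kcat_se,
            "K_M": self.K_M,
            "K_M_se": self.K_M_se,
            "r_squared": self.r_squared,
            "warnings": self.warnings,
        }


def _r_squared(y: np.ndarray, y_fit: np.ndarray, through_origin: bool = False) -> float:
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum(y**2) if through_origin else np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(series: KineticSeries) -> EfficiencyFit:
    """Unweighted nonlinear least-squares fit of Vᵢ = Vmax·[S]/(K_M + [S]).

    kcat = Vmax/[E].  Initialised at Vmax₀ = max rate and K_M₀ = [S] at
    half-maximal rate by interpolation.  Flags unreached saturation when
    max [S] < 2·K_M.
    """
    s, v = series.substrate_conc, series.rate
    if len(np.unique(s)) < 4:
        raise ValueError("need rates at >= 4 distinct substrate concentrations")
    if np.all(v == 0):
        raise ValueError("all rates are zero")

    order = np.argsort(s)
    vmax0 = float(v.max())
    half = vmax0 / 2
    km0 = float(np.interp(half, v[order], s[order]))
    if km0 <= 0:
        km0 = float(np.median(s))

    model = Model(_mm)
    params = model.make_params(vmax=vmax0, km=km0)
    params["vmax"].min = 0
    params["km"].min = 1e-12
    result = model.fit(v, params, s=s)
    if not result.success:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {result.message}")

    vmax = result.params["vmax"].value
    km = result.params["km"].value
    vmax_se = result.params["vmax"].stderr
    km_se = result.params["km"].stderr

    e = series.enzyme_conc
    kcat = vmax / e
    kcat_se = vmax_se / e if vmax_se is not None else None
    eff = kcat / km
    eff_se = None
    if result.covar is not None and vmax_se is not None and km_se is not None:
        cov = result.covar
        iv, ik = result.var_names.index("vmax"), result.var_names.index("km")
        rel_var = (
            cov[iv, iv] / vmax**2 + cov[ik, ik] / km**2 - 2 * cov[iv, ik] / (vmax * km)
        )
        eff_se = abs(eff) * np.sqrt(max(rel_var, 0.0))

    warns = []
    if s.max() < 2 * km:
        warns.append(
            f"saturation was not reached: max [S] ({s.max():g} {series.units}) "
            f"< 2*K_M ({2 * km:g} {series.units}); consider fit_linear_efficiency"
        )
        warnings.warn(warns[-1], stacklevel=2)

    return EfficiencyFit(
        efficiency=eff,
        efficiency_se=eff_se,
        method="mm_nls",
        units=series.units,
        kcat=kcat,
        kcat_se=kcat_se,
        K_M=km,
        K_M_se=km_se,
        r_squared=_r_squared(v, result.best_fit),
        warnings=warns,
    )


def fit_linear_efficiency(series: KineticSeries, low_s_fraction: float = 0.25) -> EfficiencyFit:
    """Efficiency from the first-order (low-[S]) limit, V ≈ (kcat/K_M)·[E]·[S].

    Uses points with [S] at or below ``low_s_fraction`` of the abscissa of
    the rate maximum; the slope of V vs [S] through the origin divided by
    [E] is kcat/K_M.  kcat and K_M are not separable here.
    """
    s, v = series.substrate_conc, series.rate
    s_at_max = s[np.argmax(v)]
    mask = s <= low_s_fraction * s_at_max
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 points with [S] <= {low_s_fraction:g} x the rate maximum's "
            f"abscissa ({s_at_max:g}); got {int(mask.sum())}"
        )
    s_lo, v_lo = s[mask], v[mask]
    slope = float(np.sum(s_lo * v_lo) / np.sum(s_lo**2))
    resid = v_lo - slope * s_lo
    dof = len(s_lo) - 1
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(s_lo**2))) if dof else None
    e = series.enzyme_conc
    return EfficiencyFit(
        efficiency=slope / e,
        efficiency_se=slope_se / e if slope_se is not None else None,
        method="linear",
        units=series.units,
        r_squared=_r_squared(v_lo, slope * s_lo, through_origin=True),
    )


def fit_depletion(series: DepletionSeries, max_conversion: float = 0.25) -> EfficiencyFit:
    """First-order depletion estimator: ln(S₀/Sₜ) = (kcat/K_M)·[E]·t.

    Only points at or below ``max_conversion`` (default 25%) substrate
    conversion are used; the regression is through the origin since
    ln(S₀/S₀) = 0 at t = 0 exactly.
    """
    if len(series.time) < 3:
        raise ValueError("need >= 3 time points")
    conversion = 1.0 - series.substrate / series.s0
    mask = conversion <= max_conversion + 1e-12
    if not mask.any():
        raise ValueError(
            f"all points exceed {100 * max_conversion:.0f}% conversion; the "
            f"first-order estimator is not applicable"
        )
    t = series.time[mask]
    y = np.log(series.s0 / series.substrate[mask])
    slope = float(np.sum(t * y) / np.sum(t**2))
    resid = y - slope * t
    dof = len(t) - 1
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(t**2))) if dof else None
    e = series.enzyme_conc
    return EfficiencyFit(
        efficiency=slope / e,
        efficiency_se=slope_se / e if slope_se is not None else None,
        method="depletion",
        units=series.units,
        r_squared=_r_squared(y, slope * t, through_origin=True),
    )


# ---------------------------------------------------------------------------
# activity units and reducing-end assay helpers


@dataclass(frozen=True)
class ActivityMeasurement:
    """Specific activity (U per µmole enzyme; 1 U = 1 µmole reducing ends
    per minute) and the equivalent turnover rate in s⁻¹."""

    specific_activity: float
    turnover: float

    def __post_init__(self) -> None:
        if abs(self.turnover - self.specific_activity / 60.0) > 1e-9:
            raise ValueError("turnover must equal specific_activity / 60")


def specific_activity_to_turnover(a: float, rounded: bool = True) -> float:
    """Convert U/µmole enzyme to a turnover rate in s⁻¹ (divide by 60).

    With ``rounded`` the result is reported at conventional display
    precision: nearest integer at ≥ 10 s⁻¹, one decimal below.
    """
    if a < 0:
        raise ValueError("specific activity must be non-negative")
    turnover = a / 60.0
    if not rounded:
        return turnover
    return float(round(turnover)) if turnover >= 10 else round(turnover, 1)


@dataclass
class PahbahCalibration:
    """Linear reducing-end calibration: signal = slope·conc + intercept."""

    slope: float
    intercept: float
    conc_range: tuple[float, float]

    def apply(self, signal: float) -> float:
        """Invert the calibration; warns on extrapolation, clamps below-blank
        signals to concentration 0."""
        conc = (signal - self.intercept) / self.slope
        if conc < 0:
            warnings.warn("signal below blank; clamping concentration to 0", stacklevel=2)
            return 0.0
        if not self.conc_range[0] <= conc <= self.conc_range[1]:
            warnings.warn(
                f"concentration {conc:g} outside standard range {self.conc_range}",
                stacklevel=2,
            )
        return conc


def pahbah_calibrate(standards: Sequence[tuple[float, float]]) -> PahbahCalibration:
    """Ordinary least-squares line through reducing-sugar standards
    (mannose concentration, signal)."""
    if len(standards) < 3:
        raise ValueError("need >= 3 standards")
    conc = np.array([c for c, _ in standards], dtype=float)
    sig = np.array([s for _, s in standards], dtype=float)
    order = np.argsort(conc)
    conc, sig = conc[order], sig[order]
    if np.any(np.diff(sig) <= 0):
        raise ValueError("standard signals must increase monotonically with concentration")
    slope, intercept = np.polyfit(conc, sig, 1)
    return PahbahCalibration(float(slope), float(intercept), (float(conc[0]), float(conc[-1])))


def initial_rate(
    timecourse: Sequence[tuple[float, float]], r2_threshold: float = 0.98
) -> float:
    """Slope of the longest initial window of a product time course whose
    linear fit keeps R² ≥ ``r2_threshold``."""
    if len(timecourse) < 3:
        raise ValueError("need >= 3 time points")
    t = np.array([p[0] for p in timecourse], dtype=float)
    y = np.array([p[1] for p in timecourse], dtype=float)
    for end in range(len(t), 2, -1):
        tt, yy = t[:end], y[:end]
        slope, intercept = np.polyfit(tt, yy, 1)
        if _r_squared(yy, slope * tt + intercept) >= r2_threshold:
            return float(slope)
    raise ValueError(f"no initial window of >= 3 points reaches R^2 >= {r2_threshold}")
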