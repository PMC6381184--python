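"""Isotope envelopes and ¹⁸O heavy/light product deconvolution.

Hydrolysis in H₂¹⁸O labels the newly formed reducing end of the glycon
(enzyme-retained) fragment with ¹⁸O, while the leaving-group fragment keeps
its original ¹⁶O reducing end.  The heavy:light ratio of a product is read
from MALDI-TOF monoisotopic peak areas and corrected twice:

1. **M+2 overlap** — the natural (M+2) isotope peak of the light species
   falls on the heavy monoisotopic peak and is subtracted using the light
   species' envelope ratio a₂/a₀;
2. **incomplete labelling** — the reaction water is only a fraction *p*
   H₂¹⁸O (default 0.92), so the observed heavy area is scaled by 1/p and
   the deficit reassigned to the light pool, conserving the total.

Peak areas are taken at monoisotopic positions only; no envelope fitting.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .glycans import Glycan, adduct_mz

__all__ = [
    "ISOTOPE_ABUNDANCES",
    "HEAVY_SHIFT_DA",
    "IsotopeEnvelope",
    "PeakList",
    "LabelingConfig",
    "LabelPair",
    "isotope_envelope",
    "extract_pair",
    "correct_m2_overlap",
    "correct_labeling",
    "ratio_string",
]

# IUPAC natural isotopic abundances keyed by nominal mass offset from the
# lightest isotope.
ISOTOPE_ABUNDANCES: dict[str, dict[int, float]] = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "Na": {0: 1.0},
}

# exact 18O - 16O mass difference (Da)
HEAVY_SHIFT_DA = 2.004246


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative abundances at nominal offsets 0, +1, +2, … Da from the
    monoisotopic peak; normalised to sum to 1."""

    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        a = self.abundances
        if not a or a[0] <= 0:
            raise ValueError("envelope must have a positive monoisotopic abundance")
        if abs(sum(a) - 1.0) > 1e-9:
            raise ValueError("envelope abundances must sum to 1")

    def ratio(self, i: int) -> float:
        """aᵢ/a₀; zero beyond the truncation point."""
        if i >= len(self.abundances):
            return 0.0
        return self.abundances[i] / self.abundances[0]


def isotope_envelope(f: Counter | dict[str, int], n_peaks: int | None = None) -> IsotopeEnvelope:
    """Natural isotope envelope of a formula by polynomial convolution.

    Each element contributes its per-atom isotope polynomial raised to the
    atom count; the product over elements gives the abundance at each
    nominal mass offset.  Truncated where the cumulative fraction reaches
    1 − 1e−6 (or at ``n_peaks`` if given), then renormalised.
    """
    if n_peaks is not None and n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    env = np.array([1.0])
    for element, count in f.items():
        if element not in ISOTOPE_ABUNDANCES:
            raise ValueError(f"unknown element {element!r}")
        if count == 0:
            continue
        iso = ISOTOPE_ABUNDANCES[element]
        atom = np.zeros(max(iso) + 1)
        for offset, ab in iso.items():
            atom[offset] = ab
        # exponentiation by squaring over convolution
        power = np.array([1.0])
        base = atom
        k = count
        while k:
            if k & 1:
                power = np.convolve(power, base)
            k >>= 1
            if k:
                base = np.convolve(base, base)
        env = np.convolve(env, power)
    cum = np.cumsum(env)
    cut = int(np.searchsorted(cum, 1.0 - 1e-6)) + 1
    if n_peaks is not None:
        cut = n_peaks
    env = env[:cut] if cut <= len(env) else np.pad(env, (0, cut - len(env)))
    env = env / env.sum()
    return IsotopeEnvelope(tuple(env))


# ---------------------------------------------------------------------------
# peak lists


@dataclass
class PeakList:
    """A centroided spectrum: strictly increasing m/z with non-negative areas."""

    mz: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.mz.shape != self.area.shape or self.mz.ndim != 1:
            raise ValueError("mz and area must be 1-D arrays of equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.area < 0):
            raise ValueError("peak areas must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    @classmethod
    def from_file(cls, path: str | Path) -> "PeakList":
        """Read a two-column delimited text file (m/z, area); header optional."""
        df = _read_two_columns(path, ["mz", "area"])
        order = np.argsort(df["mz"].to_numpy())
        return cls(df["mz"].to_numpy()[order], df["area"].to_numpy()[order])

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"mz": self.mz, "area": self.area}).to_csv(path, sep="\t", index=False)


def _read_two_columns(path: str | Path, names: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    # tolerate a header row of non-numeric labels
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    df = df.iloc[:, : len(names)].copy()
    df.columns = names
    for i, c in enumerate(names):
        try:
            df[c] = df[c].astype(float)
        except (TypeError, ValueError):
            if i > 0:
                raise
    return df


@dataclass(frozen=True)
class LabelingConfig:
    """¹⁸O labelling parameters.

    p
        Fraction of reaction water that is H₂¹⁸O (default 0.92, the usual
        enrichment reached when diluting 97% ¹⁸O stock water into a reaction).
    heavy_shift
        Mass increment per ¹⁸O, the exact ¹⁸O−¹⁶O difference (Da).
    match_tolerance
        m/z window for assigning peaks to theoretical positions (Da).
    """

    p: float = 0.92
    heavy_shift: float = HEAVY_SHIFT_DA
    match_tolerance: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("labelling fraction p must be in (0, 1]")
        if self.heavy_shift <= 0:
            raise ValueError("heavy_shift must be positive")


@dataclass(frozen=True)
class LabelPair:
    """Light/heavy monoisotopic areas for one product species.

    Before corrections the areas are raw peak areas; after
    :func:`correct_labeling` they are the deconvolved light/heavy molar
    proportions (``corrected=True``).
    """

    species: Glycan
    light_area: float
    heavy_area: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.light_area < 0 or self.heavy_area < 0:
            raise ValueError("areas must be non-negative")

    @property
    def heavy_fraction(self) -> float:
        total = self.light_area + self.heavy_area
        if total == 0:
            return 0.0
        return self.heavy_area / total


def _match_peak(peaks: PeakList, target: float, tol: float) -> int:
    hits = np.nonzero(np.abs(peaks.mz - target) <= tol)[0]
    if len(hits) == 0:
        raise ValueError(f"no peak within {tol} Da of expected m/z {target:.3f}")
    if len(hits) > 1:
        raise ValueError(
            f"ambiguous match: {len(hits)} peaks within {tol} Da of m/z {target:.3f}"
        )
    return int(hits[0])


def extract_pair(peaks: PeakList, species: Glycan, cfg: LabelingConfig) -> LabelPair:
    """Read raw light/heavy monoisotopic areas for a species from a spectrum.

    The light position is the sodium-adduct monoisotopic m/z; the heavy
    position is that plus ``cfg.heavy_shift``.
    """
    light_mz = adduct_mz(species)
    i_light = _match_peak(peaks, light_mz, cfg.match_tolerance)
    i_heavy = _match_peak(peaks, light_mz + cfg.heavy_shift, cfg.match_tolerance)
    return LabelPair(species, float(peaks.area[i_light]), float(peaks.area[i_heavy]))


def correct_m2_overlap(pair: LabelPair, env: IsotopeEnvelope) -> LabelPair:
    """Subtract the light species' natural (M+2) peak from the heavy area.

    The observed heavy monoisotopic area contains the light species' +2
    isotopologue: A_heavy = H·a₀ + L·a₂.  Subtracting light_area·(a₂/a₀)
    leaves H·a₀.  A negative result (noise) is clamped to 0 with a warning.
    """
    if pair.corrected:
        raise ValueError("pair is already fully corrected")
    heavy = pair.heavy_area - pair.light_area * env.ratio(2)
    if heavy < 0:
        warnings.warn(
            f"M+2 correction drove the heavy area of {pair.species} negative "
            f"({heavy:.3g}); clamped to 0",
            stacklevel=2,
        )
        heavy = 0.0
    return replace(pair, heavy_area=heavy)


def correct_labeling(pair: LabelPair, cfg: LabelingConfig) -> LabelPair:
    """Correct for the fraction (1−p) of ordinary H₂¹⁶O in the reaction.

    Only a fraction p of glycon products acquire ¹⁸O, so the true heavy
    pool is heavy/p; the remainder of the total is light.  The total is
    conserved exactly.
    """
    if pair.corrected:
        raise ValueError("pair is already corrected")
    total = pair.light_area + pair.heavy_area
    heavy_true = pair.heavy_area / cfg.p
    if heavy_true > total * (1 + 1e-12):
        raise ValueError(
            f"labelling fraction p={cfg.p} inconsistent with data: corrected heavy "
            f"{heavy_true:.4g} exceeds total {total:.4g}"
        )
    light_true = total - heavy_true
    return LabelPair(pair.species, light_true, heavy_true, corrected=True)


def ratio_string(pair: LabelPair) -> str:
    """Light:heavy ratio of a corrected pair as ``"1:x"`` (x to one decimal)."""
    if not pair.corrected:
        raise ValueError("ratio_string requires a corrected pair")
    if pair.light_area == 0:
        return "0:1 (no light product)"
    return f"1:{pair.heavy_area / pair.light_area:.1f}"
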