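"""Synthetic instrument data with the statistical structure the analysis
assumes: MALDI-TOF isotope envelopes of sodiated products with a mixed
heavy/light reducing-end oxygen population, HPAEC-style product tables
drawn from binding-mode frequencies, Michaelis–Menten initial-rate series,
first-order depletion time courses, and decorated galactomannan polymers.

Noise is multiplicative log-normal (CV-parameterised) on areas and rates,
with an optional uniform additive baseline on spectra.  Every generator is
deterministic under a fixed seed, and zero-noise outputs are exactly
invertible by the corresponding estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .glycans import Glycan, adduct_mz, formula
from .isotopes import LabelingConfig, PeakList, isotope_envelope
from .kinetics import DepletionSeries, KineticSeries
from .subsites import ModeFrequencies, ProductTable, simulate_digest

__all__ = [
    "NoiseModel",
    "PolymerSpec",
    "gen_spectrum",
    "gen_hpaec_table",
    "gen_mm_series",
    "gen_depletion_series",
    "gen_polymer",
]

# nominal spacing of adjacent isotopologue peaks (approx. 13C-12C), Da
ISOTOPE_SPACING = 1.00336


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise (coefficient of variation ``cv``)
    plus an optional uniform additive baseline for spectra."""

    cv: float = 0.02
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.baseline < 0:
            raise ValueError("cv and baseline must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(values, dtype=float)
        if self.cv > 0:
            sigma = np.sqrt(np.log1p(self.cv**2))
            out = out * rng.lognormal(-(sigma**2) / 2, sigma, size=out.shape)
        if self.baseline > 0:
            out = out + rng.uniform(0, self.baseline, size=out.shape)
        return out


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_spectrum(
    components: Sequence[tuple[Glycan, float, float]],
    cfg: LabelingConfig,
    noise: NoiseModel = NoiseModel(cv=0.0),
    seed: int | np.random.Generator | None = None,
) -> PeakList:
    """Forward-model a MALDI-TOF peak list of sodiated products.

    ``components`` are (species, total molar amount, true glycon fraction θ);
    a fraction θ·p of each species carries the ¹⁸O reducing end.  The light
    envelope is placed at the sodium-adduct m/z; light isotopologues at +2
    and beyond merge with the heavy envelope at +heavy_shift, so the
    observed heavy monoisotopic area is H·a₀ + L·a₂ by construction.
    """
    rng = _rng(seed)
    peaks: dict[float, float] = {}
    for species, total, theta in components:
        if not 0 <= theta <= 1:
            raise ValueError("glycon fraction must be in [0, 1]")
        heavy = total * theta * cfg.p
        light = total - heavy
        env = isotope_envelope(formula(species))
        m0 = adduct_mz(species)
        for i, a in enumerate(env.abundances):
            if i < 2:
                mz = m0 + i * ISOTOPE_SPACING
                peaks[mz] = peaks.get(mz, 0.0) + light * a
            else:
                mz = m0 + cfg.heavy_shift + (i - 2) * ISOTOPE_SPACING
                peaks[mz] = peaks.get(mz, 0.0) + light * a
        for i, a in enumerate(env.abundances):
            mz = m0 + cfg.heavy_shift + i * ISOTOPE_SPACING
            peaks[mz] = peaks.get(mz, 0.0) + heavy * a
    mz = np.array(sorted(peaks))
    area = noise.apply(np.array([peaks[m] for m in mz]), rng)
    return PeakList(mz, area)


def gen_hpaec_table(
    substrate: Glycan,
    freqs: ModeFrequencies,
    n_events: int,
    cfg: LabelingConfig = LabelingConfig(),
    noise: NoiseModel = NoiseModel(cv=0.0),
    seed: int | np.random.Generator | None = None,
) -> ProductTable:
    """Chromatographic product table from simulated digestion events, with
    multiplicative quantification noise."""
    rng = _rng(seed)
    table, _ = simulate_digest(substrate, freqs, n_events, cfg, rng)
    noisy = noise.apply(np.array(list(table.amounts.values())), rng)
    return ProductTable(dict(zip(table.amounts, noisy)))


def gen_mm_series(
    kcat: float,
    K_M: float,
    enzyme_conc: float,
    s_grid: Sequence[float],
    noise: NoiseModel = NoiseModel(cv=0.0),
    seed: int | np.random.Generator | None = None,
    units: Literal["mg/ml", "mM"] = "mg/ml",
) -> KineticSeries:
    """Initial-rate series from the Michaelis–Menten law
    V = kcat·[E]·[S]/(K_M + [S]); zero-noise output is exact."""
    if kcat < 0 or K_M <= 0 or enzyme_conc <= 0:
        raise ValueError("parameters must be positive")
    rng = _rng(seed)
    s = np.asarray(s_grid, dtype=float)
    v = kcat * enzyme_conc * s / (K_M + s)
    return KineticSeries(s, noise.apply(v, rng), enzyme_conc, units)


def gen_depletion_series(
    efficiency: float,
    enzyme_conc: float,
    s0: float,
    times: Sequence[float],
    noise: NoiseModel = NoiseModel(cv=0.0),
    seed: int | np.random.Generator | None = None,
    units: Literal["mg/ml", "mM"] = "mM",
) -> DepletionSeries:
    """First-order depletion Sₜ = S₀·exp(−(kcat/K_M)·[E]·t); zero-noise
    output is exact."""
    if efficiency < 0 or enzyme_conc <= 0 or s0 <= 0:
        raise ValueError("parameters must be positive")
    rng = _rng(seed)
    t = np.asarray(times, dtype=float)
    st = s0 * np.exp(-efficiency * enzyme_conc * t)
    st = np.minimum(noise.apply(st, rng), s0)
    return DepletionSeries(t, st, s0, enzyme_conc, units)


# ---------------------------------------------------------------------------
# decorated polymers


@dataclass(frozen=True)
class PolymerSpec:
    """A galactomannan polymer to emulate.

    ``pattern`` selects the decoration process: ``guar`` — galactosyls
    mainly in pairs/triplets with few bare stretches, Gal:Man 1:2;
    ``locust_bean`` — blockwise-irregular with long unsubstituted blocks,
    Gal:Man 1:4.  Default lengths follow the degrees of polymerisation of
    the two gums (900 and 1500).
    """

    pattern: Literal["guar", "locust_bean"]
    length: int | None = None

    def __post_init__(self) -> None:
        if self.length is not None and self.length < 1:
            raise ValueError("length must be >= 1")

    @property
    def n(self) -> int:
        if self.length is not None:
            return self.length
        return 900 if self.pattern == "guar" else 1500

    @property
    def target_density(self) -> float:
        """Decorated fraction of backbone positions (Gal per Man)."""
        return 0.5 if self.pattern == "guar" else 0.25


# Two-state Markov transition probabilities (P(decorated | previous state)),
# tuned so the stationary decorated fraction matches the Gal:Man target while
# reproducing the qualitative run structure: short clustered runs for guar,
# long bare blocks for locust bean gum.
_MARKOV = {
    # (p_decorate_after_bare, p_stay_decorated)
    "guar": (0.3, 0.7),  # stationary 0.3/(0.3+0.3) = 0.5; mean run 3.3
    "locust_bean": (0.1, 0.7),  # stationary 0.1/(0.1+0.3) = 0.25; mean bare block 10
}


def gen_polymer(
    spec: PolymerSpec,
    seed: int | np.random.Generator | None = None,
    substitution_scale: float = 1.0,
) -> Glycan:
    """Draw a decorated mannan backbone from a two-state Markov process.

    ``substitution_scale`` rescales both transition probabilities into the
    decorated state (0 gives a bare mannan).  Positions are numbered from
    the reducing end as for oligosaccharides.
    """
    rng = _rng(seed)
    n = spec.n
    p01, p11 = _MARKOV[spec.pattern]
    p01 *= substitution_scale
    p11 = min(p11 * substitution_scale, 1.0) if substitution_scale < 1 else p11
    if substitution_scale == 0:
        return Glycan(n)
    decorations = set()
    state = rng.random() < spec.target_density * substitution_scale
    for pos in range(1, n + 1):
        if state:
            decorations.add(pos)
        state = rng.random() < (p11 if state else p01)
    return Glycan(n, frozenset(decorations))


# ---------------------------------------------------------------------------
# fixture writers


def make_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    cfg: LabelingConfig = LabelingConfig(),
) -> dict[str, Path]:
    """Emit a complete worked-example directory of delimited-text inputs:
    a wild-type M5 digest spectrum and product table, MM and depletion
    kinetic series, and a DASH ladder/peak table."""
    from .subsites import BindingMode

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    # M5 digest reproducing the wild-type mode frequencies
    m5 = Glycan(5)
    freqs = ModeFrequencies(
        {
            BindingMode(4, 1): 0.80,
            BindingMode(1, 4): 0.09,
            BindingMode(3, 2): 0.07,
            BindingMode(2, 3): 0.04,
        }
    )
    table, counts = simulate_digest(m5, freqs, 10**6, cfg, rng)
    paths["product_table"] = out / "m5_products.tsv"
    table.to_file(paths["product_table"])

    components = []
    for name, size in (("M4", 4), ("M3", 3)):
        h, l = counts.get(name, (0, 0))
        total = h + l
        theta = (h / cfg.p) / total if total else 0.0
        components.append((Glycan(size), float(total), theta))
    spectrum = gen_spectrum(components, cfg, NoiseModel(cv=0.0), rng)
    paths["spectrum"] = out / "m5_spectrum.tsv"
    spectrum.to_file(paths["spectrum"])

    mm = gen_mm_series(636.0, 2.2, 4e-9, np.linspace(0.1, 10, 10), NoiseModel(0.02), rng)
    paths["mm_series"] = out / "mm_guar_wt.tsv"
    np.savetxt(
        paths["mm_series"],
        np.column_stack([mm.substrate_conc, mm.rate]),
        delimiter="\t",
        header="substrate_conc\trate",
        comments="",
    )

    times = np.arange(2.0, 50.0, 5.4) * 60.0
    dep = gen_depletion_series(84.0, 2e-6, 0.1, times, NoiseModel(0.02), rng)
    paths["depletion_series"] = out / "depletion_mggmm_wt.tsv"
    np.savetxt(
        paths["depletion_series"],
        np.column_stack([dep.time, dep.substrate]),
        delimiter="\t",
        header="time_s\tsubstrate_mM",
        comments="",
    )

    paths["dash_ladder"] = out / "dash_ladder.tsv"
    with open(paths["dash_ladder"], "w") as fh:
        fh.write("migration\tde\n")
        for i, (name, de) in enumerate(
            (("M1", 0.9), ("M2", 1.87), ("M3", 2.85), ("MMG", 3.81))
        ):
            fh.write(f"{10.0 + 5.0 * i:.2f}\t{de}\n")
    return paths
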