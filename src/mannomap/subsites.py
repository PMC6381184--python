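"""Productive binding modes across a glycosidase cleft and their inference.

An endomannanase cleft has glycon subsites −1…−n and aglycon subsites
+1…+n (no subsite 0); cleavage occurs between −1 and +1.  A *productive*
binding mode of an oligosaccharide is a contiguous placement occupying
both −1 and +1.  Each mode yields two products: the glycon fragment gains
a new (¹⁸O-labelled, "heavy") reducing end, the aglycon fragment keeps the
original ("light") one.

Two distinct modes can yield the same product sizes (mannopentaose gives
M4+M1 from both −4..+1 and −1..+4), so chromatographic pair shares alone
cannot resolve them.  Combining a pair's share with the corrected
heavy fraction of one member splits it:

    frequency(mode with heavy product P) = share(pair) × heavy_fraction(P)
    frequency(complement mode)           = share(pair) × (1 − heavy_fraction(P))
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .glycans import Glycan, format_name, parse_name, residue_at_subsite
from .isotopes import LabelPair, LabelingConfig

__all__ = [
    "SubsiteCleft",
    "BindingMode",
    "ModeFrequencies",
    "ProductTable",
    "enumerate_modes",
    "products_of_mode",
    "mode_count",
    "pair_shares",
    "infer_mode_frequencies",
    "simulate_digest",
]

# Galactosyl decorations are tolerated in these subsites by the fungal GH26
# endomannanases studied here (and excluded elsewhere in the cleft).
DEFAULT_DECORATION_ALLOWED = frozenset({-3, -2, -1, 1})


@dataclass(frozen=True)
class SubsiteCleft:
    """Cleft geometry: −n_negative…−1 glycon and +1…+n_positive aglycon
    subsites, plus the set of subsites tolerating a galactosyl decoration."""

    n_negative: int = 4
    n_positive: int = 4
    decoration_allowed: frozenset[int] = DEFAULT_DECORATION_ALLOWED

    def __post_init__(self) -> None:
        if self.n_negative < 1 or self.n_positive < 1:
            raise ValueError("cleft needs at least one subsite on each side")
        object.__setattr__(
            self, "decoration_allowed", frozenset(self.decoration_allowed)
        )
        for s in self.decoration_allowed:
            if s == 0 or not -self.n_negative <= s <= self.n_positive:
                raise ValueError(f"decoration_allowed subsite {s} outside cleft")


@dataclass(frozen=True, order=True)
class BindingMode:
    """One contiguous productive placement: k_neg residues in −k_neg…−1 and
    k_pos residues in +1…+k_pos."""

    k_neg: int
    k_pos: int

    def __post_init__(self) -> None:
        if self.k_neg < 1 or self.k_pos < 1:
            raise ValueError("a productive mode occupies both −1 and +1")

    @property
    def label(self) -> str:
        return f"-{self.k_neg}..+{self.k_pos}"

    def __str__(self) -> str:
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "BindingMode":
        left, right = label.replace("−", "-").split("..")
        return cls(-int(left), int(right))


def mode_count(n: int, cleft: SubsiteCleft) -> int:
    """Number of productive modes for a backbone of length n (closed form)."""
    if n < 1:
        raise ValueError("backbone length must be >= 1")
    lo = max(1, n - cleft.n_positive)
    hi = min(n - 1, cleft.n_negative)
    return max(0, hi - lo + 1)


def enumerate_modes(
    substrate: Glycan,
    cleft: SubsiteCleft,
    enforce_decoration: bool = False,
) -> list[BindingMode]:
    """All productive binding modes of a substrate in a cleft.

    With ``enforce_decoration`` set, modes placing a decorated mannose in a
    subsite outside ``cleft.decoration_allowed`` are excluded (a hard
    include/exclude filter; no energetic weighting).
    """
    n = substrate.backbone_length
    modes = []
    for k_neg in range(max(1, n - cleft.n_positive), min(n - 1, cleft.n_negative) + 1):
        mode = BindingMode(k_neg, n - k_neg)
        if enforce_decoration and not _decorations_tolerated(substrate, mode, cleft):
            continue
        modes.append(mode)
    return modes


def _decorations_tolerated(g: Glycan, mode: BindingMode, cleft: SubsiteCleft) -> bool:
    for pos in g.decorations:
        # invert residue_at_subsite: position -> subsite
        if pos <= mode.k_pos:
            subsite = mode.k_pos - pos + 1
        else:
            subsite = mode.k_pos - pos  # negative
        if subsite not in cleft.decoration_allowed:
            return False
    return True


def products_of_mode(substrate: Glycan, mode: BindingMode) -> tuple[Glycan, Glycan]:
    """(heavy glycon fragment, light aglycon fragment) of one cleavage.

    The glycon fragment comprises backbone positions k_pos+1 … k_pos+k_neg
    (renumbered from its new reducing end); the aglycon fragment keeps
    positions 1 … k_pos and the original reducing end.  Decorations travel
    with their residues.
    """
    if mode.k_neg + mode.k_pos != substrate.backbone_length:
        raise ValueError(
            f"mode {mode} does not cover backbone length {substrate.backbone_length}"
        )
    split = mode.k_pos
    heavy = Glycan(
        mode.k_neg, frozenset(d - split for d in substrate.decorations if d > split)
    )
    light = Glycan(split, frozenset(d for d in substrate.decorations if d <= split))
    return heavy, light


# ---------------------------------------------------------------------------
# product tables and mode frequencies


@dataclass
class ProductTable:
    """Relative molar amounts of quantified product species (chromatography)."""

    amounts: dict[str, float]

    def __post_init__(self) -> None:
        canon = {}
        for name, amount in self.amounts.items():
            if amount < 0:
                raise ValueError(f"negative amount for {name}")
            canon[format_name(parse_name(name))] = float(amount)
        self.amounts = canon

    def get(self, species: Glycan) -> float | None:
        return self.amounts.get(format_name(species))

    @classmethod
    def from_file(cls, path: str | Path) -> "ProductTable":
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        try:
            float(df.iloc[0, 1])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        return cls({str(r.iloc[0]).strip(): float(r.iloc[1]) for _, r in df.iterrows()})

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(
            {"species": list(self.amounts), "amount": list(self.amounts.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ModeFrequencies:
    """Relative frequency of each productive binding mode (sums to 1)."""

    frequencies: dict[BindingMode, float]

    def __post_init__(self) -> None:
        for f in self.frequencies.values():
            if f < -1e-12:
                raise ValueError("frequencies must be non-negative")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1 (got {total})")

    def as_percent(self) -> dict[BindingMode, int]:
        """Frequencies rounded to nearest integer percent."""
        return {m: round(100 * f) for m, f in self.frequencies.items()}

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "mode": [m.label for m in self.frequencies],
                "fraction": list(self.frequencies.values()),
                "percent": [round(100 * f) for f in self.frequencies.values()],
            }
        ).to_csv(path, sep="\t", index=False)


def _pair_groups(
    substrate: Glycan, cleft: SubsiteCleft
) -> dict[tuple[int, int], list[BindingMode]]:
    """Group productive modes by unordered product-size pair (small, large)."""
    groups: dict[tuple[int, int], list[BindingMode]] = {}
    for mode in enumerate_modes(substrate, cleft):
        key = tuple(sorted((mode.k_neg, mode.k_pos)))
        groups.setdefault(key, []).append(mode)
    return groups


def pair_shares(
    substrate: Glycan, cleft: SubsiteCleft, table: ProductTable
) -> dict[tuple[int, int], float]:
    """Relative share of each complementary product pair from molar amounts.

    Each pair's share is computed from the amount of its smaller product
    (and from the larger product where both are quantified; the two
    estimates are averaged if they agree within 5%, otherwise this is an
    error — chromatographic response differences are the caller's
    responsibility).  For a symmetric pair (two identical halves) the
    doubled molar amount is halved.
    """
    groups = _pair_groups(substrate, cleft)
    if not groups:
        raise ValueError("substrate has no productive binding modes in this cleft")

    def amount_for(size_key: tuple[int, int], which: int) -> float | None:
        # distinct species of this size across the group's modes (for a
        # decorated substrate the two modes of a pair yield different species)
        size = size_key[which]
        species = {
            format_name(p)
            for mode in groups[size_key]
            for p in products_of_mode(substrate, mode)
            if p.backbone_length == size
        }
        amounts = [table.amounts[s] for s in species if s in table.amounts]
        if not amounts:
            return None
        amt = float(sum(amounts))
        if size_key[0] == size_key[1]:
            amt /= 2.0  # a symmetric cleavage yields two molecules per event
        return amt

    small = {k: amount_for(k, 0) for k in groups}
    large = {k: amount_for(k, 1) for k in groups}

    def shares_from(amounts: dict) -> dict | None:
        if any(v is None for v in amounts.values()):
            return None
        total = sum(amounts.values())
        if total <= 0:
            return None
        return {k: v / total for k, v in amounts.items()}

    s_small, s_large = shares_from(small), shares_from(large)
    if s_small is None and s_large is None:
        raise ValueError("product table does not quantify every pair")
    if s_small is not None and s_large is not None:
        for k in groups:
            hi, lo = max(s_small[k], s_large[k]), min(s_small[k], s_large[k])
            if hi > 0 and (hi - lo) / hi >= 0.05:
                raise ValueError(
                    f"pair {k}: small/large product shares disagree by >= 5% "
                    f"({s_small[k]:.4f} vs {s_large[k]:.4f})"
                )
        return {k: 0.5 * (s_small[k] + s_large[k]) for k in groups}
    return s_small if s_small is not None else s_large


def infer_mode_frequencies(
    substrate: Glycan,
    cleft: SubsiteCleft,
    table: ProductTable,
    pairs: Iterable[LabelPair],
) -> ModeFrequencies:
    """Infer productive binding-mode frequencies from product quantification
    plus corrected heavy/light label pairs.

    The chromatographic table fixes each complementary pair's share; for a
    pair produced by two distinct modes, the corrected heavy fraction of
    either member splits the share between the modes.
    """
    shares = pair_shares(substrate, cleft, table)
    total = sum(shares.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"pair shares sum to {total}, not 1")

    by_species = {format_name(p.species): p for p in pairs}
    for p in pairs:
        if not p.corrected:
            raise ValueError(f"label pair for {p.species} is not corrected")

    groups = _pair_groups(substrate, cleft)
    freqs: dict[BindingMode, float] = {}
    for key, modes in groups.items():
        share = shares[key]
        if len(modes) == 1:
            freqs[modes[0]] = share
            continue
        if len(modes) != 2:
            raise AssertionError("a size pair is produced by at most two modes")
        resolved = False
        for mode in modes:
            heavy, _ = products_of_mode(substrate, mode)
            pair = by_species.get(format_name(heavy))
            if pair is not None:
                other = modes[1] if mode is modes[0] else modes[0]
                freqs[mode] = share * pair.heavy_fraction
                freqs[other] = share * (1.0 - pair.heavy_fraction)
                resolved = True
                break
        if not resolved:
            raise ValueError(
                f"missing corrected label pair for product size pair {key}: supply a "
                f"heavy/light pair for one of its members"
            )
    return ModeFrequencies(freqs)


def simulate_digest(
    substrate: Glycan,
    freqs: ModeFrequencies,
    n_events: int,
    cfg: LabelingConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[ProductTable, dict[str, tuple[int, int]]]:
    """Forward-simulate single-cleavage digestion events.

    Each event draws a productive mode by frequency; the glycon product is
    ¹⁸O-heavy with probability ``cfg.p``, the aglycon product is always
    light.  Returns the molar product table and raw per-species
    (heavy, light) molecule counts.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    modes = sorted(freqs.frequencies)
    probs = np.array([freqs.frequencies[m] for m in modes])
    counts = rng.multinomial(n_events, probs / probs.sum())

    amounts: dict[str, float] = {}
    hl: dict[str, list[int]] = {}
    for mode, count in zip(modes, counts):
        if count == 0:
            continue
        heavy_g, light_g = products_of_mode(substrate, mode)
        h_name, l_name = format_name(heavy_g), format_name(light_g)
        n_heavy = int(rng.binomial(count, cfg.p))
        amounts[h_name] = amounts.get(h_name, 0.0) + count
        amounts[l_name] = amounts.get(l_name, 0.0) + count
        hl.setdefault(h_name, [0, 0])
        hl.setdefault(l_name, [0, 0])
        hl[h_name][0] += n_heavy
        hl[h_name][1] += count - n_heavy
        hl[l_name][1] += count
    return ProductTable(amounts), {k: (v[0], v[1]) for k, v in hl.items()}
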