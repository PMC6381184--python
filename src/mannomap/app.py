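"""Pipeline orchestration, configuration, and command-line interface.

The subsite pipeline ties the stages together: read a MALDI peak list and
an HPAEC product table, extract and doubly correct heavy/light label
pairs for every size-ambiguous product, combine them with the pair shares
and report productive binding-mode frequencies.

Exit codes: 0 success, 2 input error, 3 inference/fit error.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Literal

import click
import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .glycans import format_name, formula, monoisotopic_mass, parse_name
from .isotopes import (
    LabelPair,
    LabelingConfig,
    PeakList,
    correct_labeling,
    correct_m2_overlap,
    extract_pair,
    isotope_envelope,
    ratio_string,
)
from .kinetics import (
    DepletionSeries,
    EfficiencyFit,
    KineticSeries,
    fit_depletion,
    fit_linear_efficiency,
    fit_michaelis_menten,
)
from .dash import DextranLadder, annotate_peaks, calibrate_de
from .subsites import (
    ModeFrequencies,
    ProductTable,
    SubsiteCleft,
    enumerate_modes,
    infer_mode_frequencies,
    products_of_mode,
    _pair_groups,
)

log = logging.getLogger("mannomap")

EXIT_INPUT_ERROR = 2
EXIT_INFERENCE_ERROR = 3


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; the defaults describe a fungal GH26
    endomannanase (cleft −4…+4, p = 0.92, decorations tolerated in −3, −2,
    −1, +1)."""

    n_negative: int = 4
    n_positive: int = 4
    decoration_allowed: list[int] = Field(default=[-3, -2, -1, 1])
    p: float = 0.92
    heavy_shift: float = 2.004246
    match_tolerance: float = 0.3
    units: Literal["mg/ml", "mM"] = "mM"
    seed: int = 0

    @field_validator("p")
    @classmethod
    def _check_p(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("labelling fraction p must be in (0, 1]")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def cleft(self) -> SubsiteCleft:
        return SubsiteCleft(self.n_negative, self.n_positive, frozenset(self.decoration_allowed))

    def labeling(self) -> LabelingConfig:
        return LabelingConfig(self.p, self.heavy_shift, self.match_tolerance)


def _stage(name: str):
    """Tag exceptions raised inside a pipeline stage with the stage name."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_subsite_pipeline(
    cfg: PipelineConfig,
    spectrum_path: str | Path,
    product_table_path: str | Path,
    substrate: str = "M5",
) -> dict:
    """End-to-end binding-mode inference; returns a machine-readable report
    covering raw areas, both corrections, ratio strings, pair shares and
    final frequencies (fractions and integer percents)."""
    sub = parse_name(substrate)
    cleft = cfg.cleft()
    lab = cfg.labeling()
    log.info("substrate %s, cleft -%d..+%d, p=%.3f", sub, cleft.n_negative, cleft.n_positive, cfg.p)

    with _stage("read-spectrum"):
        peaks = PeakList.from_file(spectrum_path)
        if len(peaks) == 0:
            raise ValueError("spectrum contains no peaks")
    with _stage("read-product-table"):
        table = ProductTable.from_file(product_table_path)

    pairs: list[LabelPair] = []
    pair_report = {}
    with _stage("label-pairs"):
        for key, modes in _pair_groups(sub, cleft).items():
            if len(modes) < 2:
                continue
            pair = None
            errors = []
            for mode in modes:
                heavy, _ = products_of_mode(sub, mode)
                try:
                    pair = extract_pair(peaks, heavy, lab)
                    break
                except ValueError as e:
                    errors.append(str(e))
            if pair is None:
                raise ValueError(
                    f"no label pair extractable for product size pair {key}: "
                    + "; ".join(errors)
                )
            env = isotope_envelope(formula(pair.species))
            raw = pair
            m2 = correct_m2_overlap(raw, env)
            corrected = correct_labeling(m2, lab)
            pairs.append(corrected)
            pair_report[format_name(pair.species)] = {
                "raw_light_area": raw.light_area,
                "raw_heavy_area": raw.heavy_area,
                "m2_corrected_heavy_area": m2.heavy_area,
                "corrected_light": corrected.light_area,
                "corrected_heavy": corrected.heavy_area,
                "heavy_fraction": corrected.heavy_fraction,
                "ratio": ratio_string(corrected),
            }

    with _stage("infer-frequencies"):
        freqs = infer_mode_frequencies(sub, cleft, table, pairs)

    from .subsites import pair_shares as _shares

    report = {
        "substrate": format_name(sub),
        "config": cfg.model_dump(),
        "label_pairs": pair_report,
        "pair_shares": {
            f"{k[0]}+{k[1]}": v for k, v in _shares(sub, cleft, table).items()
        },
        "mode_frequencies": {m.label: f for m, f in freqs.frequencies.items()},
        "mode_percent": {m.label: p for m, p in freqs.as_percent().items()},
    }
    return report


def run_kinetics(
    cfg: PipelineConfig,
    series_path: str | Path,
    method: Literal["mm_nls", "linear", "depletion"],
    enzyme_conc: float,
    s0: float | None = None,
) -> EfficiencyFit:
    """Dispatch a delimited-text kinetic series to one of the estimators."""
    with _stage(f"fit-{method}"):
        if method == "depletion":
            if s0 is None:
                raise ValueError("depletion fitting requires S0")
            series = DepletionSeries.from_file(series_path, s0, enzyme_conc, cfg.units)
            return fit_depletion(series)
        series = KineticSeries.from_file(series_path, enzyme_conc, cfg.units)
        if method == "mm_nls":
            return fit_michaelis_menten(series)
        if method == "linear":
            return fit_linear_efficiency(series)
        raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# CLI


def _load_config(path: str | None) -> PipelineConfig:
    try:
        return PipelineConfig.from_file(path) if path else PipelineConfig()
    except Exception as e:
        raise click.exceptions.Exit(EXIT_INPUT_ERROR) from e


@click.group()
@click.option("-v", "--verbose", count=True, help="Increase logging verbosity.")
@click.version_option(__version__)
def cli(verbose: int) -> None:
    """Subsite mapping and kinetics for GH26 endomannanases."""
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(level=level, stream=sys.stderr, format="%(name)s %(levelname)s %(message)s")


@cli.command()
@click.argument("species")
@click.option("--adduct", type=click.Choice(["neutral", "sodium"]), default="sodium")
def mass(species: str, adduct: str) -> None:
    """Monoisotopic (adduct) mass of a species name."""
    try:
        g = parse_name(species)
    except ValueError as e:
        click.echo(f"error: {e}", err=True)
        raise click.exceptions.Exit(EXIT_INPUT_ERROR)
    click.echo(f"{monoisotopic_mass(formula(g), adduct):.3f}")


@cli.command()
@click.argument("species")
@click.option("--n-peaks", type=int, default=None)
def envelope(species: str, n_peaks: int | None) -> None:
    """Natural isotope envelope of a species' sodiated formula."""
    try:
        g = parse_name(species)
        f = formula(g)
        f["Na"] = 1
        env = isotope_envelope(f, n_peaks)
    except ValueError as e:
        click.echo(f"error: {e}", err=True)
        raise click.exceptions.Exit(EXIT_INPUT_ERROR)
    for i, a in enumerate(env.abundances):
        click.echo(f"M+{i}\t{a:.6g}")


@cli.command()
@click.argument("species")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--enforce-decoration/--no-enforce-decoration", default=False)
def modes(species: str, config_path: str | None, enforce_decoration: bool) -> None:
    """Enumerate productive binding modes and their products."""
    cfg = _load_config(config_path)
    try:
        g = parse_name(species)
        found = enumerate_modes(g, cfg.cleft(), enforce_decoration)
    except ValueError as e:
        click.echo(f"error: {e}", err=True)
        raise click.exceptions.Exit(EXIT_INPUT_ERROR)
    for m in found:
        heavy, light = products_of_mode(g, m)
        click.echo(f"{m.label}\theavy={format_name(heavy)}\tlight={format_name(light)}")


@cli.command("infer-modes")
@click.argument("spectrum", type=click.Path(exists=True))
@click.argument("product_table", type=click.Path(exists=True))
@click.option("--substrate", default="M5", show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--json-out", type=click.Path(), default=None, help="Write the full report as JSON.")
def infer_modes_cmd(
    spectrum: str, product_table: str, substrate: str, config_path: str | None, json_out: str | None
) -> None:
    """Infer productive binding-mode frequencies from a spectrum + table."""
    cfg = _load_config(config_path)
    try:
        report = run_subsite_pipeline(cfg, spectrum, product_table, substrate)
    except (FileNotFoundError, OSError) as e:
        click.echo(f"error: {e}", err=True)
        raise click.exceptions.Exit(EXIT_INPUT_ERROR)
    except Exception as e:
        click.echo(f"error: {e}", err=True)
        raise click.exceptions.Exit(EXIT_INFERENCE_ERROR)
    for name, info in report["label_pairs"].items():
        click.echo(f"{name}: ratio {info['ratio']}, heavy fraction {info['heavy_fraction']:.3f}")
    for label, pct in report["mode_percent"].items():
        click.echo(f"{label}\t{report['mode_frequencies'][label]:.4f}\t{pct}%")
    if json_out:
        Path(json_out).write_text(json.dumps(report, indent=2))


@cli.command()
@click.option("--substrate", default="M5", show_default=True)
@click.option("--frequencies", required=True, help='e.g. "-4..+1:0.8,-1..+4:0.09,-3..+2:0.07,-2..+3:0.04"')
@click.option("--n-events", type=int, default=10**5, show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out-table", type=click.Path(), required=True)
def simulate(substrate, frequencies, n_events, config_path, out_table) -> None:
    """Simulate a digest and write the product table."""
    from .subsites import BindingMode, simulate_digest

    cfg = _load_config(config_path)
    try:
        g = parse_name(substrate)
        fmap = {}
        for part in frequencies.split(","):
            label, value = part.rsplit(":", 1)
            fmap[BindingMode.from_label(label)] = float(value)
        freqs = ModeFrequencies(fmap)
    except ValueError as e:
        click.echo(f"error: {e}", err=True)
        raise click.exceptions.Exit(EXIT_INPUT_ERROR)
    table, _ = simulate_digest(g, freqs, n_events, cfg.labeling(), cfg.seed)
    table.to_file(out_table)
    click.echo(f"wrote {out_table}")


def _fit_command(name: str, method: str, needs_s0: bool):
    @cli.command(name)
    @click.argument("series", type=click.Path(exists=True))
    @click.option("--enzyme-conc", type=float, required=True, help="Enzyme concentration (molar units of the series).")
    @click.option("--s0", type=float, default=None, help="Initial substrate concentration.")
    @click.option("--config", "config_path", type=click.Path(exists=True), default=None)
    def _cmd(series: str, enzyme_conc: float, s0: float | None, config_path: str | None) -> None:
        cfg = _load_config(config_path)
        if needs_s0 and s0 is None:
            click.echo("error: --s0 is required for depletion fitting", err=True)
            raise click.exceptions.Exit(EXIT_INPUT_ERROR)
        try:
            fit = run_kinetics(cfg, series, method, enzyme_conc, s0)
        except (FileNotFoundError, OSError) as e:
            click.echo(f"error: {e}", err=True)
            raise click.exceptions.Exit(EXIT_INPUT_ERROR)
        except Exception as e:
            click.echo(f"error: {e}", err=True)
            raise click.exceptions.Exit(EXIT_INFERENCE_ERROR)
        click.echo(json.dumps(fit.to_dict(), indent=2))

    _cmd.__doc__ = f"Fit a kinetic series with the {method} estimator."
    return _cmd


_fit_command("fit-mm", "mm_nls", needs_s0=False)
_fit_command("fit-linear", "linear", needs_s0=False)
_fit_command("fit-depletion", "depletion", needs_s0=True)


@cli.command("calibrate-dash")
@click.argument("ladder", type=click.Path(exists=True))
@click.argument("peaks", type=click.Path(exists=True))
@click.option("--tolerance", type=float, default=0.05, show_default=True)
def calibrate_dash(ladder: str, peaks: str, tolerance: float) -> None:
    """Calibrate migration to DE from a ladder and annotate peak migrations."""
    import pandas as pd

    try:
        lad = DextranLadder.from_file(ladder)
        cal = calibrate_de(lad)
        df = pd.read_csv(peaks, sep=None, engine="python", comment="#", header=None)
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        migrations = df.iloc[:, 0].astype(float).tolist()
    except Exception as e:
        click.echo(f"error: {e}", err=True)
        raise click.exceptions.Exit(EXIT_INPUT_ERROR)
    for peak in annotate_peaks(migrations, cal, tolerance=tolerance):
        species = peak.species or "unassigned"
        click.echo(f"{peak.migration:g}\t{peak.de:.3f}\t{species}")


@cli.command("make-fixtures")
@click.argument("out_dir", type=click.Path())
@click.option("--seed", type=int, default=0, show_default=True)
def make_fixtures_cmd(out_dir: str, seed: int) -> None:
    """Write a worked-example directory of synthetic input files."""
    from .synthetic_data import make_fixtures

    paths = make_fixtures(out_dir, seed)
    for name, path in paths.items():
        click.echo(f"{name}: {path}")


if __name__ == "__main__":
    cli()
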