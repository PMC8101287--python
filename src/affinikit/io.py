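"""CSV readers/writers and configuration parsing.

Dialects (all UTF-8, header required):

* sensorgram long format — columns ``cycle_id, time_s, response_ru, conc_M,
  phase, ligand_density_ru`` (the last column may be missing or empty:
  density unknown);
* equilibrium points — ``conc_M, response_ru``;
* cross-titration plate — first row donor concentrations (nM), first column
  acceptor concentrations (nM), body counts; rows whose first cell is
  ``buffer`` hold background wells;
* inhibition series — ``role, conc_nM, signal`` with roles ``sample``,
  ``no_inhibitor``, ``background``;
* flow events — ``intensity, live`` (live optional, 0/1);
* pipeline config — INI-style ``key = value`` sections.

Concentrations are molar internally; the CLI boundary accepts unit
suffixes (``57uM``, ``1.32nM``) via :func:`parse_concentration`.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidParameterError
from .flow import EventTable
from .models import Sensorgram
from .plates import CrossTitrationPlate, InhibitionSeries
from .steady_state import EquilibriumPoint

__all__ = [
    "read_sensorgram_csv", "write_sensorgram_csv",
    "read_equilibrium_csv", "write_equilibrium_csv",
    "read_plate_csv", "write_plate_csv",
    "read_inhibition_csv", "write_inhibition_csv",
    "read_events_csv", "write_events_csv",
    "PipelineConfig", "read_config", "write_config",
    "parse_concentration", "write_fit_report", "write_residuals_csv",
]

_SENSORGRAM_COLUMNS = ["cycle_id", "time_s", "response_ru", "conc_M", "phase"]

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
                 "nM": 1e-9, "pM": 1e-12}


def parse_concentration(text: str) -> float:
    """Parse ``'7.1uM'``-style concentration strings to molar."""
    s = str(text).strip()
    for unit in sorted(_UNIT_FACTORS, key=len, reverse=True):
        if s.endswith(unit):
            return float(s[: -len(unit)]) * _UNIT_FACTORS[unit]
    return float(s)


# -- sensorgrams ------------------------------------------------------------

def write_sensorgram_csv(sensorgrams, path) -> None:
    """Write cycles to the long-format sensorgram dialect, full precision."""
    frames = []
    for sg in sensorgrams:
        frames.append(pd.DataFrame({
            "cycle_id": sg.cycle_id,
            "time_s": sg.times,
            "response_ru": sg.responses,
            "conc_M": sg.concentration,
            "phase": sg.phases,
            "ligand_density_ru": (np.nan if sg.ligand_density is None
                                  else sg.ligand_density),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g")


def read_sensorgram_csv(path) -> list[Sensorgram]:
    """Read the long-format dialect back into per-cycle sensorgrams.

    Cycles keep file order; a missing or empty ``ligand_density_ru`` column
    yields ``ligand_density=None``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SENSORGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"malformed header: missing columns {missing}")
    has_density = "ligand_density_ru" in df.columns
    out = []
    for cycle_id in df["cycle_id"].drop_duplicates():
        sub = df[df["cycle_id"] == cycle_id]
        conc = sub["conc_M"].unique()
        if conc.size != 1:
            raise DataError(
                f"cycle {cycle_id!r} has multiple conc_M values")
        density = None
        if has_density:
            d = sub["ligand_density_ru"].dropna().unique()
            if d.size > 1:
                raise DataError(
                    f"cycle {cycle_id!r} has multiple ligand densities")
            density = float(d[0]) if d.size else None
        times = sub["time_s"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise DataError(f"cycle {cycle_id!r}: time_s not strictly "
                            "increasing")
        try:
            sg = Sensorgram(times=times,
                            responses=sub["response_ru"].to_numpy(float),
                            phases=sub["phase"].to_numpy(object),
                            concentration=float(conc[0]),
                            ligand_density=density,
                            cycle_id=str(cycle_id))
        except InvalidParameterError as exc:
            raise DataError(f"cycle {cycle_id!r}: {exc}") from exc
        out.append(sg)
    return out


# -- equilibrium points -----------------------------------------------------

def write_equilibrium_csv(points, path) -> None:
    pd.DataFrame({
        "conc_M": [p.concentration for p in points],
        "response_ru": [p.response for p in points],
    }).to_csv(path, index=False, float_format="%.17g")


def read_equilibrium_csv(path) -> list[EquilibriumPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("conc_M", "response_ru"):
        if col not in df.columns:
            raise DataError(f"malformed header: missing column {col!r}")
    return [EquilibriumPoint(concentration=float(c), response=float(r))
            for c, r in zip(df["conc_M"], df["response_ru"])]


# -- plates -----------------------------------------------------------------

def write_plate_csv(plate: CrossTitrationPlate, path) -> None:
    """First row donor concs, first column acceptor concs, body counts;
    background wells appear as ``buffer`` rows."""
    lines = ["acceptor_nM," + ",".join(f"{c:g}" for c in plate.donor_concs)]
    for acc, row in zip(plate.acceptor_concs, plate.signal):
        lines.append(f"{acc:g}," + ",".join(f"{v:.17g}" for v in row))
    for bg in plate.background_wells:
        lines.append("buffer," + f"{bg:.17g}" +
                     "," * (plate.donor_concs.size - 1))
    Path(path).write_text("\n".join(lines) + "\n")


def read_plate_csv(path) -> CrossTitrationPlate:
    rows = [line.split(",") for line in
            Path(path).read_text().strip().splitlines()]
    if not rows or not rows[0][0].startswith("acceptor"):
        raise DataError("malformed plate header: expected 'acceptor_nM,...'")
    donor = np.array([float(v) for v in rows[0][1:] if v != ""])
    acceptor, signal, background = [], [], []
    for row in rows[1:]:
        if row[0].strip().lower() == "buffer":
            background.append(float(row[1]))
            continue
        acceptor.append(float(row[0]))
        vals = [float(v) for v in row[1:] if v != ""]
        if len(vals) != donor.size:
            raise DataError("plate row length does not match donor series")
        signal.append(vals)
    return CrossTitrationPlate(
        donor_concs=donor, acceptor_concs=np.array(acceptor),
        signal=np.array(signal), background_wells=np.array(background))


# -- inhibition series ------------------------------------------------------

def write_inhibition_csv(series: InhibitionSeries, path) -> None:
    rows = [("sample", c, s)
            for c, s in zip(series.inhibitor_concs, series.signal)]
    if series.no_inhibitor_signal is not None:
        rows.append(("no_inhibitor", 0.0, series.no_inhibitor_signal))
    if series.background_signal is not None:
        rows.append(("background", 0.0, series.background_signal))
    pd.DataFrame(rows, columns=["role", "conc_nM", "signal"]).to_csv(
        path, index=False, float_format="%.17g")


def read_inhibition_csv(path) -> InhibitionSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("role", "conc_nM", "signal"):
        if col not in df.columns:
            raise DataError(f"malformed header: missing column {col!r}")
    samples = df[df["role"] == "sample"]
    no_inh = df[df["role"] == "no_inhibitor"]["signal"]
    bg = df[df["role"] == "background"]["signal"]
    return InhibitionSeries(
        inhibitor_concs=samples["conc_nM"].to_numpy(float),
        signal=samples["signal"].to_numpy(float),
        no_inhibitor_signal=float(no_inh.iloc[0]) if len(no_inh) else None,
        background_signal=float(bg.iloc[0]) if len(bg) else None)


# -- flow events ------------------------------------------------------------

def write_events_csv(events: EventTable, path) -> None:
    pd.DataFrame({
        "intensity": events.intensities,
        "live": events.live_flags.astype(int),
    }).to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path, sample_label: str = "stain") -> EventTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if "intensity" not in df.columns:
        raise DataError("malformed header: missing column 'intensity'")
    live = (df["live"].to_numpy(bool) if "live" in df.columns else None)
    return EventTable(intensities=df["intensity"].to_numpy(float),
                      live_flags=live, sample_label=sample_label)


# -- pipeline configuration -------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat configuration for the end-to-end pipeline.

    ``analyte_mw`` (Da) is required whenever molar kinetic constants are
    requested; thresholds are all surfaced here rather than hard-coded.
    """

    analyte_mw: float | None = None
    model: str = "bivalent"
    scope: str = "global"
    readout_time: float = 30.0
    baseline_window: float = 10.0
    fold_threshold: float = 3.0
    trend_threshold: float = 0.8
    positivity_quantile: float = 0.999
    noise_sd_ru: float = 2.0
    seed: int = 0
    output_dir: str = "affinikit-out"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.analyte_mw is not None and self.analyte_mw <= 0:
            raise InvalidParameterError("analyte_mw must be > 0")
        if self.readout_time <= 0:
            raise InvalidParameterError("readout_time must be > 0")


_CONFIG_FIELDS = {
    "analyte_mw": float, "model": str, "scope": str, "readout_time": float,
    "baseline_window": float, "fold_threshold": float,
    "trend_threshold": float, "positivity_quantile": float,
    "noise_sd_ru": float, "seed": int, "output_dir": str,
}


def read_config(path) -> PipelineConfig:
    """Parse an INI-style ``key = value`` config file (any sections)."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise DataError(f"config file not found: {path}")
    kwargs, extras = {}, {}
    for section in cp.sections():
        for key, value in cp.items(section):
            if key in _CONFIG_FIELDS:
                kwargs[key] = _CONFIG_FIELDS[key](value)
            else:
                extras[key] = value
    return PipelineConfig(extras=extras, **kwargs)


def write_config(config: PipelineConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp["pipeline"] = {k: str(getattr(config, k)) for k in _CONFIG_FIELDS
                      if getattr(config, k) is not None}
    if config.extras:
        cp["extras"] = {k: str(v) for k, v in config.extras.items()}
    with open(path, "w") as fh:
        cp.write(fh)


# -- fit reports ------------------------------------------------------------

def write_fit_report(result, path) -> None:
    """Key-value text report of a kinetic fit."""
    lines = [f"model = {result.model}", f"scope = {result.scope}",
             f"converged = {result.converged}",
             f"chi_square = {result.chi_square_paper:.6g}",
             f"ssr = {result.ssr:.6g}"]
    p = result.params
    if result.model == "bivalent":
        lines += [f"k_on1_per_M_s = {p.k_on1:.6g}",
                  f"k_off1_per_s = {p.k_off1:.6g}",
                  f"k_on2_per_RU_s = {p.k_on2_ru:.6g}",
                  f"k_off2_per_s = {p.k_off2:.6g}"]
    else:
        lines += [f"k_on_per_M_s = {p.k_on:.6g}",
                  f"k_off_per_s = {p.k_off:.6g}"]
    lines.append(f"R_max_RU = {p.R_max:.6g}")
    lines.append("RI_RU = " + ", ".join(f"{r:.4g}" for r in
                                        result.ri_per_cycle))
    if result.derived is not None:
        lines.append(f"K_D1_M = {result.derived.K_D1:.6g}")
        if result.derived.K_D2 is not None:
            lines.append(f"K_D2_M = {result.derived.K_D2:.6g}")
            lines.append(f"k_on2_per_M_s = {result.derived.k_on2_molar:.6g}")
    lines.append("concentrations_M = " + ", ".join(
        f"{c:.6g}" for c in result.concentration_range))
    Path(path).write_text("\n".join(lines) + "\n")


def write_residuals_csv(result, sensorgrams, path) -> None:
    """Residual traces in sensorgram dialect (response column = residual)."""
    from .models import PHASE_ASSOCIATION, PHASE_DISSOCIATION
    frames = []
    for sg, resid in zip(sensorgrams, result.residuals):
        fitted = sg.mask(PHASE_ASSOCIATION) | sg.mask(PHASE_DISSOCIATION)
        frames.append(pd.DataFrame({
            "cycle_id": sg.cycle_id,
            "time_s": sg.times[fitted],
            "response_ru": resid,
            "conc_M": sg.concentration,
            "phase": sg.phases[fitted],
            "ligand_density_ru": (np.nan if sg.ligand_density is None
                                  else sg.ligand_density),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g")
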