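"""Readers, writers, configuration and report assembly.

All on-disk formats are plain CSV and JSON.  Readers validate the
schema and report offending rows with line numbers; writers are
deterministic for fixed inputs, so pipeline runs are reproducible
byte-for-byte at a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .itc import ITCProtocol, Isotherm
from .stoppedflow import Trace, ObservedRates
from .titration import TitrationCurve, ShiftPerturbation
from .cpmg import DispersionProfile, T_CP_DEFAULT, F_N_MHZ_DEFAULT, r2eff_from_intensity

__all__ = [
    "ParseError",
    "read_table",
    "read_isotherm",
    "read_protocol_config",
    "read_trace",
    "read_observed_rates",
    "read_titration",
    "read_perturbations",
    "read_dispersion",
    "ResultBundle",
    "write_report",
    "RunConfig",
    "run_pipeline",
]


class ParseError(ValueError):
    """A structured input-file validation error."""


_SCHEMAS = {
    "isotherm": ("injection", "volume_uL", "heat_kcal_per_mol"),
    "trace": ("time_s", "fluorescence"),
    "observed_rates": ("ligand_uM", "kapp1_s", "kapp2_s"),
    "titration": ("residue", "pH", "delta_N_ppm"),
    "perturbations": ("residue", "dHN_ppm", "dN_ppm"),
    "dispersion": ("residue", "nu_cpmg_hz", "r2eff_s", "rep"),
    "dispersion_intensity": ("residue", "nu_cpmg_hz", "intensity", "rep"),
}

_NON_NUMERIC = {"residue"}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the named schemas.

    Raises :class:`ParseError` naming the missing column or the first
    offending row (1-based data row numbers) on non-numeric cells.
    """
    if schema_name not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: file contains no data rows")
    required = _SCHEMAS[schema_name]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r} "
                             f"(schema {schema_name!r} needs {required})")
    for col in df.columns:
        if col in _NON_NUMERIC:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 1
            raise ParseError(f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} "
                             f"in column {col!r} at data row {row}")
        df[col] = coerced
    return df


def read_isotherm(path) -> Isotherm:
    df = read_table(path, "isotherm")
    vols = df["volume_uL"].to_numpy() * 1e-6
    err = df["heat_err"].to_numpy() if "heat_err" in df.columns else None
    return Isotherm(heats=df["heat_kcal_per_mol"].to_numpy(),
                    cumulative_volumes=np.cumsum(vols), errors=err)


def read_protocol_config(path) -> ITCProtocol:
    """Protocol from a JSON config: cell_volume_mL, cell_mM, syringe_mM,
    temperature_C and the list injection_volumes_uL."""
    with open(path) as fh:
        cfg = json.load(fh)
    try:
        return ITCProtocol(
            cell_volume=float(cfg["cell_volume_mL"]) * 1e-3,
            cell_protein_conc=float(cfg["cell_mM"]) * 1e-3,
            syringe_ligand_conc=float(cfg["syringe_mM"]) * 1e-3,
            injection_volumes=tuple(float(v) * 1e-6 for v in cfg["injection_volumes_uL"]),
            temperature=float(cfg.get("temperature_C", 25.0)) + 273.15,
        )
    except KeyError as e:
        raise ParseError(f"{path}: missing protocol key {e.args[0]!r}") from None


def read_trace(path, ligand: float, protein: float) -> Trace:
    df = read_table(path, "trace")
    return Trace(times=df["time_s"].to_numpy(), fluorescence=df["fluorescence"].to_numpy(),
                 ligand=ligand, protein=protein)


def read_observed_rates(path) -> ObservedRates:
    df = read_table(path, "observed_rates")
    kw = {}
    if "kapp1_err" in df.columns:
        kw["kapp1_err"] = df["kapp1_err"].to_numpy()
    if "kapp2_err" in df.columns:
        kw["kapp2_err"] = df["kapp2_err"].to_numpy()
    return ObservedRates(ligand=df["ligand_uM"].to_numpy(),
                         kapp1=df["kapp1_s"].to_numpy(), kapp2=df["kapp2_s"].to_numpy(), **kw)


def read_titration(path) -> list:
    """One TitrationCurve per residue from the long-format table."""
    df = read_table(path, "titration")
    curves = []
    for res, grp in df.groupby("residue", sort=True):
        err = grp["err"].to_numpy() if "err" in grp.columns else None
        curves.append(TitrationCurve(residue=str(res), ph=grp["pH"].to_numpy(),
                                     shifts=grp["delta_N_ppm"].to_numpy(), errors=err))
    return curves


def read_perturbations(path) -> list:
    df = read_table(path, "perturbations")
    return [ShiftPerturbation(residue=str(r.residue), d_hn=float(r.dHN_ppm), d_n=float(r.dN_ppm))
            for r in df.itertuples()]


def read_dispersion(path, t_cp: float = T_CP_DEFAULT, f_n_mhz: float = F_N_MHZ_DEFAULT) -> list:
    """Dispersion profiles from long-format CSV, R2eff or intensity form.

    The intensity form carries reference rows with ``nu_cpmg_hz = 0``
    (CPMG period omitted); intensities are converted per replicate with
    the constant-time relation before duplicate averaging.
    """
    df = pd.read_csv(path)
    if "r2eff_s" in df.columns:
        df = read_table(path, "dispersion")
    elif "intensity" in df.columns:
        raw = read_table(path, "dispersion_intensity")
        rows = []
        for (res, rep), grp in raw.groupby(["residue", "rep"]):
            refs = grp[grp["nu_cpmg_hz"] == 0]
            if refs.empty:
                raise ParseError(f"{path}: residue {res!r} rep {rep} lacks a "
                                 "reference row (nu_cpmg_hz=0)")
            i0 = float(refs["intensity"].mean())
            for r in grp[grp["nu_cpmg_hz"] > 0].itertuples():
                rows.append({"residue": res, "nu_cpmg_hz": r.nu_cpmg_hz,
                             "r2eff_s": r2eff_from_intensity(float(r.intensity), i0, t_cp),
                             "rep": rep})
        df = pd.DataFrame(rows)
    else:
        raise ParseError(f"{path}: need either an 'r2eff_s' or an 'intensity' column")
    profiles = []
    for res, grp in df.groupby("residue", sort=True):
        piv = grp.pivot_table(index="nu_cpmg_hz", columns="rep", values="r2eff_s")
        if piv.isna().any().any():
            raise ParseError(f"{path}: residue {res!r} has unbalanced replicates")
        profiles.append(DispersionProfile.from_replicates(
            str(res), piv.index.to_numpy(), piv.to_numpy(), t_cp=t_cp, f_n_mhz=f_n_mhz))
    return profiles


# ---------------------------------------------------------------------------
# result bundles and reports

from . import __version__ as _pkg_version  # noqa: E402


@dataclass
class ResultBundle:
    """Fitted parameters, derived quantities and tables of one pipeline run."""

    kind: str
    parameters: dict
    derived: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    seed: int | None = None
    config_hash: str | None = None
    version: str = _pkg_version

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash, "version": self.version}


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(o).items()}
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in o]
    return o


def write_report(bundle: ResultBundle, out_dir) -> list:
    """Write the JSON summary and every table; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    summary = {
        "kind": bundle.kind,
        "parameters": _jsonable(bundle.parameters),
        "derived": _jsonable(bundle.derived),
        "provenance": bundle.provenance(),
    }
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(p)
    for name, df in bundle.tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# pipeline dispatch


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    kind: str  # itc_ls | itc_bayes | sf_mech | pka | shifts | cpmg_individual | cpmg_global
    data: str
    out_dir: str
    seed: int = 0
    options: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Dispatch a run to the matching model and write its report."""
    from . import pipelines

    fn = {
        "itc_ls": pipelines.run_itc,
        "itc_bayes": pipelines.run_itc,
        "sf_mech": pipelines.run_mechanism,
        "pka": pipelines.run_pka,
        "shifts": pipelines.run_shifts,
        "cpmg_individual": pipelines.run_cpmg,
        "cpmg_global": pipelines.run_cpmg,
    }.get(config.kind)
    if fn is None:
        raise ValueError(f"unknown pipeline kind {config.kind!r}")
    bundle = fn(config)
    write_report(bundle, config.out_dir)
    return bundle
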