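"""Configuration, calibration and file I/O.

Parameter configs are flat JSON objects keyed by the field names of
:class:`~txtlkit.params.TXTLParameters`; unknown keys are rejected. CSVs are
plain RFC-4180 with a mandatory header; every file written here gets a
``<name>.meta.json`` sidecar embedding the package version and the exact
parameter set used.
"""

from __future__ import annotations

import json
from importlib import metadata, resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .estimation import DecayTrace, RateCurveData
from .params import KineticsTrace, TXTLParameters

__all__ = [
    "best_fit_parameters",
    "load_params",
    "save_params",
    "mgml_to_micromolar",
    "trace_to_frame",
    "write_trace_csv",
    "read_trace_csv",
    "write_rate_curve_csv",
    "read_rate_curve_csv",
    "write_decay_csv",
    "read_decay_csv",
    "package_version",
]

TRACE_COLUMNS = ["time_s", "mrna_nM", "degfp_dark_nM", "degfp_mat_nM", "E0_nM", "R0_nM"]
RATE_COLUMNS = ["plasmid_nM", "max_rate_nM_per_s", "promoter", "utr"]


def package_version() -> str:
    try:
        return metadata.version("txtlkit")
    except metadata.PackageNotFoundError:  # running from a source tree
        return "0+unknown"


def best_fit_parameters(**overrides: float) -> TXTLParameters:
    """The bundled best-fit parameter set (plasmid defaults to 0 nM).

    ``k_mat`` in the bundle is a documented placeholder, not a published
    value; override it when a measured maturation rate is available.
    """
    raw = json.loads(resources.files("txtlkit.data").joinpath("bestfit.json").read_text())
    raw.update(overrides)
    return TXTLParameters(**raw)


def load_params(path: Path | str) -> TXTLParameters:
    """Read a flat JSON parameter config; unknown keys raise a validation error."""
    return TXTLParameters(**json.loads(Path(path).read_text()))


def save_params(params: TXTLParameters, path: Path | str) -> None:
    Path(path).write_text(json.dumps(params.model_dump(), indent=2) + "\n")


def _write_sidecar(path: Path, params: Optional[TXTLParameters]) -> None:
    meta = {"txtlkit_version": package_version()}
    if params is not None:
        meta["parameters"] = params.model_dump()
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def mgml_to_micromolar(conc_mg_per_ml: float, molar_mass_kda: float) -> float:
    """Convert a protein mass concentration (mg/mL) to µM given its mass in kDa.

    1 mg/mL of a 25.4 kDa reporter is 39.37 µM — the conversion used to
    calibrate plate-reader fluorescence against a pure protein standard.
    """
    if molar_mass_kda <= 0:
        raise ValueError("molar mass must be positive")
    if conc_mg_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_mg_per_ml * 1000.0 / molar_mass_kda


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def trace_to_frame(trace: KineticsTrace) -> pd.DataFrame:
    n = trace.times.size
    return pd.DataFrame(
        {
            "time_s": trace.times,
            "mrna_nM": trace.m,
            "degfp_dark_nM": trace.deGFP_dark,
            "degfp_mat_nM": trace.deGFP_mat,
            "E0_nM": np.full(n, np.nan if trace.E0 is None else trace.E0),
            "R0_nM": np.full(n, np.nan) if trace.R0 is None else trace.R0,
        }
    )


def write_trace_csv(trace: KineticsTrace, path: Path | str) -> None:
    path = Path(path)
    trace_to_frame(trace).to_csv(path, index=False)
    _write_sidecar(path, trace.params)


def read_trace_csv(path: Path | str) -> KineticsTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns: {missing}")
    e0 = df["E0_nM"].iloc[0] if len(df) else np.nan
    return KineticsTrace(
        times=df["time_s"].to_numpy(),
        m=df["mrna_nM"].to_numpy(),
        deGFP_dark=df["degfp_dark_nM"].to_numpy(),
        deGFP_mat=df["degfp_mat_nM"].to_numpy(),
        E0=None if np.isnan(e0) else float(e0),
        R0=df["R0_nM"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# rate-curve CSV
# ---------------------------------------------------------------------------

def write_rate_curve_csv(
    data: RateCurveData, path: Path | str, params: Optional[TXTLParameters] = None
) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "plasmid_nM": data.plasmid_concs,
            "max_rate_nM_per_s": data.measured_max_rates,
            "promoter": data.promoter_label,
            "utr": data.utr_label,
        }
    ).to_csv(path, index=False)
    _write_sidecar(path, params)


def read_rate_curve_csv(path: Path | str) -> RateCurveData:
    df = pd.read_csv(path)
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate-curve CSV missing columns: {missing}")
    return RateCurveData(
        plasmid_concs=df["plasmid_nM"].to_numpy(),
        measured_max_rates=df["max_rate_nM_per_s"].to_numpy(),
        promoter_label=str(df["promoter"].iloc[0]) if len(df) else "",
        utr_label=str(df["utr"].iloc[0]) if len(df) else "",
    )


# ---------------------------------------------------------------------------
# decay CSV
# ---------------------------------------------------------------------------

def write_decay_csv(
    trace: DecayTrace, path: Path | str, params: Optional[TXTLParameters] = None
) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "signal_nM": trace.signal}).to_csv(path, index=False)
    _write_sidecar(path, params)


def read_decay_csv(path: Path | str) -> DecayTrace:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "signal_nM" not in df.columns:
        raise ValueError("decay CSV must have columns time_s,signal_nM")
    return DecayTrace(times=df["time_s"].to_numpy(), signal=df["signal_nM"].to_numpy())
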