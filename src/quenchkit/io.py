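"""CSV readers/writers and JSON reporting for the analysis pipeline.

CSV dialects (comma-separated, decimal point, header required):

* ensemble titration — ``quencher_conc_uM, probe_conc_uM, absorbance,
  fluorescence``, one row per (quencher, probe) measurement;
* absorbance titration — ``metal_conc_uM, absorbance``; the probe
  concentration, path length, wavelength and A0 travel in a config;
* photon trace — ``time_s, counts``, one file per molecule, listed in a
  manifest CSV with columns ``file, molecule_id, quencher_conc_uM``;
* spectrum — ``wavelength_nm, value``.

Concentrations are µM on disk (the instrument-facing unit) and mol/L
in memory.  JSON reports round floats to 12 significant digits so that
identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .benesi import AbsorbanceTitration
from .ensemble import FluorAbsSeries
from .forster import Spectrum
from .traces import PhotonTrace

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_absorbance_csv",
    "write_absorbance_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_trace_manifest",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_json_report",
    "parse_config",
]

UM = 1e-6  # µM -> mol/L


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad = df[list(cols)].isna().any(axis=1)
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed/missing values on line(s) {', '.join(lines)}")


def read_titration_csv(path) -> list[FluorAbsSeries]:
    """Read an ensemble titration CSV into per-concentration series."""
    df = pd.read_csv(path)
    _require_columns(df, ("quencher_conc_uM", "probe_conc_uM", "absorbance", "fluorescence"), path)
    series = []
    for conc_uM, grp in df.groupby("quencher_conc_uM", sort=True):
        series.append(
            FluorAbsSeries(
                quencher_conc=float(conc_uM) * UM,
                absorbance=grp["absorbance"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                meta={"probe_conc": grp["probe_conc_uM"].to_numpy() * UM},
            )
        )
    return series


def write_titration_csv(series_list: list[FluorAbsSeries], path) -> None:
    rows = []
    for s in series_list:
        probe = np.asarray(s.meta.get("probe_conc", np.full(s.absorbance.size, np.nan)))
        for p, a, f in zip(probe, s.absorbance, s.fluorescence):
            rows.append({
                "quencher_conc_uM": s.quencher_conc / UM,
                "probe_conc_uM": p / UM if np.isfinite(p) else np.nan,
                "absorbance": a,
                "fluorescence": f,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_absorbance_csv(path, L0: float, d: float, A0: float,
                        lambda_eval: float = 551.0) -> AbsorbanceTitration:
    """Read a metal/absorbance titration CSV (L0, d in SI: mol/L, cm)."""
    df = pd.read_csv(path)
    _require_columns(df, ("metal_conc_uM", "absorbance"), path)
    return AbsorbanceTitration(
        L0=L0, d=d, lambda_eval=lambda_eval,
        metal_conc=df["metal_conc_uM"].to_numpy() * UM,
        absorbance=df["absorbance"].to_numpy(), A0=A0,
    )


def write_absorbance_csv(t: AbsorbanceTitration, path) -> None:
    pd.DataFrame({
        "metal_conc_uM": t.metal_conc / UM,
        "absorbance": t.absorbance,
    }).to_csv(path, index=False)


def read_trace_csv(path, molecule_id: str | None = None,
                   quencher_conc: float | None = None) -> PhotonTrace:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "counts"), path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: a trace needs at least 2 bins")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time_s must be evenly spaced")
    return PhotonTrace(bin_width=float(dt[0]), counts=df["counts"].to_numpy(),
                       molecule_id=molecule_id, quencher_conc=quencher_conc)


def write_trace_csv(trace: PhotonTrace, path) -> None:
    t = np.arange(trace.counts.size) * trace.bin_width
    pd.DataFrame({"time_s": t, "counts": trace.counts}).to_csv(path, index=False)


def read_trace_manifest(path) -> list[PhotonTrace]:
    """Read a manifest CSV and load every listed trace file.

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("file", "molecule_id"), path)
    traces = []
    for _, row in df.iterrows():
        f = Path(row["file"])
        if not f.is_absolute():
            f = path.parent / f
        qc = float(row["quencher_conc_uM"]) * UM if "quencher_conc_uM" in df.columns else None
        traces.append(read_trace_csv(f, molecule_id=str(row["molecule_id"]), quencher_conc=qc))
    return traces


def read_spectrum_csv(path, kind: str) -> Spectrum:
    df = pd.read_csv(path)
    _require_columns(df, ("wavelength_nm", "value"), path)
    return Spectrum(wavelength=df["wavelength_nm"].to_numpy(),
                    value=df["value"].to_numpy(), kind=kind)


def write_spectrum_csv(spec: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelength, "value": spec.value}).to_csv(path, index=False)


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return float(f"{x:.{sig}g}") if np.isfinite(x) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def write_json_report(payload: dict, path) -> None:
    """Write a JSON report with floats at 12 significant digits.

    Rounding plus sorted keys makes reports byte-identical across runs
    of the same config and seed.
    """
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def parse_config(path) -> dict[str, str]:
    """Parse a plain ``key = value`` config file (# comments, blank lines ok)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
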