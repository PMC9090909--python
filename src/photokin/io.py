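"""Plain-text readers and writers: spectrum CSV, kinetic-trace CSV,
calibration JSON, geometry/config YAML.

All files are UTF-8 CSV/JSON with '.' decimal separator; write∘read is
the identity to full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .actinometry import ActinometerCalibration
from .errors import ParseError
from .simulate import KineticTrace
from .spectra import ReactorGeometry, Spectrum, UNIT_DIMENSIONLESS

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_trace",
    "write_trace",
    "read_calibration",
    "write_calibration",
    "read_geometry",
]

SPECTRUM_COLUMNS = ["wavelength_nm", "value"]
TRACE_COLUMNS = ["time_s", "conc_A_M"]


def _read_csv(path, expected: list[str], optional: list[str] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(df.columns)
    if cols[: len(expected)] != expected:
        raise ParseError(
            f"{path}: line 1: expected header {','.join(expected)}"
            f"{',' + ','.join(optional) if optional else ''}; got {','.join(cols)}"
        )
    for col in df.columns:
        for i, raw in enumerate(df[col]):
            if isinstance(raw, str) and "," in raw:
                raise ParseError(
                    f"{path}: line {i + 2}: comma decimal separator in "
                    f"{raw!r}; use '.'"
                )
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ParseError(f"{path}: column {col!r} is not numeric ({exc})") from exc
    return df


def read_spectrum(path, unit: str = UNIT_DIMENSIONLESS) -> Spectrum:
    """Read a two-column `wavelength_nm,value` CSV (header mandatory)."""
    df = _read_csv(path, SPECTRUM_COLUMNS)
    wl = df["wavelength_nm"].to_numpy()
    if np.any(np.diff(wl) <= 0):
        raise ParseError(f"{path}: wavelengths must be strictly increasing")
    return Spectrum(wl, df["value"].to_numpy(), unit)


def write_spectrum(spectrum: Spectrum, path, sidecar_unit: bool = True) -> None:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength, "value": spectrum.value}
    ).to_csv(path, index=False, float_format="%.17g")
    if sidecar_unit:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"unit": spectrum.unit}) + "\n"
        )


def read_trace(path) -> KineticTrace:
    """Read a `time_s,conc_A_M[,conc_B_M]` CSV."""
    df = _read_csv(path, TRACE_COLUMNS, optional=["conc_B_M"])
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ParseError(f"{path}: times must be non-decreasing")
    cb = df["conc_B_M"].to_numpy() if "conc_B_M" in df.columns else None
    return KineticTrace(t, df["conc_A_M"].to_numpy(), cb, provenance="measured")


def write_trace(trace: KineticTrace, path, sidecar: bool = True) -> None:
    path = Path(path)
    data = {"time_s": trace.t, "conc_A_M": trace.C_A}
    if trace.C_B is not None:
        data["conc_B_M"] = trace.C_B
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = {
            "provenance": trace.provenance,
            "noise_rsd": trace.noise_rsd,
            "seed": trace.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta) + "\n")


def write_calibration(cal: ActinometerCalibration, path) -> None:
    doc = {
        "drug_id": cal.drug_id,
        "lamp_id": cal.lamp_id,
        "beta_eta": cal.beta_eta,
        "intercept": cal.intercept,
        "r2": cal.r2,
        "n": cal.n,
        "points": [{"p0_tot": p, "k_eta": k} for p, k in cal.points],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_calibration(path) -> ActinometerCalibration:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        return ActinometerCalibration(
            drug_id=doc["drug_id"],
            lamp_id=doc["lamp_id"],
            beta_eta=float(doc["beta_eta"]),
            intercept=float(doc.get("intercept", 0.0)),
            r2=float(doc.get("r2", 1.0)),
            points=tuple((float(p["p0_tot"]), float(p["k_eta"])) for p in doc.get("points", [])),
            n=int(doc.get("n", len(doc.get("points", [])))),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing calibration key {exc}") from exc


def read_geometry(path) -> ReactorGeometry:
    """Geometry from a YAML/key-value config with keys l_irr_cm,
    area_cm2, volume_dm3 (all optional, defaults apply)."""
    try:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: geometry config must be a mapping")
    known = {"l_irr_cm", "area_cm2", "volume_dm3"}
    unknown = set(doc) - known
    if unknown:
        raise ParseError(f"{path}: unknown geometry keys {sorted(unknown)}")
    return ReactorGeometry(**{k: float(v) for k, v in doc.items()})
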