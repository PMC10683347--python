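"""Readers and writers for the package's plain-text file formats.

Spectra files are CSV with a first column ``wavenumber_cm-1`` and one
column per sample (header row = sample ids). All numeric output is written
at 17 significant digits so that a read/write round trip is bit-identical.
Side-car concentrations use a two-column CSV (sample_id, mg_per_mL).
"""
from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatography import DBCResult, FractionTable
from .spectra import SpectraBlock, SpectrumError

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_concentrations",
    "write_concentrations",
    "read_fractions",
    "write_fractions",
    "read_uv_trace",
    "write_uv_trace",
    "write_dbc_report",
    "write_manifest",
]

WAVENUMBER_COLUMN = "wavenumber_cm-1"
FLOAT_FORMAT = "%.17g"


def _read_csv_strict(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise SpectrumError(
            f"{path}: missing value at row {r + 2}, column '{df.columns[c]}'"
        )
    return df


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    # numpy's str->float conversion is round-trip exact, unlike the csv
    # parser's fast path
    out = {}
    for col in df.columns:
        vals = df[col].to_numpy()
        try:
            out[col] = vals.astype(float)
        except ValueError:
            for i, v in enumerate(vals):
                try:
                    float(v)
                except ValueError:
                    raise SpectrumError(
                        f"{path}: non-numeric cell '{v}' at row {i + 2}, "
                        f"column '{col}'"
                    ) from None
            raise
    return pd.DataFrame(out)


def read_spectra(path, concentrations_path=None) -> SpectraBlock:
    """Read a spectra CSV (and an optional concentrations side-car)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if header[0] != WAVENUMBER_COLUMN:
        raise SpectrumError(
            f"{path}: first column must be '{WAVENUMBER_COLUMN}', got '{header[0]}'"
        )
    ids = header[1:]
    dup = sorted({s for s in ids if ids.count(s) > 1})
    if dup:
        raise SpectrumError(f"{path}: duplicate sample ids {dup}")
    raw = _read_csv_strict(path)
    raw.columns = header  # undo pandas' mangling of duplicate headers
    num = _to_numeric(raw, path)
    w = num[WAVENUMBER_COLUMN].to_numpy()
    matrix = num[ids].to_numpy().T
    conc = None
    if concentrations_path is not None:
        table = read_concentrations(concentrations_path)
        try:
            conc = np.array([table[s] for s in ids])
        except KeyError as exc:
            raise SpectrumError(
                f"{concentrations_path}: no concentration for sample {exc}"
            ) from exc
    return SpectraBlock(w, matrix, tuple(ids), conc)


def write_spectra(block: SpectraBlock, path) -> None:
    df = pd.DataFrame(
        block.intensities.T, columns=list(block.sample_ids), index=block.wavenumbers
    )
    df.index.name = WAVENUMBER_COLUMN
    df.to_csv(path, float_format=FLOAT_FORMAT)


def read_concentrations(path) -> dict:
    df = _read_csv_strict(path)
    if list(df.columns) != ["sample_id", "mg_per_mL"]:
        raise SpectrumError(
            f"{path}: expected columns sample_id, mg_per_mL, got {list(df.columns)}"
        )
    vals = _to_numeric(df[["mg_per_mL"]], path)["mg_per_mL"]
    ids = df["sample_id"].tolist()
    dup = sorted({s for s in ids if ids.count(s) > 1})
    if dup:
        raise SpectrumError(f"{path}: duplicate sample ids {dup}")
    return dict(zip(ids, vals))


def write_concentrations(block: SpectraBlock, path) -> None:
    if block.concentrations is None:
        raise SpectrumError("block carries no concentrations")
    df = pd.DataFrame(
        {"sample_id": list(block.sample_ids), "mg_per_mL": block.concentrations}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fractions(path, c0: float) -> FractionTable:
    df = _read_csv_strict(path)
    expected = ["fraction_id", "v_start_mL", "v_end_mL", "titer_mg_per_mL"]
    if list(df.columns) != expected:
        raise SpectrumError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    num = _to_numeric(df[expected[1:]], path)
    return FractionTable(
        num["v_start_mL"].to_numpy(),
        num["v_end_mL"].to_numpy(),
        num["titer_mg_per_mL"].to_numpy(),
        c0,
    )


def write_fractions(fractions: FractionTable, path) -> None:
    df = pd.DataFrame(
        {
            "fraction_id": [f"F{i + 1:02d}" for i in range(fractions.titer.size)],
            "v_start_mL": fractions.v_start,
            "v_end_mL": fractions.v_end,
            "titer_mg_per_mL": fractions.titer,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_uv_trace(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv_strict(path)
    expected = ["volume_mL", "A280_AU"]
    if list(df.columns) != expected:
        raise SpectrumError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    num = _to_numeric(df, path)
    return num["volume_mL"].to_numpy(), num["A280_AU"].to_numpy()


def write_uv_trace(volumes, a280, path) -> None:
    pd.DataFrame({"volume_mL": volumes, "A280_AU": a280}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_dbc_report(result: DBCResult, path) -> None:
    payload = {
        "method": result.method,
        "V10_mL": result.v10_mL,
        "DBC_mg_per_mL": result.dbc_mg_per_mL,
        "inputs": result.inputs,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, stage: str, config: dict, inputs: dict, log=None) -> None:
    """Record input hashes, the config snapshot and per-stage logs."""
    from . import __version__

    payload = {
        "stage": stage,
        "software": {"name": "raman-dbc", "version": __version__, "python": platform.python_version()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
        "log": log or [],
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
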