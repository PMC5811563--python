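"""Delimited-text and JSON I/O with explicit units in every column name."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .waveforms import BMatrix, GradientWaveform

__all__ = [
    "write_waveform",
    "read_waveform",
    "bmatrix_record",
    "write_bmatrices",
    "write_signal_table",
    "read_signal_table",
    "write_manifest",
]


def write_waveform(path: str | Path, w: GradientWaveform, params: dict | None = None) -> None:
    """Waveform as TSV (time_s, gx_T_per_m, gy_T_per_m, gz_T_per_m) with a
    JSON parameter sidecar ``<path>.json``."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": w.times,
            "gx_T_per_m": w.g[:, 0],
            "gy_T_per_m": w.g[:, 1],
            "gz_T_per_m": w.g[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "dt_s": w.dt,
        "omega_m_rad_s": w.omega_m,
        "echo_time_index": w.echo_time_index,
    }
    if params:
        sidecar["params"] = params
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_waveform(path: str | Path) -> GradientWaveform:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(Path(str(path) + ".json").read_text())
    g = df[["gx_T_per_m", "gy_T_per_m", "gz_T_per_m"]].to_numpy(float)
    return GradientWaveform(
        times=df["time_s"].to_numpy(float),
        g=g,
        dt=float(meta["dt_s"]),
        echo_time_index=int(meta["echo_time_index"]),
        omega_m=float(meta["omega_m_rad_s"]),
    )


def bmatrix_record(bm: BMatrix, chi_deg: float | None = None) -> dict:
    return {
        "omega_hz": bm.omega_m / (2 * np.pi),
        "chi_deg": chi_deg,
        "b_ms_per_um2": bm.b_ms_um2,
        "B_s_per_m2": bm.B.tolist(),
    }


def write_bmatrices(path: str | Path, records: list[dict]) -> None:
    Path(path).write_text(json.dumps(records, indent=1))


def write_signal_table(path: str | Path, table: pd.DataFrame) -> None:
    """Signal table as TSV; simulation metadata (seed, dt, walkers) goes to a
    ``<path>.json`` manifest so every run is replayable."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if table.attrs:
        write_manifest(str(path) + ".json", dict(table.attrs))


def read_signal_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    manifest = Path(str(path) + ".json")
    if manifest.exists():
        df.attrs.update(json.loads(manifest.read_text()))
    return df


def write_manifest(path: str | Path, payload: dict) -> None:
    from . import __version__

    payload = dict(payload)
    payload.setdefault("package_version", __version__)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
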