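"""Delimited-table input/output for activity, curve, scan and photon data.

One CSV dialect everywhere: comma-separated, UTF-8, '.' decimal, with
'#'-prefixed metadata lines (seed, provenance) before the header.  Units
follow the package convention — concentrations in µM, times in seconds,
rates in s⁻¹.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .fits import ActivityDataset
from .photons import PhotonTrajectory

__all__ = [
    "read_activity_csv",
    "write_activity_csv",
    "write_curve_csv",
    "read_photon_csv",
    "write_photon_csv",
    "read_burst_csv",
    "write_burst_csv",
    "file_sha256",
]

ACTIVITY_COLUMNS = ["variant", "fixed_cosubstrate_uM", "conc_uM", "velocity", "replicate"]


class InputError(ValueError):
    """Malformed input table."""


def _write_with_metadata(path, frame: pd.DataFrame, metadata: dict | None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: file contains no table") from exc


def write_activity_csv(path, data: ActivityDataset, metadata: dict | None = None) -> None:
    frame = pd.DataFrame(
        {
            "variant": data.variant,
            "fixed_cosubstrate_uM": data.fixed_cosubstrate_conc,
            "conc_uM": data.conc,
            "velocity": data.velocity,
            "replicate": data.replicate if data.replicate is not None else 0,
        }
    )
    _write_with_metadata(path, frame, metadata)


def read_activity_csv(path) -> ActivityDataset:
    """Load and validate an initial-velocity table.

    Rows with non-numeric or negative concentrations are rejected with their
    line numbers; a header-only file is an error.
    """
    frame = _read_table(path)
    missing = [c for c in ("conc_uM", "velocity") if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    if len(frame) == 0:
        raise InputError(f"{path}: table has a header but no data rows")

    conc = pd.to_numeric(frame["conc_uM"], errors="coerce")
    vel = pd.to_numeric(frame["velocity"], errors="coerce")
    bad = conc.isna() | vel.isna() | (conc < 0)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering (metadata
        # lines shift this further, but the row index is what pandas kept)
        rows = [int(i) + 2 for i in frame.index[bad]]
        raise InputError(
            f"{path}: malformed or negative rows at data lines {rows} "
            "(need numeric conc_uM >= 0 and numeric velocity)"
        )

    variant = str(frame["variant"].iloc[0]) if "variant" in frame.columns else ""
    fixed = (
        float(frame["fixed_cosubstrate_uM"].iloc[0])
        if "fixed_cosubstrate_uM" in frame.columns
        else float("nan")
    )
    replicate = frame["replicate"].to_numpy() if "replicate" in frame.columns else None
    return ActivityDataset(
        conc=conc.to_numpy(float),
        velocity=vel.to_numpy(float),
        fixed_cosubstrate_conc=fixed,
        variant=variant,
        replicate=replicate,
    )


def write_curve_csv(path, curve, metadata: dict | None = None) -> None:
    """Write an ActivityCurve as a tidy table."""
    _write_with_metadata(path, curve.to_frame(), metadata)


def write_photon_csv(path, traj: PhotonTrajectory, metadata: dict | None = None) -> None:
    frame = pd.DataFrame(
        {
            "time_s": traj.times,
            "channel": np.where(traj.channels == 1, "A", "D"),
        }
    )
    _write_with_metadata(path, frame, metadata)


def read_photon_csv(path, bursts_path=None) -> PhotonTrajectory:
    frame = _read_table(path)
    missing = [c for c in ("time_s", "channel") if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    channel = frame["channel"].astype(str).str.strip().str.upper()
    unknown = ~channel.isin(["D", "A"])
    if unknown.any():
        rows = [int(i) + 2 for i in frame.index[unknown]]
        raise InputError(f"{path}: unknown channel labels at data lines {rows}")
    bursts = read_burst_csv(bursts_path) if bursts_path is not None else None
    return PhotonTrajectory(
        times=pd.to_numeric(frame["time_s"]).to_numpy(float),
        channels=(channel == "A").to_numpy().astype(np.int8),
        bursts=bursts,
    )


def write_burst_csv(path, bursts, metadata: dict | None = None) -> None:
    frame = pd.DataFrame(bursts, columns=["start_index", "end_index"])
    _write_with_metadata(path, frame, metadata)


def read_burst_csv(path) -> tuple[tuple[int, int], ...]:
    frame = _read_table(path)
    missing = [c for c in ("start_index", "end_index") if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return tuple(
        (int(a), int(b)) for a, b in zip(frame["start_index"], frame["end_index"])
    )


def file_sha256(path) -> str:
    """Hex digest used to pin parameter files in run logs."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
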