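"""Plain-text readers and writers for sessions, rate maps and correlograms.

Formats
-------
Trajectory: CSV with header ``t_seconds,x_cm,y_cm``.
Spikes: one spike time (seconds) per line.
Rate map / correlogram: delimited matrix with ``#``-prefixed metadata header
lines; rate maps carry a sidecar ``<name>.mask.csv`` visited-mask matrix.
Floats are written with shortest round-trip formatting, so a write/read
cycle is bit-exact.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .core import LinearRateMap, RateMap, SpikeTrain, Trajectory
from .correlograms import Correlogram1D, Correlogram2D

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_spikes", "read_spikes",
    "write_rate_map", "read_rate_map",
    "write_correlogram", "read_correlogram",
    "read_session",
]

_FLOAT_FMT = "%.17g"


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    arr = np.column_stack([traj.times, traj.positions])
    np.savetxt(path, arr, delimiter=",", fmt=_FLOAT_FMT,
               header="t_seconds,x_cm,y_cm", comments="")


def read_trajectory(path: str | Path) -> Trajectory:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if "t_seconds" not in header:
            raise ValueError(f"{path}: missing trajectory header")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed row at line {ln}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value at line {ln}") from exc
    arr = np.asarray(rows)
    if len(arr) == 0:
        raise ValueError(f"{path}: empty trajectory file")
    dts = np.diff(arr[:, 0])
    if np.any(dts <= 0):
        bad = int(np.argmax(dts <= 0)) + 3  # +2 header/0-base, +1 next row
        raise ValueError(f"{path}: non-monotone timestamp at line {bad}")
    return Trajectory(times=arr[:, 0], positions=arr[:, 1:])


def write_spikes(path: str | Path, spikes: SpikeTrain) -> None:
    np.savetxt(path, spikes.spike_times, fmt=_FLOAT_FMT)


def read_spikes(path: str | Path, cell_id: str | None = None) -> SpikeTrain:
    with open(path) as fh:
        times = []
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                times.append(float(line))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric spike time at line {ln}") from exc
    if cell_id is None:
        cell_id = Path(path).stem
    return SpikeTrain(spike_times=np.asarray(times), cell_id=cell_id)


def _write_matrix(path: str | Path, arr: np.ndarray,
                  meta: dict[str, object]) -> None:
    header = "\n".join(f"{k}={v}" for k, v in meta.items())
    np.savetxt(path, arr, delimiter=",", fmt=_FLOAT_FMT, header=header)


def _read_matrix(path: str | Path) -> tuple[np.ndarray, dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            line = line[1:].strip()
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return arr, meta


def write_rate_map(path: str | Path, rate_map: RateMap) -> None:
    meta = {
        "kind": "rate_map",
        "origin_x": repr(rate_map.origin[0]),
        "origin_y": repr(rate_map.origin[1]),
        "bin_size": repr(rate_map.bin_size),
    }
    _write_matrix(path, rate_map.values, meta)
    mask_path = _mask_path(path)
    np.savetxt(mask_path, rate_map.visited_mask.astype(int),
               delimiter=",", fmt="%d")


def _mask_path(path: str | Path) -> str:
    base, _ = os.path.splitext(str(path))
    return base + ".mask.csv"


def read_rate_map(path: str | Path) -> RateMap:
    values, meta = _read_matrix(path)
    mask_path = _mask_path(path)
    if os.path.exists(mask_path):
        mask = np.loadtxt(mask_path, delimiter=",", ndmin=2).astype(bool)
    else:
        mask = values > 0
    return RateMap(values=values, visited_mask=mask,
                   origin=(float(meta["origin_x"]), float(meta["origin_y"])),
                   bin_size=float(meta.get("bin_size", 1.0)))


def write_correlogram(path: str | Path, corr: Correlogram2D) -> None:
    meta = {
        "kind": "correlogram2d",
        "mode": corr.mode,
        "bin_size": repr(corr.bin_size),
        "n_cells": corr.n_cells,
    }
    _write_matrix(path, corr.values, meta)


def read_correlogram(path: str | Path) -> Correlogram2D:
    values, meta = _read_matrix(path)
    return Correlogram2D(values=values, valid=np.isfinite(values),
                         bin_size=float(meta.get("bin_size", 1.0)),
                         mode=meta.get("mode", "zero_fill_pearson"),
                         n_cells=int(meta.get("n_cells", 1)))


def read_session(traj_path: str | Path,
                 spike_paths: list[str | Path],
                 ) -> tuple[Trajectory, list[SpikeTrain]]:
    """Load a session: one trajectory plus per-cell spike files.

    Cell ids default to the spike-file stems.  Spike times outside the
    trajectory time range are an error.
    """
    traj = read_trajectory(traj_path)
    trains = []
    for p in spike_paths:
        st = read_spikes(p)
        st.check_within(traj)
        trains.append(st)
    return traj, trains
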