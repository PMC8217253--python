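"""Readers and writers for the on-disk formats of all four techniques.

* Reflectivity: 3/4-column whitespace ASCII (Q [Å^-1], R, dR[, dQ FWHM]) with
  a ``#`` header naming the contrast and solvent SLD (ORSO-style data block).
* QCM-D: CSV with columns time_s, f3, d3, f5, d5, f7, d7 — frequency columns
  overtone-normalised (df_raw/n) as instrument exports are — plus a sidecar
  YAML of step annotations.
* Force volume: a directory with ``index.yaml`` (grid shape, scan size,
  speed), per-ramp two-column text files and a rigid reference ramp; or a
  single-file ``.npz`` container.
* Ellipsometry: CSV time series (time_s, n_f, d_f_nm) or raw
  (time_s, psi_deg, delta_deg).
"""

from __future__ import annotations

import pathlib
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .forcevolume import ForceRamp
from .materials import ContrastDefinition
from .qcmd import QcmdTrace
from .reflectometry import ContrastMeasurement

__all__ = [
    "write_reflectivity",
    "read_reflectivity",
    "write_qcmd_csv",
    "read_qcmd_csv",
    "write_steps_yaml",
    "read_steps_yaml",
    "write_fv_dir",
    "read_fv_dir",
    "write_fv_npz",
    "read_fv_npz",
    "write_ellipsometry_csv",
    "read_ellipsometry_csv",
    "load_config",
]


def write_reflectivity(path, meas: ContrastMeasurement) -> None:
    """Write one reflectivity curve as 4-column ASCII with a named header."""
    header = (
        f"contrast: {meas.contrast.name}\n"
        f"solvent_sld_1e-6_A-2: {meas.contrast.solvent_sld:.6f}\n"
        f"d2o_volume_fraction: {meas.contrast.d2o_volume_fraction:.6f}\n"
        f"background: {meas.background:.6e}\n"
        "columns: Q_A-1 R dR dQ_FWHM_A-1"
    )
    dq = meas.dq_over_q * meas.q
    np.savetxt(path, np.column_stack([meas.q, meas.reflectivity, meas.dr, dq]),
               header=header)


def read_reflectivity(path) -> ContrastMeasurement:
    """Read a 3/4-column reflectivity file written by :func:`write_reflectivity`.

    3-column files are assigned the default 4% dq/q resolution.
    """
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] not in (3, 4):
        raise ValueError(f"{path}: expected 3 or 4 columns, got shape {data.shape}")
    q, r, dr = data[:, 0], data[:, 1], data[:, 2]
    dq_over_q = float(np.median(data[:, 3] / q)) if data.shape[1] == 4 else 0.04
    contrast = ContrastDefinition(
        meta.get("contrast", pathlib.Path(path).stem),
        float(meta["solvent_sld_1e-6_A-2"]),
        float(meta.get("d2o_volume_fraction", 0.0)),
    )
    return ContrastMeasurement(q, r, dr, contrast, dq_over_q,
                               background=float(meta.get("background", 0.0)))


# ---------------------------------------------------------------------------
# QCM-D


def write_qcmd_csv(path, trace: QcmdTrace) -> None:
    """Write a trace as CSV with overtone-normalised frequency columns."""
    cols = {"time_s": trace.time}
    for n in trace.overtones:
        cols[f"f{n}"] = trace.df[n] / n  # on-disk convention: df_raw / n
        cols[f"d{n}"] = trace.dd[n]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_qcmd_csv(path, steps_path=None) -> QcmdTrace:
    """Read a QCM-D CSV (normalised df columns -> raw internal shifts)."""
    frame = pd.read_csv(path)
    overtones = sorted(int(c[1:]) for c in frame.columns if c.startswith("f"))
    if not overtones:
        raise ValueError(f"{path}: no overtone columns (f3, f5, ...) found")
    df = {n: frame[f"f{n}"].to_numpy() * n for n in overtones}
    dd = {n: frame[f"d{n}"].to_numpy() for n in overtones}
    annotations = read_steps_yaml(steps_path) if steps_path else []
    return QcmdTrace(frame["time_s"].to_numpy(), df, dd, annotations)


def write_steps_yaml(path, annotations: Sequence[tuple[str, float]]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([{"label": lab, "start_s": float(t)} for lab, t in annotations], fh)


def read_steps_yaml(path) -> list[tuple[str, float]]:
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [(e["label"], float(e["start_s"])) for e in entries]


# ---------------------------------------------------------------------------
# Force volume


def write_fv_dir(path, ramps: Sequence[ForceRamp], reference: ForceRamp,
                 grid_shape: tuple[int, int], scan_size_um: float = 2.0,
                 speed_um_s: float = 1.0) -> None:
    """Write a force-volume container directory (index.yaml + ramp files)."""
    root = pathlib.Path(path)
    root.mkdir(parents=True, exist_ok=True)
    index = {
        "grid_shape": list(grid_shape),
        "scan_size_um": scan_size_um,
        "speed_um_s": speed_um_s,
        "n_ramps": len(ramps),
        "reference": "reference.txt",
        "columns": "piezo_nm signal_V",
    }
    with open(root / "index.yaml", "w") as fh:
        yaml.safe_dump(index, fh)
    for i, ramp in enumerate(ramps):
        np.savetxt(root / f"ramp_{i:05d}.txt",
                   np.column_stack([ramp.piezo_z, ramp.detector_signal]))
    np.savetxt(root / "reference.txt",
               np.column_stack([reference.piezo_z, reference.detector_signal]))


def read_fv_dir(path):
    """Read a force-volume directory; returns (ramps, reference, grid_shape)."""
    root = pathlib.Path(path)
    with open(root / "index.yaml") as fh:
        index = yaml.safe_load(fh)
    ramps = []
    for i in range(int(index["n_ramps"])):
        data = np.loadtxt(root / f"ramp_{i:05d}.txt")
        ramps.append(ForceRamp(data[:, 0], data[:, 1]))
    ref = np.loadtxt(root / index.get("reference", "reference.txt"))
    reference = ForceRamp(ref[:, 0], ref[:, 1])
    return ramps, reference, tuple(index["grid_shape"])


def write_fv_npz(path, ramps: Sequence[ForceRamp], reference: ForceRamp,
                 grid_shape: tuple[int, int]) -> None:
    """Single-file compressed force-volume container."""
    np.savez_compressed(
        path,
        piezo=np.stack([r.piezo_z for r in ramps]),
        signal=np.stack([r.detector_signal for r in ramps]),
        ref_piezo=reference.piezo_z,
        ref_signal=reference.detector_signal,
        grid_shape=np.array(grid_shape),
    )


def read_fv_npz(path):
    with np.load(path) as data:
        ramps = [ForceRamp(p, s) for p, s in zip(data["piezo"], data["signal"])]
        reference = ForceRamp(data["ref_piezo"], data["ref_signal"])
        grid_shape = tuple(int(x) for x in data["grid_shape"])
    return ramps, reference, grid_shape


# ---------------------------------------------------------------------------
# Ellipsometry / config


def write_ellipsometry_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_ellipsometry_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "n_f" in frame.columns and "d_f_nm" in frame.columns:
        return frame
    if "psi_deg" in frame.columns and "delta_deg" in frame.columns:
        return frame
    raise ValueError(
        f"{path}: expected columns (n_f, d_f_nm) or (psi_deg, delta_deg)"
    )


def load_config(path) -> dict:
    """Load a YAML study configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)
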