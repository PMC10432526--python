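"""HDF5 / CSV container I/O.

Cubes and vibration maps go to HDF5 (self-describing: every sweep parameter
is an attribute); dispersion tables and depth profiles to CSV with a
provenance comment header.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acquisition import MScanCube
from .config import SweepConfig
from .demod import SidebandPlan, VibrationMap
from .elastic import DispersionCurve

_SWEEP_FIELDS = ("lambda0", "f_A", "n_samples", "f_s", "sigma_env", "sigma_T", "k1")


def write_cube(path: str | Path, cube: MScanCube) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=cube.data.astype(np.float32))
        h5.create_dataset("x", data=cube.x)
        if cube.stimulus_phase is not None:
            h5.create_dataset("stimulus_phase", data=cube.stimulus_phase)
        for name in _SWEEP_FIELDS:
            h5.attrs[f"sweep/{name}"] = getattr(cube.sweep, name)
        h5.attrs["f_m"] = cube.f_m
        h5.attrs["phi"] = cube.phi
        h5.attrs["snr_db"] = np.nan if cube.snr_db is None else cube.snr_db
        h5.attrs["seed"] = -1 if cube.seed is None else cube.seed


def read_cube(path: str | Path) -> MScanCube:
    with h5py.File(path, "r") as h5:
        sweep = SweepConfig(**{n: h5.attrs[f"sweep/{n}"] for n in _SWEEP_FIELDS})
        snr = float(h5.attrs["snr_db"])
        seed = int(h5.attrs["seed"])
        return MScanCube(
            data=h5["data"][...].astype(float),
            x=h5["x"][...],
            stimulus_phase=h5["stimulus_phase"][...] if "stimulus_phase" in h5 else None,
            sweep=sweep,
            f_m=float(h5.attrs["f_m"]),
            phi=float(h5.attrs["phi"]),
            snr_db=None if np.isnan(snr) else snr,
            seed=None if seed < 0 else seed,
        )


def write_vibration_map(path: str | Path, vib: VibrationMap) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("k0_delta", data=vib.k0_delta)
        h5.create_dataset("mask", data=vib.mask)
        if vib.x is not None:
            h5.create_dataset("x", data=vib.x)
        h5.attrs["k0"] = vib.k0
        h5.attrs["delta_z"] = np.nan if vib.delta_z is None else vib.delta_z
        h5.attrs["jitter_corrected"] = vib.jitter_corrected
        for name in ("f_m", "f_A", "n", "f_folded", "f_apparent", "z_m", "z_m_pixels"):
            h5.attrs[f"plan/{name}"] = getattr(vib.plan, name)
        h5.attrs["plan/lobe"] = vib.plan.lobe


def read_vibration_map(path: str | Path) -> VibrationMap:
    with h5py.File(path, "r") as h5:
        plan = SidebandPlan(
            f_m=float(h5.attrs["plan/f_m"]),
            f_A=float(h5.attrs["plan/f_A"]),
            n=int(h5.attrs["plan/n"]),
            f_folded=float(h5.attrs["plan/f_folded"]),
            f_apparent=float(h5.attrs["plan/f_apparent"]),
            z_m=float(h5.attrs["plan/z_m"]),
            z_m_pixels=float(h5.attrs["plan/z_m_pixels"]),
            lobe=str(h5.attrs["plan/lobe"]),
        )
        dz = float(h5.attrs["delta_z"])
        return VibrationMap(
            k0_delta=h5["k0_delta"][...],
            mask=h5["mask"][...].astype(bool),
            plan=plan,
            k0=float(h5.attrs["k0"]),
            x=h5["x"][...] if "x" in h5 else None,
            delta_z=None if np.isnan(dz) else dz,
            jitter_corrected=bool(h5.attrs["jitter_corrected"]),
        )


def write_dispersion(
    path: str | Path, disp: DispersionCurve, provenance: dict | None = None,
    residual: np.ndarray | None = None,
) -> None:
    df = disp.to_frame()
    if residual is not None:
        df["residual"] = residual
    header = ""
    if provenance:
        header = "# " + json.dumps(provenance, sort_keys=True, default=float) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def read_dispersion(path: str | Path) -> DispersionCurve:
    df = pd.read_csv(path, comment="#")
    return DispersionCurve.from_frame(df)
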