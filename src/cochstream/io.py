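"""Container I/O: HDF5 for fields, CSV for record tables and profiles."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .cohort import RECORD_COLUMNS
from .flow import DriftField, cross_section_flux
from .geometry import CochlearGeometry, cf_from_place
from .transport import EffectTimeProfile

__all__ = [
    "save_drift",
    "load_drift",
    "flux_profile_to_csv",
    "save_records",
    "load_records",
    "effect_time_profile_to_csv",
]


def save_drift(path, drift: DriftField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=drift.u)
        f.create_dataset("v", data=drift.v)
        f.create_dataset("x_faces", data=drift.x_faces)
        f.create_dataset("y_faces", data=drift.y_faces)
        f.attrs["omega"] = drift.omega
        f.attrs["membrane_index"] = -1 if drift.membrane_index is None else drift.membrane_index
        f.attrs["peak_oscillatory_speed"] = drift.peak_oscillatory_speed
        f.attrs["meta_json"] = json.dumps(drift.meta, default=str)


def load_drift(path) -> DriftField:
    with h5py.File(path, "r") as f:
        jm = int(f.attrs["membrane_index"])
        return DriftField(
            x_faces=f["x_faces"][()],
            y_faces=f["y_faces"][()],
            membrane_index=None if jm < 0 else jm,
            u=f["u"][()],
            v=f["v"][()],
            omega=float(f.attrs["omega"]),
            peak_oscillatory_speed=float(f.attrs["peak_oscillatory_speed"]),
            meta=json.loads(f.attrs["meta_json"]),
        )


def flux_profile_to_csv(path, drift: DriftField, n_points: int = 100) -> pd.DataFrame:
    """Axial drift-flux profiles per layer (columns x_m, flux_corti, flux_scala)."""
    L = drift.length_m
    xs = np.linspace(L / n_points, L * (1 - 1.0 / n_points), n_points)
    df = pd.DataFrame(
        {
            "x_m": xs,
            "flux_corti": [cross_section_flux(drift, x, "corti") for x in xs],
            "flux_scala": [cross_section_flux(drift, x, "scala") for x in xs],
        }
    )
    df.to_csv(path, index=False)
    return df


def save_records(path, records: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    records.loc[:, list(RECORD_COLUMNS)].to_csv(path, index=False)


def load_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df


def effect_time_profile_to_csv(
    path, profile: EffectTimeProfile, geom: CochlearGeometry | None = None
) -> pd.DataFrame:
    df = pd.DataFrame({"x_m": profile.x_m, "te_s": profile.te_s})
    if geom is not None:
        df.insert(1, "cf_hz", cf_from_place(geom, profile.x_m))
    df.to_csv(path, index=False)
    return df
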