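"""File formats: epoch sets (HDF5), growth functions and cohorts (CSV),
stimuli (WAV + JSON sidecar), and JSON reports.

Units are explicit in every container (uV for EEG epochs, dB SPL / dB HL
for levels) because the pipeline mixes three dB referents.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dpoae_threshold import DPGrowthFunction
from .synthdata import COHORT_VARIABLES, EpochSet

__all__ = [
    "write_epochs_h5",
    "read_epochs_h5",
    "write_growth_csv",
    "read_growth_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_json_report",
    "VALID_GROUPS",
]

VALID_GROUPS = {"yNH", "yNH_excluded", "oNH", "oHI"}


def write_epochs_h5(path: str | Path, epochs: EpochSet) -> None:
    """Store an epoch set: datasets ``data`` (uV) and ``polarity``, sampling
    rate and provenance as attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("polarity", data=epochs.polarity.astype(np.int8))
        f.attrs["sample_rate_hz"] = epochs.sample_rate
        f.attrs["units"] = "uV"
        f.attrs["epoch_duration_s"] = epochs.epoch_duration
        f.attrs["meta_json"] = json.dumps(epochs.meta, default=str)


def read_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        units = f.attrs.get("units", "uV")
        if units != "uV":
            raise ValueError(f"epoch data must be in uV, file declares "
                             f"{units!r}")
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        return EpochSet(f["data"][()], float(f.attrs["sample_rate_hz"]),
                        f["polarity"][()], meta=meta)


def write_growth_csv(path: str | Path, growth: DPGrowthFunction) -> None:
    pd.DataFrame({"L2_dB": growth.L2, "Ldc_dB": growth.ldc_mean,
                  "Ldc_sd_dB": growth.ldc_sd}).to_csv(path, index=False)


def read_growth_csv(path: str | Path, f2: float = 4000.0,
                    ratio: float = 1.2) -> DPGrowthFunction:
    df = pd.read_csv(path)
    required = {"L2_dB", "Ldc_dB", "Ldc_sd_dB"}
    if not required.issubset(df.columns):
        raise ValueError(f"growth CSV must have columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    return DPGrowthFunction(df["L2_dB"].values, df["Ldc_dB"].values,
                            df["Ldc_sd_dB"].values, f2=f2, ratio=ratio)


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise ValueError("cohort CSV must have a 'group' column")
    bad = set(df["group"].unique()) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if df.get("id") is not None and df["id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort CSV")
    missing = [v for v in COHORT_VARIABLES if v not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing variables: {missing}")
    return df


def write_json_report(path: str | Path, payload: dict,
                      provenance: dict | None = None) -> None:
    out = dict(payload)
    if provenance:
        out["provenance"] = provenance
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
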