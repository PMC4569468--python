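"""File round-tripping: NIfTI volumes/masks and the pipeline CSV schemas."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

CURVE_COLUMNS = ("time_min", "enhancement")
INPUT_CURVE_COLUMNS = ("time_min", "enhancement", "site")
COHORT_COLUMNS = ("patient_id", "os_months", "event")


class SchemaError(ValueError):
    """A table is missing required columns or shapes disagree."""


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None):
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)


def read_dynamic_and_mask(vol_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    vol = read_volume(vol_path)
    mask = read_volume(mask_path) > 0.5
    if vol.ndim != 4:
        raise SchemaError(f"dynamic volume must be 4-D, got shape {vol.shape}")
    if mask.shape != vol.shape[:3]:
        raise SchemaError(
            f"mask shape {mask.shape} does not match dynamic volume spatial "
            f"shape {vol.shape[:3]}"
        )
    return vol, mask


def _require(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_curve_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, CURVE_COLUMNS, f"curve file {path}")
    return df


def read_input_curve_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, INPUT_CURVE_COLUMNS, f"input-curve file {path}")
    return df


def read_vfa_csv(path):
    """Variable-flip-angle series from CSV (flip_deg, signal columns; one
    TR_ms value)."""
    from .input_functions import VfaSeries

    df = pd.read_csv(path)
    _require(df, ("flip_deg", "signal", "TR_ms"), f"VFA file {path}")
    return VfaSeries(df["flip_deg"].to_numpy(), df["signal"].to_numpy(),
                     float(df["TR_ms"].iloc[0]))


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, COHORT_COLUMNS, f"cohort file {path}")
    return df


def write_table(path, df: pd.DataFrame):
    """Deterministic CSV output (fixed float formatting, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.8g")
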