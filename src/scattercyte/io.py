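"""Reading and writing the pipeline's file formats.

LSP sets travel as HDF5 (datasets ``angles``, ``intensities``, ``labels``
plus an optional ground-truth parameter table and config attributes) or as
flat CSV with one row per cell (angle columns then a label column).
Feature tables are plain CSV with the header
``D_um, nc_ratio, ri_n, ri_c, label, residual``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .population import LSPSet

__all__ = [
    "write_lsp_set_h5",
    "read_lsp_set_h5",
    "write_lsp_set_csv",
    "read_lsp_set_csv",
    "write_feature_table",
    "read_feature_table",
]


def write_lsp_set_h5(
    lsps: LSPSet, path: str | Path, truth: pd.DataFrame | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("angles", data=lsps.angles)
        f.create_dataset("intensities", data=lsps.intensities)
        f.create_dataset(
            "labels", data=np.array(lsps.labels, dtype=h5py.string_dtype())
        )
        if truth is not None:
            f.create_dataset(
                "truth_params",
                data=truth[["D_um", "nc_ratio", "ri_n", "ri_c"]].to_numpy(),
            )
        f.attrs["meta"] = json.dumps(lsps.meta, sort_keys=True, default=str)


def read_lsp_set_h5(path: str | Path) -> tuple[LSPSet, pd.DataFrame | None]:
    with h5py.File(path, "r") as f:
        lsps = LSPSet(
            angles=f["angles"][...],
            intensities=f["intensities"][...],
            labels=[s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][...]],
            meta=json.loads(f.attrs.get("meta", "{}")),
        )
        truth = None
        if "truth_params" in f:
            truth = pd.DataFrame(
                f["truth_params"][...], columns=["D_um", "nc_ratio", "ri_n", "ri_c"]
            )
            truth["label"] = lsps.labels
    return lsps, truth


def write_lsp_set_csv(lsps: LSPSet, path: str | Path) -> None:
    """One row per cell: intensity at each angle, then the label."""
    cols = [f"theta_{a:.1f}" for a in lsps.angles]
    df = pd.DataFrame(lsps.intensities, columns=cols)
    df["label"] = lsps.labels
    df.to_csv(path, index=False)


def read_lsp_set_csv(path: str | Path) -> LSPSet:
    df = pd.read_csv(path)
    label_col = "label" if "label" in df.columns else None
    angle_cols = [c for c in df.columns if c.startswith("theta_")]
    if not angle_cols:
        raise ValueError("no angle columns (theta_*) found")
    angles = np.array([float(c.split("_", 1)[1]) for c in angle_cols])
    labels = df[label_col].astype(str).tolist() if label_col else [""] * len(df)
    return LSPSet(angles=angles, intensities=df[angle_cols].to_numpy(), labels=labels)


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    cols = ["D_um", "nc_ratio", "ri_n", "ri_c", "label", "residual"]
    extra = [c for c in features.columns if c not in cols]
    features[cols + extra].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
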