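"""NIfTI / TSV / JSON / YAML handling shared by the command-line workflows.

Volumes are written with an identity affine; voxel indices are 0-based and
no world-coordinate interpretation is attached.  Every command drops a JSON
provenance sidecar with the configuration, seeds and package version next
to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml


def save_volume(data: np.ndarray, path: str | Path, dtype=None) -> Path:
    """Write a 3D/4D array as NIfTI with an identity affine."""
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj)


def save_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a metrics table as TSV (round-trippable with read_table)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def save_sidecar(payload: dict, path: str | Path) -> Path:
    """Write a JSON provenance sidecar (config echo, seeds, versions)."""
    from . import __version__

    path = Path(path)
    body = {"abtlayers_version": __version__, **payload}
    path.write_text(json.dumps(body, indent=2, sort_keys=True, default=str)
                    + "\n")
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
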