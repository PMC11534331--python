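"""NIfTI and tabular I/O helpers (thin wrappers over nibabel / pandas)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["read_volume", "write_volume", "read_labels_tsv", "write_maps"]


def read_volume(path):
    """Load a NIfTI volume; returns (data, img) with the image kept for its
    affine/header."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img


def write_volume(data, like, path) -> None:
    """Write ``data`` as NIfTI reusing the affine/header of image ``like``."""
    out = nib.Nifti1Image(np.asarray(data), like.affine, like.header)
    nib.save(out, str(path))


def write_maps(maps, like, out_dir) -> dict:
    """Write ParameterMaps (cbf/att/kw + flags) beside each other."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("cbf", "att", "kw", "flags"):
        arr = getattr(maps, name)
        p = out_dir / f"{name}.nii.gz"
        out = nib.Nifti1Image(
            np.asarray(arr, dtype=np.float64 if name != "flags" else np.uint8),
            like.affine,
        )
        nib.save(out, str(p))
        paths[name] = p
    return paths


def read_labels_tsv(path) -> dict[str, int]:
    """Read a two-column name<TAB>label region map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "label"])
    return dict(zip(df["name"], df["label"].astype(int)))
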