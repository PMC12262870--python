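"""File I/O: NIfTI maps and masks, BIDS-style events TSV, tidy tables, JSON.

Maps are written one 3-D NIfTI image per subject per measure, with values
outside the ROI mask set to zero; affines are interpreted as RAS+ mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .maps import ConnectivityMap, ROIGeometry
from .synthetic import TaskDesign

__all__ = [
    "write_map", "read_maps", "write_mask", "read_mask",
    "write_events_tsv", "read_events_tsv", "write_json",
]


def write_mask(roi: ROIGeometry, path) -> Path:
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), roi.affine)
    nib.save(img, str(path))
    return Path(path)


def read_mask(path, name: str | None = None, **roi_kwargs) -> ROIGeometry:
    img = nib.load(str(path))
    return ROIGeometry(name=name or Path(path).stem.split(".")[0],
                       mask=np.asarray(img.dataobj) > 0,
                       affine=img.affine, **roi_kwargs)


def write_map(cmap: ConnectivityMap, path) -> Path:
    img = nib.Nifti1Image(cmap.to_volume(fill=0.0), cmap.roi.affine)
    nib.save(img, str(path))
    return Path(path)


def read_maps(paths, mask_path, name: str | None = None,
              subject_ids: list[str] | None = None) -> list[ConnectivityMap]:
    """Load per-subject map images restricted to a shared ROI mask.

    Every image must match the mask's shape and affine; a mismatch raises an
    error naming the offending file.
    """
    roi = read_mask(mask_path, name=name)
    maps = []
    ids = subject_ids or [Path(p).stem.split(".")[0] for p in paths]
    for path, sid in zip(paths, ids):
        img = nib.load(str(path))
        if img.shape[:3] != roi.mask.shape:
            raise ValueError(f"{path}: shape {img.shape[:3]} does not match "
                             f"mask shape {roi.mask.shape}")
        if not np.allclose(img.affine, roi.affine, atol=1e-6):
            raise ValueError(f"{path}: affine does not match the mask affine")
        data = np.asarray(img.dataobj, dtype=float)
        maps.append(ConnectivityMap(roi=roi, values=data[roi.mask],
                                    subject_id=sid))
    return maps


def write_events_tsv(design: TaskDesign, path, block: int | None = None) -> Path:
    """BIDS events dialect: onset, duration, trial_type (one file per run)."""
    sel = np.ones(design.n_trials, bool) if block is None \
        else design.block == block
    df = pd.DataFrame({
        "onset": design.onsets[sel],
        "duration": np.full(int(sel.sum()), design.trial_duration),
        "trial_type": [f"snr{s:+d}_{y}" for s, y in
                       zip(design.snr_db[sel], design.syllable[sel])],
    })
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing events columns "
                         f"{sorted(required - set(df.columns))}")
    return df


def write_json(obj, path) -> Path:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
    return Path(path)
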