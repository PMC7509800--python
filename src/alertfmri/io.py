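"""NIfTI-1 reading/writing for sessions, masks, and statistical maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from alertfmri.bold_synth import BoldSession, TumorMask
from alertfmri.errors import DimensionError

__all__ = [
    "save_session",
    "load_session",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
]


def save_session(session: BoldSession, path: str | Path) -> None:
    img = nib.Nifti1Image(session.data.astype(np.float32), session.affine)
    img.header.set_zooms((session.voxel_size_mm,) * 3 + (session.tr_s,))
    nib.save(img, str(path))


def load_session(
    bold_path: str | Path, mask_path: str | Path, tr_s: float | None = None
) -> BoldSession:
    img = nib.load(str(bold_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionError(f"expected 4D BOLD, got {data.ndim}D")
    zooms = img.header.get_zooms()
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    mask = load_mask(mask_path)
    return BoldSession(
        data=data,
        tr_s=tr_s,
        voxel_size_mm=float(zooms[0]),
        affine=np.asarray(img.affine, dtype=float),
        brain_mask=mask,
    )


def save_volume(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.affine, dtype=float)


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0
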