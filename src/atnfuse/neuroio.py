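"""Optional ingestion of voxel/vertex containers into the pipeline's matrix form.

Bridges per-subject NIfTI volumes (or GIFTI surface maps) into the
subjects-by-features TSV matrices the rest of the pipeline consumes: one row
per subject, one column per in-mask voxel/vertex, feature IDs encoding the
linear index so a matrix row can be exported back into a volume losslessly.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def _load_data(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    if hasattr(img, "agg_data"):  # GIFTI
        try:
            return np.asarray(img.agg_data(), dtype=float)
        except TypeError:
            pass
    return np.asarray(img.get_fdata(), dtype=float)


def ingest_neuro_volumes(paths: list[str | Path], mask: str | Path | np.ndarray
                         ) -> tuple[np.ndarray, list[str]]:
    """Stack per-subject volumes into a subjects-by-in-mask-voxels matrix.

    All inputs must share the mask's grid; feature IDs are ``vox<linear index>``.
    """
    mask_arr = mask if isinstance(mask, np.ndarray) else _load_data(mask)
    mask_bool = np.asarray(mask_arr) > 0
    lin = np.flatnonzero(mask_bool.ravel())
    rows = []
    shapes = {}
    for p in paths:
        data = _load_data(p)
        shapes[str(p)] = data.shape
        if data.shape != mask_bool.shape:
            offending = {k: v for k, v in shapes.items() if v != mask_bool.shape}
            raise ValueError(
                f"grid mismatch with mask {mask_bool.shape}: {offending}")
        rows.append(data.ravel()[lin])
    matrix = np.vstack(rows) if rows else np.empty((0, lin.size))
    feature_ids = [f"vox{int(i):08d}" for i in lin]
    return matrix, feature_ids


def export_volume(row: np.ndarray, feature_ids: list[str], mask_shape: tuple,
                  affine: np.ndarray | None = None, out_path: str | Path | None = None):
    """Inverse of :func:`ingest_neuro_volumes` for one subject/component row.

    Off-mask voxels are zero; in-mask values are restored exactly.
    """
    vol = np.zeros(int(np.prod(mask_shape)))
    idx = np.array([int(f[3:]) for f in feature_ids])
    vol[idx] = np.asarray(row, dtype=float)
    vol = vol.reshape(mask_shape)
    if out_path is not None:
        img = nib.Nifti1Image(vol, affine if affine is not None else np.eye(4))
        nib.save(img, str(out_path))
    return vol
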