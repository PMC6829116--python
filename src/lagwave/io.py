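"""NIfTI / TSV / JSON persistence for datasets, maps, and templates."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import Dataset, ROISet, TemplateSet


def _affine(tr: float | None = None) -> np.ndarray:
    return np.eye(4)


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as 4-D NIfTI plus a JSON sidecar (tr, run bounds)."""
    path = Path(path)
    vol = dataset.embed(dataset.data, fill=0.0)
    img = nib.Nifti1Image(vol.astype(np.float32), _affine())
    img.header.set_zooms((1.0, 1.0, 1.0, dataset.tr))
    nib.save(img, str(path))
    sidecar = {
        "tr": dataset.tr,
        "run_bounds": [list(b) for b in dataset.run_bounds],
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_dataset(path: str | Path) -> Dataset:
    """Read a 4-D NIfTI + sidecar back into a Dataset (mask = any nonzero)."""
    path = Path(path)
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    mask = np.any(vol != 0, axis=3)
    idx = np.argwhere(mask)
    data = vol[mask]
    return Dataset(data=data, tr=float(sidecar["tr"]),
                   run_bounds=[tuple(b) for b in sidecar["run_bounds"]],
                   shape=vol.shape[:3], voxel_indices=idx)


def save_map(values: np.ndarray, dataset: Dataset, path: str | Path) -> None:
    """Write a per-voxel map as 3-D NIfTI; invalid voxels become NaN."""
    vol = dataset.embed(np.asarray(values, float))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), _affine()), str(path))


def save_template_set(templates: TemplateSet, dataset: Dataset, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, tpl in templates.templates.items():
        save_map(tpl, dataset, out_dir / f"{name}.nii.gz")


def save_roi_set(rois: ROISet, dataset: Dataset, path: str | Path) -> None:
    vol = dataset.embed(rois.labels.astype(float), fill=0.0)
    nib.save(nib.Nifti1Image(vol.astype(np.int16), _affine()), str(path))


def save_series_tsv(series: np.ndarray, path: str | Path, prefix: str = "c") -> None:
    """Components-by-time (or time-by-components) series as TSV."""
    arr = np.asarray(series, float)
    if arr.ndim == 1:
        arr = arr[None, :]
    df = pd.DataFrame(arr.T, columns=[f"{prefix}{i:02d}" for i in range(arr.shape[0])])
    df.to_csv(path, sep="\t", index=False)


def save_matrix_tsv(matrix: np.ndarray, names: list[str], path: str | Path) -> None:
    pd.DataFrame(np.asarray(matrix, float), index=names, columns=names).to_csv(path, sep="\t")
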