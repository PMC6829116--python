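"""Core containers shared across the pipeline.

The central object is :class:`Dataset`: a masked voxels-by-timepoints matrix
with its repetition time, run boundaries, and the 3-D grid geometry needed to
put per-voxel maps back into volume space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

RunBounds = list[tuple[int, int]]


def check_run_bounds(bounds: Sequence[tuple[int, int]], n_timepoints: int) -> RunBounds:
    """Validate that half-open run bounds tile [0, T) without gaps or overlap."""
    bounds = [(int(a), int(b)) for a, b in bounds]
    if not bounds:
        raise ValueError("at least one run is required")
    cursor = 0
    for a, b in bounds:
        if a != cursor or b <= a:
            raise ValueError(f"run bounds {bounds} do not tile [0, {n_timepoints})")
        cursor = b
    if cursor != n_timepoints:
        raise ValueError(f"run bounds {bounds} do not cover all {n_timepoints} timepoints")
    return bounds


@dataclass
class Dataset:
    """Masked voxel x time BOLD-like matrix with acquisition metadata.

    Attributes
    ----------
    data : (V, T) float array
    tr : float
        Seconds per sample; must be positive.
    run_bounds : list of (start, end)
        Half-open, 0-based timepoint ranges of the concatenated runs.
    shape : (nx, ny, nz)
        Grid shape of the underlying volume.
    voxel_indices : (V, 3) int array
        Grid coordinate of each row of ``data``.
    """

    data: np.ndarray
    tr: float
    run_bounds: RunBounds
    shape: tuple[int, int, int]
    voxel_indices: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be voxels x timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.run_bounds = check_run_bounds(self.run_bounds, self.n_timepoints)
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.voxel_indices.shape != (self.n_voxels, 3):
            raise ValueError("voxel_indices must be (V, 3)")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_bounds)

    @property
    def mask(self) -> np.ndarray:
        """Boolean 3-D grid with True at every voxel of the matrix."""
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.voxel_indices.T)] = True
        return m

    def runs(self) -> list[np.ndarray]:
        """Views of the data split at the run boundaries."""
        return [self.data[:, a:b] for a, b in self.run_bounds]

    def embed(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back into a 3-D (or 4-D) grid volume."""
        values = np.asarray(values, dtype=float)
        out = np.full(self.shape + values.shape[1:], fill)
        out[tuple(self.voxel_indices.T)] = values
        return out

    def with_data(self, data: np.ndarray) -> "Dataset":
        """Same geometry and metadata, new matrix."""
        return Dataset(data, self.tr, list(self.run_bounds), self.shape,
                       self.voxel_indices.copy())


@dataclass
class TemplateSet:
    """Named per-voxel spatial templates; exactly one is the whole-brain map."""

    templates: dict[str, np.ndarray]
    whole_brain: str
    mask: np.ndarray  # (V,) bool, matching-domain mask

    def __post_init__(self) -> None:
        if self.whole_brain not in self.templates:
            raise ValueError(f"whole-brain template {self.whole_brain!r} missing")
        sizes = {np.asarray(t).shape for t in self.templates.values()}
        if len(sizes) != 1:
            raise ValueError("all templates must share one geometry")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def network_names(self) -> list[str]:
        return [n for n in self.templates if n != self.whole_brain]


@dataclass
class ROISet:
    """Integer parcellation over the voxel list; label 0 is background."""

    labels: np.ndarray  # (V,) int
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels)) - {0}
        if not self.names:
            self.names = {int(k): f"roi{int(k)}" for k in sorted(present)}
        for k in self.names:
            if int(k) not in present:
                raise ValueError(f"named ROI {k} has no voxels")

    @property
    def roi_labels(self) -> list[int]:
        return sorted(self.names)
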