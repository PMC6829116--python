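"""Run-wise detrending, band-pass filtering, concatenation, whole-brain signal.

Filtering is zero-phase (forward-backward Butterworth): the voxel-wise lag
maps computed downstream are the scientific object of the pipeline, so the
filter itself must introduce no phase delay. The band alone is the scientific
parameter; the filter family (4th-order Butterworth applied forward and
backward) is this package's declared default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import Dataset


@dataclass
class PreprocessConfig:
    band: tuple[float, float] = (0.01, 0.1)
    detrend: bool = True
    gm_threshold: float = 0.10
    order: int = 4  # Butterworth order before the forward-backward pass


def design_bandpass(band: tuple[float, float], tr: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the band-pass filter for sampling interval tr."""
    low, high = band
    nyquist = 0.5 / tr
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist = {nyquist:.4g} Hz at TR {tr} s"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")


def _min_run_length(sos: np.ndarray) -> int:
    # sosfiltfilt pads with 3 * (2 * n_sections + 1) samples; require three
    # such filter lengths so the transient never dominates a run.
    return 3 * (3 * (2 * sos.shape[0] + 1))


def preprocess_run(run: np.ndarray, tr: float, config: PreprocessConfig | None = None) -> np.ndarray:
    """Detrend (degree-1) and zero-phase band-pass one run.

    ``run`` is voxels x timepoints (a 1-D series is also accepted). Filtering
    is applied within the run only: never across run seams.
    """
    config = config or PreprocessConfig()
    run = np.atleast_2d(np.asarray(run, dtype=float))
    sos = design_bandpass(config.band, tr, config.order)
    n = run.shape[1]
    min_len = _min_run_length(sos)
    if n < min_len:
        raise ValueError(
            f"run of {n} samples is shorter than the minimum {min_len} "
            f"(three filter lengths) for this band-pass design"
        )
    if n * tr < 10.0 / config.band[0]:
        warnings.warn(
            f"Run duration {n * tr:.0f} s is shorter than 10 periods of the "
            f"lower band edge ({10.0 / config.band[0]:.0f} s); low-frequency "
            "estimates may be unstable",
            UserWarning,
        )
    out = run
    if config.detrend:
        out = signal.detrend(out, axis=1, type="linear")
    out = signal.sosfiltfilt(sos, out, axis=1)
    return out


def preprocess_dataset(dataset: Dataset, config: PreprocessConfig | None = None) -> Dataset:
    """Apply :func:`preprocess_run` to every run of a dataset independently."""
    filtered = [preprocess_run(r, dataset.tr, config) for r in dataset.runs()]
    data, _ = concatenate_runs(filtered)
    return dataset.with_data(data)


def concatenate_runs(runs: list[np.ndarray]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Concatenate run matrices along time; returns (data, run_bounds)."""
    shapes = [np.asarray(r).shape for r in runs]
    if len({s[0] for s in shapes}) != 1:
        raise ValueError(f"runs have mismatched voxel counts: shapes {shapes}")
    bounds = []
    cursor = 0
    for r in runs:
        t = np.asarray(r).shape[1]
        bounds.append((cursor, cursor + t))
        cursor += t
    return np.concatenate([np.asarray(r, float) for r in runs], axis=1), bounds


def deconcatenate(data: np.ndarray, run_bounds: list[tuple[int, int]]) -> list[np.ndarray]:
    """Split a concatenated matrix back into its runs (round-trip exact)."""
    return [data[:, a:b] for a, b in run_bounds]


def whole_brain_signal(dataset: Dataset, gm_probability: np.ndarray,
                       threshold: float = 0.10) -> np.ndarray:
    """Unweighted mean series over voxels with gray-matter probability >= threshold.

    The threshold is inclusive: a voxel exactly at the threshold is kept.
    """
    gm = np.asarray(gm_probability, dtype=float)
    if gm.shape != (dataset.n_voxels,):
        raise ValueError("gray-matter map must be per-voxel on the dataset geometry")
    mask = gm >= threshold
    if not mask.any():
        raise ValueError(f"gray-matter mask at threshold {threshold} is empty")
    return dataset.data[mask].mean(axis=0)
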