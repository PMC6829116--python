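"""Synthetic resting-state datasets with planted traveling waves.

The generator emulates the signal structure the pipeline is built to recover:
band-limited (0.01-0.1 Hz) sources, of which some are *global waves* — a
shared source reaching each voxel with a per-voxel lag and magnitude — and
some are *local* sources confined to network masks, plus band-passed white
noise. Ground truth (sources, lag fields, magnitude fields, labels, noise) is
retained so every stage can be scored against what was planted.

Source shifting uses the same sinc-interpolation routine as the analysis
(:mod:`lagwave.shift`), so generator and estimator share one delay convention:
positive lag = the voxel's signal arrives later than the source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.ndimage import gaussian_filter

from .preprocess import PreprocessConfig, preprocess_run
from .shift import sinc_shift
from .types import Dataset, ROISet, TemplateSet


# --------------------------------------------------------------------------
# sources

def _band_project(x: np.ndarray, band: tuple[float, float], tr: float,
                  keep_low_inclusive: bool = True) -> np.ndarray:
    """Hard spectral projection of a series onto [low, high] Hz (rFFT bins)."""
    freqs = np.fft.rfftfreq(x.size, d=tr)
    spec = np.fft.rfft(x)
    low, high = band
    keep = (freqs >= low) & (freqs <= high) if keep_low_inclusive else (freqs <= high)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=x.size)


def generate_band_limited_source(timepoints: int, tr: float,
                                 band: tuple[float, float] = (0.01, 0.1),
                                 seed: int | None = None,
                                 rng: np.random.Generator | None = None,
                                 modulation_depth: float = 2.0 / 3.0) -> np.ndarray:
    """One unit-variance, band-limited, super-Gaussian source series.

    A band-limited Gaussian carrier is amplitude-modulated by a slow
    non-negative envelope (making the series bursty, hence non-Gaussian, which
    temporal ICA needs), then projected back onto the band and standardized.
    By construction essentially all spectral power lies inside the band.
    ``modulation_depth`` in [0, 1) sets how bursty the series is (0 = Gaussian,
    near 1 = strongly non-Gaussian); the default gives mild, BOLD-like
    burstiness with excess kurtosis of a few units.
    """
    if timepoints < 64:
        raise ValueError("at least 64 timepoints are required")
    low, high = band
    nyquist = 0.5 / tr
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must lie strictly inside (0, Nyquist) "
            f"with Nyquist = {nyquist:.4g} Hz at TR {tr} s"
        )
    if rng is None:
        rng = default_rng(seed)
    carrier = _band_project(rng.standard_normal(timepoints), band, tr)
    slow = np.fft.rfftfreq(timepoints, d=tr) < low
    spec = np.fft.rfft(rng.standard_normal(timepoints))
    spec[~slow] = 0.0
    envelope = np.fft.irfft(spec, n=timepoints)
    sd = envelope.std()
    if sd > 0:
        envelope = envelope / sd
    d = modulation_depth
    if not 0 <= d < 1:
        raise ValueError("modulation_depth must be in [0, 1)")
    s = carrier * ((1.0 - d) + d * envelope ** 2)
    s = _band_project(s, band, tr)
    s = s - s.mean()
    return s / s.std()


def make_node_fixture(n_sources: int = 5, n_nodes: int = 20, n_runs: int = 6,
                      timepoints_per_run: int = 1200, tr: float = 0.72,
                      band: tuple[float, float] = (0.01, 0.1),
                      noise_sd: float = 0.25, modulation_depth: float = 0.9,
                      seed: int = 0):
    """Node-level test bed for temporal ICA: strongly non-Gaussian band-limited
    sources mixed into node series plus spatially mixed white noise.

    Emulates the input of the temporal-ICA stage directly (as if produced by
    dual regression of many functional nodes), skipping the voxel level.
    Returns (sources (n_sources, T), node series matrix (T, n_nodes),
    run_bounds).
    """
    rng = default_rng(SeedSequence(seed))
    T = n_runs * timepoints_per_run
    sources = np.zeros((n_sources, T))
    for c in range(n_sources):
        for r in range(n_runs):
            sources[c, r * timepoints_per_run:(r + 1) * timepoints_per_run] = (
                generate_band_limited_source(timepoints_per_run, tr, band, rng=rng,
                                             modulation_depth=modulation_depth))
    mixing = rng.normal(size=(n_nodes, n_sources))
    spatial = rng.normal(size=(n_nodes, n_nodes)) / np.sqrt(n_nodes)
    noise = rng.standard_normal((T, n_nodes)) @ spatial.T
    noise /= noise.std(axis=0)
    X = (mixing @ sources).T + noise_sd * noise
    X /= X.std(axis=0)
    run_bounds = [(r * timepoints_per_run, (r + 1) * timepoints_per_run)
                  for r in range(n_runs)]
    return sources, X, run_bounds


# --------------------------------------------------------------------------
# geometry helpers

def default_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Elliptic-cylinder mask (a crude brain-slab stand-in) on the grid."""
    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rx, ry = (nx - 1) / 2.0, (ny - 1) / 2.0
    disk = ((x - rx) / (rx + 0.2)) ** 2 + ((y - ry) / (ry + 0.2)) ** 2 <= 1.0
    return np.repeat(disk[:, :, None], nz, axis=2)


def build_lag_field(voxel_indices: np.ndarray, origin_cell: Sequence[float],
                    speed: float, pitch: float = 1.0,
                    max_lag: float | None = None) -> np.ndarray:
    """Per-voxel lag (s) of a wave radiating from an origin at fixed speed.

    lag(v) = Euclidean grid distance(v, origin) * pitch / speed; the origin
    itself has lag 0. Warns when the field exceeds the analysis window.
    """
    if speed <= 0:
        raise ValueError("propagation speed must be positive")
    d = np.linalg.norm(np.asarray(voxel_indices, float) - np.asarray(origin_cell, float),
                       axis=1)
    lags = d * pitch / speed
    if max_lag is not None and lags.max() > max_lag:
        warnings.warn(
            f"maximum planted lag {lags.max():.2f} s exceeds the analysis "
            f"window of {max_lag:.2f} s",
            UserWarning,
        )
    return lags


def _smooth_positive_field(shape, mask_idx, rng, base=1.0, spread=0.35, sigma=2.5):
    """Smooth strictly-positive per-voxel weights (mean about ``base``)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    vals = f[tuple(mask_idx.T)]
    vals = (vals - vals.mean()) / (vals.std() + 1e-12)
    return np.clip(base + spread * vals, 0.2 * base, None)


# --------------------------------------------------------------------------
# configuration and ground truth

@dataclass
class WaveSpec:
    """A global wave: either an origin+speed or an explicit lag field (s)."""

    origin: tuple[float, float, float] | None = None
    speed: float | None = None  # grid cells per second
    lag_field: np.ndarray | None = None  # per-voxel seconds


def attenuating_magnitude(voxel_indices: np.ndarray, origin, shape,
                          rng: np.random.Generator,
                          floor: float = 0.35, length: float = 12.0) -> np.ndarray:
    """Default magnitude field of a wave: strong near its origin, attenuating
    with travelled distance (waves lose amplitude along the propagation path,
    which also makes distinct waves spatially distinct rather than fully
    overlapping), times a mild smooth spatial modulation.

    The waves stay broad (semi-global): every voxel keeps a substantial
    fraction of the origin amplitude, which is the premise that makes
    whole-brain-template classification meaningful, while the attenuation
    still reproduces the reported negative magnitude-vs-lag association
    (waves losing amplitude along the propagation path)."""
    d = np.linalg.norm(np.asarray(voxel_indices, float) - np.asarray(origin, float), axis=1)
    profile = floor + (1.0 - floor) * np.exp(-0.5 * (d / length) ** 2)
    modulation = _smooth_positive_field(shape, voxel_indices, rng, base=1.0, spread=0.15)
    return profile * modulation


@dataclass
class SimulationConfig:
    shape: tuple[int, int, int] = (20, 20, 6)
    n_runs: int = 2
    timepoints_per_run: int = 600
    tr: float = 0.72
    band: tuple[float, float] = (0.01, 0.1)
    n_global: int = 2
    n_local: int = 4
    wave_specs: list[WaveSpec] | None = None
    magnitude_fields: list[np.ndarray] | None = None
    network_masks: list[np.ndarray] | None = None  # per local source, (V,) bool
    local_magnitudes: list[np.ndarray] | None = None
    local_global_ratio: float = 1.0  # amplitude of local sources vs global waves
    noise_sd: float = 0.5
    max_lag: float = 6.3  # analysis window, seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError("band low must be below band high")
        if self.n_global == 0 and self.n_local == 0:
            raise ValueError("at least one global or local source is required")


@dataclass
class GroundTruth:
    sources: np.ndarray            # (n_components, T), unit variance, run-wise generated
    lag_fields: list[np.ndarray]   # per global wave, (V,) seconds
    magnitude_fields: list[np.ndarray]
    network_masks: list[np.ndarray]
    local_magnitudes: list[np.ndarray]
    labels: list[str]              # 'global' or 'local', aligned with sources
    noise: np.ndarray              # realized (V, T) noise matrix
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def n_global(self) -> int:
        return self.labels.count("global")

    def global_sources(self) -> np.ndarray:
        return self.sources[[i for i, l in enumerate(self.labels) if l == "global"]]

    def local_sources(self) -> np.ndarray:
        return self.sources[[i for i, l in enumerate(self.labels) if l == "local"]]


# --------------------------------------------------------------------------
# defaults for waves / networks

# Wave origins are kept away from the default network-blob centres: a wave
# whose origin sits on a network territory would genuinely resemble that
# network's template, defeating the premise that global waves are spatially
# distinct from single-network patterns.
_DEFAULT_ORIGINS = [(10.0, 4.0, 3.0), (9.0, 17.0, 2.0), (17.0, 9.0, 3.0), (3.0, 10.0, 2.0)]
_DEFAULT_SPEEDS = [5.0, 4.5, 5.5, 4.0]


def _default_network_masks(cfg: SimulationConfig, voxel_indices: np.ndarray) -> list[np.ndarray]:
    """Non-overlapping spherical blobs, one per local source."""
    nx, ny, nz = cfg.shape
    centers = [
        (nx * 0.28, ny * 0.28, nz * 0.5), (nx * 0.72, ny * 0.72, nz * 0.5),
        (nx * 0.28, ny * 0.72, nz * 0.5), (nx * 0.72, ny * 0.28, nz * 0.5),
        (nx * 0.5, ny * 0.5, nz * 0.3), (nx * 0.5, ny * 0.15, nz * 0.7),
    ]
    radius = min(nx, ny) * 0.16
    masks = []
    for i in range(cfg.n_local):
        c = np.asarray(centers[i % len(centers)], float)
        d = np.linalg.norm(voxel_indices - c, axis=1)
        masks.append(d <= radius)
    return masks


def make_template_set(magnitude_fields: list[np.ndarray],
                      network_masks: list[np.ndarray],
                      local_magnitudes: list[np.ndarray],
                      mask: np.ndarray | None = None,
                      names: list[str] | None = None) -> TemplateSet:
    """Templates matched to a simulation: each local source's magnitude
    support becomes a network template; the average global magnitude pattern
    is the whole-brain template."""
    n_vox = network_masks[0].size if network_masks else magnitude_fields[0].size
    templates: dict[str, np.ndarray] = {}
    for i, (m, lm) in enumerate(zip(network_masks, local_magnitudes)):
        name = names[i] if names else f"network{i + 1:02d}"
        tpl = np.zeros(n_vox)
        tpl[m] = lm[m]
        templates[name] = tpl
    if magnitude_fields:
        wb = np.mean(magnitude_fields, axis=0)
    else:
        wb = np.ones(n_vox)
    templates["whole_brain"] = wb
    if mask is None:
        mask = np.ones(n_vox, dtype=bool)
    return TemplateSet(templates=templates, whole_brain="whole_brain", mask=mask)


def make_roi_set(cfg: SimulationConfig, voxel_indices: np.ndarray,
                 network_masks: list[np.ndarray],
                 block: tuple[int, int, int] = (5, 5, 3)) -> ROISet:
    """Partition the mask: one ROI per network, remaining tissue in grid blocks."""
    n_vox = voxel_indices.shape[0]
    labels = np.zeros(n_vox, dtype=int)
    names: dict[int, str] = {}
    next_label = 1
    for i, m in enumerate(network_masks):
        assign = m & (labels == 0)
        if assign.any():
            labels[assign] = next_label
            names[next_label] = f"network{i + 1:02d}"
            next_label += 1
    rest = labels == 0
    block_id = (voxel_indices // np.asarray(block)).astype(int)
    for key in np.unique(block_id[rest], axis=0):
        sel = rest & np.all(block_id == key, axis=1)
        if sel.any():
            labels[sel] = next_label
            names[next_label] = f"tissue_{key[0]}_{key[1]}_{key[2]}"
            next_label += 1
    return ROISet(labels=labels, names=names)


# --------------------------------------------------------------------------
# the generator

def simulate_dataset(cfg: SimulationConfig) -> tuple[Dataset, GroundTruth, TemplateSet, ROISet]:
    """Build a dataset of planted global waves + local sources + noise.

    data(v, t) = sum_g mag_g(v) * s_g(t - lag_g(v))
               + sum_l mask_l(v) * mag_l(v) * s_l(t)
               + noise_sd * eps(v, t)

    Sources are generated independently per run and shifted run-wise (the
    analysis also treats runs separately). Noise is white Gaussian band-passed
    with the analysis filter then rescaled to ``noise_sd`` per voxel, so it
    cannot be removed by the band-pass stage.
    """
    ss = SeedSequence(cfg.seed)
    seeds = ss.spawn(4)
    rng_geom = default_rng(seeds[0])
    mask3d = default_mask(cfg.shape)
    voxel_indices = np.argwhere(mask3d)
    n_vox = voxel_indices.shape[0]
    T_run, n_runs = cfg.timepoints_per_run, cfg.n_runs
    T = T_run * n_runs

    # --- global wave structure
    wave_specs = cfg.wave_specs
    if wave_specs is None:
        wave_specs = [WaveSpec(origin=_DEFAULT_ORIGINS[g % len(_DEFAULT_ORIGINS)],
                               speed=_DEFAULT_SPEEDS[g % len(_DEFAULT_SPEEDS)])
                      for g in range(cfg.n_global)]
    lag_fields = []
    for spec in wave_specs[: cfg.n_global]:
        if spec.lag_field is not None:
            lag_fields.append(np.asarray(spec.lag_field, float))
        else:
            lag_fields.append(build_lag_field(voxel_indices, spec.origin, spec.speed,
                                              max_lag=cfg.max_lag))
    if cfg.magnitude_fields is not None:
        magnitude_fields = [np.asarray(m, float) for m in cfg.magnitude_fields]
    else:
        magnitude_fields = [
            attenuating_magnitude(voxel_indices,
                                  wave_specs[g].origin if wave_specs[g].origin is not None
                                  else voxel_indices.mean(axis=0),
                                  cfg.shape, rng_geom)
            for g in range(cfg.n_global)
        ]

    # --- local network structure
    network_masks = cfg.network_masks
    if network_masks is None:
        network_masks = _default_network_masks(cfg, voxel_indices)
    network_masks = [np.asarray(m, bool) for m in network_masks[: cfg.n_local]]
    if cfg.local_magnitudes is not None:
        local_magnitudes = [np.asarray(m, float) for m in cfg.local_magnitudes]
    else:
        local_magnitudes = [
            _smooth_positive_field(cfg.shape, voxel_indices, rng_geom,
                                   base=cfg.local_global_ratio,
                                   spread=0.3 * cfg.local_global_ratio)
            for _ in range(cfg.n_local)
        ]

    # --- sources, generated per run and concatenated
    n_comp = cfg.n_global + cfg.n_local
    src_rng = default_rng(seeds[1])
    sources = np.zeros((n_comp, T))
    for c in range(n_comp):
        for r in range(n_runs):
            sources[c, r * T_run:(r + 1) * T_run] = generate_band_limited_source(
                T_run, cfg.tr, cfg.band, rng=src_rng)

    # --- assemble
    data = np.zeros((n_vox, T))
    for g in range(cfg.n_global):
        lag_samples = lag_fields[g] / cfg.tr
        for r in range(n_runs):
            seg = sources[g, r * T_run:(r + 1) * T_run]
            for v in range(n_vox):
                data[v, r * T_run:(r + 1) * T_run] += (
                    magnitude_fields[g][v] * sinc_shift(seg, lag_samples[v])
                )
    for l in range(cfg.n_local):
        s = sources[cfg.n_global + l]
        m = network_masks[l]
        data[m] += local_magnitudes[l][m][:, None] * s[None, :]

    noise = np.zeros((n_vox, T))
    if cfg.noise_sd > 0:
        noise_rng = default_rng(seeds[2])
        pcfg = PreprocessConfig(band=cfg.band, detrend=False)
        for r in range(n_runs):
            white = noise_rng.standard_normal((n_vox, T_run))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                filt = preprocess_run(white, cfg.tr, pcfg)
            filt /= filt.std(axis=1, keepdims=True)
            noise[:, r * T_run:(r + 1) * T_run] = cfg.noise_sd * filt
        data = data + noise

    run_bounds = [(r * T_run, (r + 1) * T_run) for r in range(n_runs)]
    dataset = Dataset(data=data, tr=cfg.tr, run_bounds=run_bounds,
                      shape=cfg.shape, voxel_indices=voxel_indices)
    truth = GroundTruth(
        sources=sources,
        lag_fields=lag_fields,
        magnitude_fields=magnitude_fields,
        network_masks=network_masks,
        local_magnitudes=local_magnitudes,
        labels=["global"] * cfg.n_global + ["local"] * cfg.n_local,
        noise=noise,
        config=cfg,
    )
    templates = make_template_set(magnitude_fields, network_masks, local_magnitudes)
    rois = make_roi_set(cfg, voxel_indices, network_masks)
    return dataset, truth, templates, rois
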