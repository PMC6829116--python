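"""End-to-end driver: dataset -> labelled components -> decomposition -> FC.

Thin orchestration of the module stages for a dataset with matching templates
and ROIs; used by the analysis scripts and the recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ComponentLabel, classify_component, template_correlations
from .connstats import FCMatrix, compare_matrices, correlation_matrix, roi_mean_timeseries
from .decompose import GlobalLocalDecomposition, global_local_decompose
from .lagmap import DEFAULT_MAX_LAG_S, LagMap, MagnitudeMap, map_component
from .preprocess import PreprocessConfig, preprocess_dataset
from .reduction import NodeTimeSeries, dual_regression_stage1, spatial_ica
from .tica import StabilityReport, select_model_order
from .types import Dataset, ROISet, TemplateSet


@dataclass
class PipelineConfig:
    band: tuple[float, float] = (0.01, 0.1)
    spatial_k: int = 16           # parcellation order ~2x the expected number of
                                  # temporal components, mirroring the ratio of
                                  # spatial to temporal ICs in group analyses
    l_range: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    icasso_repeats: int = 10
    max_lag: float = DEFAULT_MAX_LAG_S
    preprocess: bool = True
    data_driven_wb_template: bool = True  # correlation map of the whole-brain mean
    seed: int = 0


@dataclass
class PipelineResult:
    dataset: Dataset
    nodes: NodeTimeSeries
    stability: StabilityReport
    components: np.ndarray                  # (n, T) reproducible centrotypes
    lag_maps: list[LagMap] = field(default_factory=list)
    magnitude_maps: list[MagnitudeMap] = field(default_factory=list)
    labels: list[ComponentLabel] = field(default_factory=list)
    decomposition: GlobalLocalDecomposition | None = None

    @property
    def global_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l.label == "global"]


def build_whole_brain_template(dataset: Dataset,
                               gm_probability: np.ndarray | None = None,
                               gm_threshold: float = 0.10,
                               max_lag: float = DEFAULT_MAX_LAG_S) -> np.ndarray:
    """Whole-brain signal template: the correlation (magnitude) map of the
    gray-matter mean signal against every voxel, at each voxel's best lag.

    This is the reference map a globally distributed component should
    resemble; because it is itself a correlation map, it shares the variance
    structure of component magnitude maps, which a raw amplitude template
    does not.
    """
    from .preprocess import whole_brain_signal
    gm = gm_probability if gm_probability is not None else np.ones(dataset.n_voxels)
    wbs = whole_brain_signal(dataset, gm, gm_threshold)
    wbs = (wbs - wbs.mean()) / wbs.std()
    _, mag = map_component(dataset, wbs, max_lag=max_lag)
    return mag.r_full


def run_pipeline(dataset: Dataset, templates: TemplateSet,
                 config: PipelineConfig | None = None,
                 decompose: bool = True) -> PipelineResult:
    config = config or PipelineConfig()
    work = dataset
    if config.preprocess:
        work = preprocess_dataset(dataset, PreprocessConfig(band=config.band))
    if config.data_driven_wb_template:
        tpls = dict(templates.templates)
        tpls[templates.whole_brain] = build_whole_brain_template(
            work, max_lag=config.max_lag)
        templates = TemplateSet(templates=tpls, whole_brain=templates.whole_brain,
                                mask=templates.mask)
    sica = spatial_ica(work, k=config.spatial_k, seed=config.seed)
    nodes = dual_regression_stage1(work, sica.retained_maps())
    stability = select_model_order(nodes, config.l_range,
                                   n_repeats=config.icasso_repeats,
                                   seed=config.seed, band_low=config.band[0])
    components = stability.components
    lag_maps, mag_maps, labels = [], [], []
    for i, comp in enumerate(components):
        lm, mm = map_component(work, comp, max_lag=config.max_lag)
        lag_maps.append(lm)
        mag_maps.append(mm)
        scores = template_correlations(mm, templates)
        labels.append(classify_component(scores, templates.whole_brain, component=i))
    result = PipelineResult(dataset=work, nodes=nodes, stability=stability,
                            components=components, lag_maps=lag_maps,
                            magnitude_maps=mag_maps, labels=labels)
    if decompose and components.size:
        gi = result.global_indices
        result.decomposition = global_local_decompose(
            work, components[gi] if gi else np.empty((0, work.n_timepoints)),
            [lag_maps[i] for i in gi])
    return result


def mixing_for_components(nodes: NodeTimeSeries, components: np.ndarray) -> np.ndarray:
    """Least-squares mixing matrix (nodes x components) for centrotype
    components, which do not carry a mixing matrix of their own."""
    comps = np.atleast_2d(components)
    coef, *_ = np.linalg.lstsq(comps.T, nodes.series, rcond=None)  # (L, K')
    return coef.T


def match_components_to_planted(components: np.ndarray, sources: np.ndarray,
                                tr: float, max_lag: float = DEFAULT_MAX_LAG_S) -> list[tuple[int, float]]:
    """Match each recovered component to the planted source it most resembles.

    Similarity is the maximum absolute lagged correlation within the analysis
    window (a traveling-wave component may be recovered at any phase along
    the wave, so zero-lag correlation alone under-matches genuine wave
    fragments). Returns per component (best source index, best |r|).
    """
    from .lagmap import lagged_correlation
    M = int(round(max_lag / tr))
    out = []
    for comp in np.atleast_2d(components):
        best = (0, -1.0)
        for j, s in enumerate(np.atleast_2d(sources)):
            _, rs = lagged_correlation(comp, s, M)
            score = float(np.max(np.abs(rs)))
            if score > best[1]:
                best = (j, score)
        out.append(best)
    return out


def fc_matrices_per_run(signal: np.ndarray, dataset: Dataset, rois: ROISet) -> list[FCMatrix]:
    """ROI correlation matrix of a voxel x time signal, one per run."""
    series, labels = roi_mean_timeseries(signal, rois)
    return [correlation_matrix(series[:, a:b], labels) for a, b in dataset.run_bounds]


def component_contrast(decomp: GlobalLocalDecomposition, dataset: Dataset,
                       rois: ROISet, n_comparisons: int = 1):
    """Compare FC(global) and FC(local) against FC(total), run-wise.

    Returns (comparison_global, comparison_local).
    """
    fc_total = [m.r for m in fc_matrices_per_run(dataset.data, dataset, rois)]
    fc_glob = [m.r for m in fc_matrices_per_run(decomp.global_, dataset, rois)]
    fc_loc = [m.r for m in fc_matrices_per_run(decomp.local, dataset, rois)]
    cmp_g = compare_matrices(fc_glob, fc_total, n_comparisons)
    cmp_l = compare_matrices(fc_loc, fc_total, n_comparisons)
    return cmp_g, cmp_l
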