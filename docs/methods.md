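# Methods

## Signal model

The generator and the analysis share one model of band-limited (0.01–0.1 Hz)
resting-state activity over a masked 3-D grid:

    data(v, t) = Σ_g mag_g(v) · s_g(t − lag_g(v))          (global waves)
               + Σ_l mask_l(v) · mag_l(v) · s_l(t)         (local sources)
               + noise_sd · ε(v, t)                        (band-passed noise)

Each global wave is a single unit-variance source reaching voxel v with a
per-voxel delay `lag_g(v)` (seconds) and amplitude `mag_g(v)`; local sources
have no lag structure and live on network masks. The sign convention,
adopted once and used everywhere, is that a positive lag means the voxel's
signal arrives later than the source. All fractional delays — in the
generator, the lag mapper, the decomposition, and the reconstructions — go
through one shared Hann-windowed sinc interpolator (radius 32 samples;
integer delays reproduce index shifting exactly), so generator and
estimator cannot diverge in convention.

### Sources

Sources are built by amplitude-modulating a band-limited Gaussian carrier
with a slow non-negative envelope, then projecting back onto the band
(hard rFFT projection) and standardizing. The modulation depth (default
2/3) sets the burstiness: bursty sources are super-Gaussian, which is the
identifiability assumption of temporal ICA. The default gives mild,
physiologically plausible excess kurtosis (a few units); the node-level ICA
test bed (`make_node_fixture`) uses depth 0.9, the strongly non-Gaussian
regime in which ICA recovery guarantees are meaningful. Sources are
generated independently per run (runs are separate acquisitions).

### Wave geometry and magnitudes

Default lag fields radiate from an origin at constant speed
(lag = grid distance / speed; origins and speeds chosen so planted lags
stay within the ±6.3 s analysis window). Magnitude fields attenuate
smoothly with distance from the wave's origin (floor 0.35 of the origin
amplitude, attenuation length 12 cells, times a mild smooth modulation).
This reproduces two features of reported global waves: distinct (partially
overlapping) spatial territories per wave, and a negative correlation
between a wave's magnitude and its lag (activity attenuating along the
propagation path). The waves remain broad — every voxel keeps a
substantial fraction of the origin amplitude — because spatially broad
magnitude is the premise that makes whole-brain-template classification
meaningful. Wave origins are deliberately placed away from the default
network-blob centres; a wave whose origin coincides with a network
territory is genuinely ambiguous under template classification.

### Noise

White Gaussian noise is band-passed with the analysis filter and rescaled
per voxel, so the band-pass stage cannot remove it. Band-limited noise at
desk scale has few effective degrees of freedom (≈ 2·bandwidth·duration ≈
78 per 600-timepoint run), which drives several of the finite-size effects
discussed under Limitations.

## Pipeline choices

- **Filtering** is zero-phase (4th-order Butterworth, forward–backward,
  applied per run, never across run seams) because voxel-wise lag is the
  scientific object: any filter phase would bias t′. Detrending is per run
  (runs have independent drifts). Only the band is a scientific parameter;
  the filter family is this package's declared default.
- **Spatial ICA** (scikit-learn FastICA over voxels) is a parcellation
  device only. The automatic order rule (PCA explained variance ≥ 99%) is
  appropriate for near-low-rank data; on noisy data the variance spread of
  voxel-wise noise makes any variance-threshold rule degenerate, so the
  pipeline driver passes an explicit order (default 16, about twice the
  expected number of temporal components — the ratio seen in group
  analyses of this design). Artifact exclusion is an explicit index list.
- **Dual regression (stage 1)** regresses each volume on all retained maps
  jointly; node series are variance-normalized (FastICA assumes comparable
  scales). Stage 2 is not needed by this pipeline.
- **Temporal ICA** is implemented directly (tanh contrast, symmetric
  decorrelation) with the whitening dimension decoupled from the number of
  extracted components L: whitening keeps the full numerical rank of the
  node space and L orthonormal unmixing rows are estimated there. This is
  essential for stability selection — when L exceeds the number of genuine
  sources, surplus components must be free to wander in the residual
  subspace across restarts/bootstraps so that their clusters score low Iq.
  Whitening to exactly L dimensions would pin the surplus component to the
  deterministic orthogonal complement of the sources and make it
  spuriously reproducible (measured Iq ≈ 0.93 for a pure noise direction).
- **Stability selection** pools estimates from repeats that each draw a
  moving-block bootstrap of timepoints (block length = one period of the
  lower band edge, blocks drawn within runs — i.i.d. resampling of smooth
  series produces degenerate estimates) and a fresh random initialization.
  Similarity is |Pearson r| between estimate time courses evaluated on the
  original series; clustering is average-linkage on 1 − similarity cut at
  L clusters; Iq is the off-diagonal intra-cluster mean similarity minus
  the mean similarity to non-members (singleton clusters get intra = 1);
  the representative is the centrotype (member with maximal similarity sum
  to its cluster). The order maximizing the count of clusters with
  Iq > 0.5 wins; ties go to the smaller order.
- **Lag mapping** scans integer lags within ±9 TR using overlap-only
  Pearson correlation (zero padding shrinks r at large lags and biases the
  argmax toward 0), restricts the discrete peak to positive correlations,
  and refines it with the parabola through the peak and its two
  neighbours. Voxels whose peak sits on the window edge are invalid for
  lag analyses (refinement needs both neighbours; clamping would bias path
  maps). Maps are computed per run and averaged over the runs in which the
  voxel was valid. For template matching a complete magnitude map is also
  produced (`r_full`): edge-peak voxels carry their discrete best positive
  r and no-positive-peak voxels carry 0 — a spatially confined component
  needs exactly this low-magnitude contrast outside its territory.
- **Classification** correlates the magnitude map with every template over
  the mask; *global* requires the whole-brain score to strictly beat every
  network score (ties are conservatively local). The whole-brain template
  is itself a correlation map — the magnitude map of the gray-matter mean
  signal computed on the data — because Pearson matching of a correlation
  map against a raw amplitude field is dominated by unrelated fluctuation
  structure.
- **Decomposition** runs per voxel and per run with an intercept; the
  intercept belongs to the local component ("the rest of the signal").
  Invalid-lag components drop out of that voxel's design; shifted
  regressors that are collinear (condition number > 1e8) are dropped later
  IC first, with a counted warning. The lag-only reconstruction weights
  every voxel's copy of component i by the RMS of mixing column i.
- **Connectivity comparison** vectorizes the off-diagonal upper triangle,
  correlates run-wise, Fisher-Z transforms, and applies a two-tailed
  one-sample t-test over runs; the Bonferroni family size is the declared
  number of planned comparisons (3 by default: global, local, and lag-only
  against total FC). The lag matrix uses absolute lag differences — the
  signed difference is incoherent with uniformly negative FC–lag
  correlations. ROIs with under 50% valid lag voxels are dropped.
- **Smoothness / resels**: fields are standardized over the mask; the
  variance of forward spatial differences gives the lag-one spatial
  autocorrelation, from which a Gaussian-ACF FWHM is solved per axis
  (this removes the finite-difference bias of the naive derivative
  estimator; near-white fields fall back to the derivative formula).
  resels = mask voxels / Π FWHM; a map–map correlation is tested with
  effective dof = resels − 2.

## Default study configuration and problem sizes

The default synthetic configuration is a 20×20×6 grid masked to ~1,800
voxels, two runs of 600 timepoints at TR 0.72 s — the acquisition
parameters of the motivating data at roughly 1/20 scale in space and time —
with two global waves, four local networks, and noise sd 0.5 (sources have
unit variance). The global:local amplitude ratio is a config parameter
(default 1) because it is an empirical unknown. The temporal-ICA test bed
uses 5 sources × 20 nodes × 7,200 timepoints: temporal ICA is the one
stage whose behaviour changes qualitatively with the number of timepoints,
and the longer series is the regime the method assumes. Smoothness
estimation is validated on 64³ fields. These sizes keep the full test
suite and the acceptance script in the minutes range on one CPU.

## What the generator does and does not emulate

It emulates: band-limited bursty sources, voxel-wise propagation delays
with attenuation, network-confined coactivation, spatially unstructured
band-limited noise, run structure. It does not emulate: hemodynamic
convolution, head motion, vascular territories (an optional confound lag
field would stand in for perfusion lag), spatial noise correlations,
non-stationary or state-dependent propagation. Passing recovery tests here
therefore demonstrates the estimators' correctness under the stated model,
not robustness to physiological artifacts.

## Known limitations (desk-scale finite-size effects)

- **Lag interference.** With two overlapping waves of comparable amplitude
  and only ~78 effective samples per run, the sample cross-correlation
  between the two sources (sd ≈ 0.11) tilts each wave's correlation peak
  by ≈ 0.19·(m_other/m_self) seconds after two-run averaging. This is a
  property of the best-positive-fit objective itself — a brute-force
  maximizer shows the same deviation — and it scales as T^(−1/2): at the
  motivating study's 120,000 timepoints it is ~0.02 s, at T = 1,200 the
  median absolute lag error under the default two-wave configuration is
  ~0.17 s. Single-wave accuracy at the same scale is ~0.05 s median.
- **Stability threshold at small T.** Band-limited noise realizations
  contain moderately re-findable non-Gaussian directions; at T = 1,200 a
  minority of "reproducible" (Iq > 0.5) clusters are such noise
  components, and their global/local label is essentially random. This
  caps end-to-end label accuracy at desk scale (measured ~0.8) even when
  every genuinely recovered component is labelled correctly.
- **Two runs** give the run-wise t-test a single degree of freedom; the
  comparison machinery is exercised, but desk-scale p-values are weak by
  construction.
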