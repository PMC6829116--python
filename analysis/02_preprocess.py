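"""Detrend and band-pass each run (0.01-0.1 Hz, zero-phase), then extract the
whole-brain mean signal that later serves as the global reference.

Writes results/preprocessing_summary.json.
"""

import numpy as np

from _common import SEED, get_preprocessed, get_simulation, save_json
from lagwave import whole_brain_signal

dataset, truth, templates, rois = get_simulation()
filtered = get_preprocessed(dataset)

wbs = whole_brain_signal(filtered, np.ones(filtered.n_voxels), 0.10)
power_kept = float((filtered.data ** 2).sum() / (dataset.data ** 2).sum())

summary = {
    "seed": SEED,
    "band_hz": [0.01, 0.1],
    "variance_fraction_kept": power_kept,
    "whole_brain_signal_sd": float(wbs.std()),
    "runs_filtered_independently": dataset.n_runs,
}
path = save_json("preprocessing_summary.json", summary)
print(f"Band-pass kept {power_kept:.1%} of the raw variance (the generator "
      "already works in-band; the filter mainly removes the small "
      "out-of-band leakage).")
print(f"Whole-brain mean signal sd: {wbs.std():.3f} -> {path}")
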