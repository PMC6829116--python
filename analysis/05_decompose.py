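"""Split every voxel's signal into the global component (regression on the
lag-shifted global ICs) and the local residual; report the relative magnitude
of the local activity.

Writes global/local volumes (scratch/) and results/decomposition_summary.json.
"""

import numpy as np

from _common import SCRATCH, SEED, get_pipeline, get_simulation, save_json
from lagwave import lag_only_reconstruct

dataset, truth, templates, rois = get_simulation()
result = get_pipeline(dataset, templates)  # pipeline band-passes internally
work = result.dataset

gi = result.global_indices
dec = result.decomposition
np.savez(SCRATCH / "decomposition.npz", global_=dec.global_, local=dec.local)

summary = {
    "seed": SEED,
    "n_global_ics_used": len(gi),
    "relative_local_magnitude": dec.relative_local_magnitude,
    "rms_global": float(np.sqrt((dec.global_ ** 2).mean())),
    "rms_local": float(np.sqrt((dec.local ** 2).mean())),
    "identity_max_abs_error": float(np.abs(dec.global_ + dec.local - work.data).max()),
}
if gi:
    from lagwave.pipeline import mixing_for_components
    mixing = mixing_for_components(result.nodes, result.components)[:, gi]
    rec = lag_only_reconstruct(result.components[gi],
                               [result.lag_maps[i] for i in gi],
                               mixing,
                               run_bounds=work.run_bounds, tr=work.tr)
    np.savez(SCRATCH / "lag_only.npz", series=rec.series, valid=rec.valid)
    summary["lag_only_valid_fraction"] = float(rec.valid.mean())
path = save_json("decomposition_summary.json", summary)
print(f"{len(gi)} ICs classified global were regressed out voxel-wise.")
print(f"Relative local magnitude RMS(local)/RMS(total) = "
      f"{dec.relative_local_magnitude:.3f} "
      "(the analogous statistic on real resting-state data is ~0.70).")
print(f"global + local reproduces the input to "
      f"{summary['identity_max_abs_error']:.1e} -> {path}")
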