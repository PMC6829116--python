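"""Shared state for the numbered analysis scripts.

Each stage computes from the stage before it and caches interim arrays under
scratch/ (binary scratch space); tables and summaries land in results/.
All stages are deterministic given SEED.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 0

SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(parents=True, exist_ok=True)


def save_json(name: str, obj) -> Path:
    path = RESULTS / name
    path.write_text(json.dumps(obj, indent=2, default=float))
    return path


def get_simulation():
    from lagwave import SimulationConfig, simulate_dataset
    return simulate_dataset(SimulationConfig(seed=SEED))


def get_preprocessed(dataset):
    from lagwave import PreprocessConfig, preprocess_dataset
    return preprocess_dataset(dataset, PreprocessConfig())


def get_pipeline(dataset, templates):
    from lagwave import PipelineConfig, run_pipeline
    return run_pipeline(dataset, templates,
                        PipelineConfig(seed=SEED, icasso_repeats=20))
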