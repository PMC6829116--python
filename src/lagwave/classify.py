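"""Global-vs-local labelling of components by template matching.

A component's magnitude map is correlated with every template in the set
(N network templates + one whole-brain map) over a common mask; it is labelled
*global* only when the whole-brain template's correlation strictly exceeds
every network template's (an exact tie stays local — the conservative read of
"more similar").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lagmap import MagnitudeMap
from .types import TemplateSet


@dataclass
class ComponentLabel:
    component: int | str
    label: str                 # 'global' | 'local'
    scores: dict[str, float]
    best_template: str


def template_correlations(magnitude: MagnitudeMap | np.ndarray,
                          templates: TemplateSet,
                          mask: np.ndarray | None = None) -> dict[str, float]:
    """Pearson r of the magnitude map with each template over the mask.

    Invalid (NaN) map voxels are excluded pairwise. A map that is constant
    over the mask has no defined correlation and is rejected.
    """
    if isinstance(magnitude, MagnitudeMap):
        values = magnitude.r_full if magnitude.r_full is not None else magnitude.r
    else:
        values = np.asarray(magnitude, float)
    mask = templates.mask if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("template-matching mask is empty")
    scores: dict[str, float] = {}
    for name, tpl in templates.templates.items():
        tpl = np.asarray(tpl, float)
        sel = mask & np.isfinite(values) & np.isfinite(tpl)
        x = values[sel]
        y = tpl[sel]
        if x.size < 3 or np.ptp(x) == 0:
            raise ValueError("magnitude map is constant (or empty) over the mask; "
                             "correlation undefined")
        if np.ptp(y) == 0:
            scores[name] = np.nan
            continue
        scores[name] = float(np.corrcoef(x, y)[0, 1])
    return scores


def classify_component(scores: dict[str, float], whole_brain: str = "whole_brain",
                       component: int | str = 0) -> ComponentLabel:
    """Label from template scores: global iff the whole-brain score strictly
    beats every network score."""
    if whole_brain not in scores:
        raise ValueError(f"scores must contain the whole-brain entry {whole_brain!r}")
    wb = scores[whole_brain]
    network = {k: v for k, v in scores.items() if k != whole_brain}
    finite = {k: v for k, v in network.items() if np.isfinite(v)}
    best_net = max(finite, key=finite.get) if finite else None
    is_global = best_net is None or wb > finite[best_net]
    best = whole_brain if is_global else best_net
    return ComponentLabel(component=component,
                          label="global" if is_global else "local",
                          scores=dict(scores), best_template=best)
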