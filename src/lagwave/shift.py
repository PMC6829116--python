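"""Band-limited fractional-delay shifting.

A single sinc-interpolation routine is shared by the synthetic generator and
every analysis stage (lag mapping, decomposition, reconstruction), so the two
sides cannot diverge in shift convention.

Convention (package-wide): a POSITIVE delay ``delta`` means the output is the
input arriving LATER, i.e. ``y[n] ~= x[n - delta]``.
"""

from __future__ import annotations

import numpy as np

DEFAULT_RADIUS = 32
"""Half-width of the Hann-windowed sinc kernel, in samples."""


def _fractional_kernel(frac: float, radius: int) -> np.ndarray:
    """Windowed-sinc kernel sampled at integer offsets minus ``frac``.

    At frac == 0 the kernel is an exact unit impulse, so integer delays
    reproduce plain index shifting.
    """
    m = np.arange(-radius, radius + 2)  # one extra tap for frac in (0, 1)
    u = m - frac
    width = radius + 1
    window = np.where(np.abs(u) < width, np.cos(np.pi * u / (2 * width)) ** 2, 0.0)
    return np.sinc(u) * window


def sinc_shift(x: np.ndarray, delta: float, radius: int = DEFAULT_RADIUS) -> np.ndarray:
    """Delay a series by ``delta`` samples using windowed-sinc interpolation.

    Parameters
    ----------
    x : 1-D array
        Input series.
    delta : float
        Delay in samples; positive delays the series (``y[n] = x[n - delta]``),
        fractional values are interpolated band-limitedly.
    radius : int
        Kernel half-width in samples. Samples outside the series are treated
        as zero, so roughly ``radius`` samples at each edge are attenuated.

    Returns
    -------
    1-D array of the same length as ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("sinc_shift expects a 1-D series")
    n = x.size
    if abs(delta) >= n / 4:
        raise ValueError(
            f"|delta| = {abs(delta):.3g} samples exceeds a quarter of the "
            f"series length ({n} samples)"
        )
    i = int(np.floor(delta))
    frac = float(delta - i)
    kernel = _fractional_kernel(frac, radius)
    full = np.convolve(x, kernel, mode="full")
    # y[n] = full[n + radius - i]: the aligned output starts at radius - i.
    start = radius - i
    out = np.zeros(n)
    lo = max(0, start)
    hi = min(full.size, start + n)
    if hi > lo:
        out[lo - start : hi - start] = full[lo:hi]
    return out


def sinc_shift_many(x: np.ndarray, deltas: np.ndarray, radius: int = DEFAULT_RADIUS) -> np.ndarray:
    """Shift one series by many delays; returns ``(len(deltas), len(x))``."""
    return np.stack([sinc_shift(x, float(d), radius=radius) for d in np.asarray(deltas, float)])
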