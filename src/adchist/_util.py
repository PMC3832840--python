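"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``window`` must be a positive odd integer so the average stays centered.
    Edge bins are averaged over however much of the window fits, which keeps
    the output the same length as the input and avoids zero-padding bias.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("moving_average expects a 1-D array")
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1:
        return v.copy()
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den
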