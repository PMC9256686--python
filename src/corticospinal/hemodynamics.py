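"""Canonical hemodynamic response function and task-drive construction.

The BOLD response to a neural event is modelled with the canonical
double-gamma HRF: a positive gamma density peaking around 6 s minus a later
undershoot gamma (16 s) scaled by 1/6, truncated at 32 s.  Convolving the
unit-sum HRF with a 0/1 task boxcar yields a "clean drive" whose plateau is
close to 1, so region amplitudes are expressed in the same units as the
boxcar height.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

from .design import BlockDesign


def double_gamma_hrf(
    tr_seconds: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Double-gamma HRF sampled at the TR, normalised to unit sum.

    Shape parameters follow the common convention (gamma shapes equal to the
    nominal peak/undershoot delays in seconds, unit dispersion).
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0.0, duration + 0.5 * tr_seconds, tr_seconds)
    h = _st.gamma.pdf(t, peak_delay) - _st.gamma.pdf(t, undershoot_delay) / peak_undershoot_ratio
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate HRF parameters")
    return h / s


def convolve_hrf(x: np.ndarray, tr_seconds: float, **hrf_kwargs) -> np.ndarray:
    """Convolve a TR-sampled regressor with the canonical HRF (causal, trimmed)."""
    x = np.asarray(x, dtype=float)
    h = double_gamma_hrf(tr_seconds, **hrf_kwargs)
    return np.convolve(x, h)[: x.size]


def hand_drive(design: BlockDesign, hand: str, **hrf_kwargs) -> np.ndarray:
    """HRF-convolved boxcar for one hand's task blocks — the clean neural drive."""
    return convolve_hrf(design.boxcar(hand), design.tr_seconds, **hrf_kwargs)
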