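"""Canonical haemodynamic response function and event-regressor construction.

The double-gamma HRF used throughout the package peaks at 6 s with an
undershoot at 16 s and a peak/undershoot ratio of 6, and is normalised to a
unit integral so that convolving a long boxcar yields a plateau of 1.  A
condition regressor built from events therefore carries amplitude directly in
the units of the event effect (percent signal change here).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

HRF_LENGTH_S = 32.0
_OVERSAMPLE_DT = 0.1


def double_gamma_hrf(dt: float, length_s: float = HRF_LENGTH_S) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a grid of spacing ``dt`` seconds.

    Normalised so that ``hrf.sum() * dt == 1``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t = np.arange(0.0, length_s, dt)
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    area = h.sum() * dt
    return h / area


def boxcar(onsets, durations, n_volumes: int, tr: float) -> np.ndarray:
    """Unconvolved 0/1 condition regressor sampled at volume times ``i * tr``.

    A volume belongs to an event iff its acquisition time lies in the
    half-open interval [onset, onset + duration).
    """
    t = np.arange(n_volumes) * tr
    out = np.zeros(n_volumes)
    for onset, duration in zip(onsets, durations):
        out[(t >= onset) & (t < onset + duration)] = 1.0
    return out


def convolved_regressor(onsets, durations, n_volumes: int, tr: float) -> np.ndarray:
    """HRF-convolved condition regressor sampled at volume times.

    The event train is built on an oversampled grid (0.1 s), convolved with
    the unit-integral HRF, and decimated at the volume times; a sustained
    block converges to a plateau of 1.
    """
    dt = _OVERSAMPLE_DT
    total_s = n_volumes * tr + HRF_LENGTH_S
    n_fine = int(np.ceil(total_s / dt))
    fine = np.zeros(n_fine)
    tf = np.arange(n_fine) * dt
    for onset, duration in zip(onsets, durations):
        fine[(tf >= onset) & (tf < onset + duration)] = 1.0
    hrf = double_gamma_hrf(dt)
    conv = np.convolve(fine, hrf)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[vol_idx]
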