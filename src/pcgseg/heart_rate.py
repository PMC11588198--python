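"""Heart-rate estimation from the frame classifier's posteriors.

The per-frame probability of *not* being in diastole is a clean, periodic
proxy for the heart-sound envelope: it pulses once per cycle regardless of
murmur content or broadband noise.  Its autocorrelation therefore shows a
clear peak at the cycle period, which is searched over 30-180 bpm (the upper
bound accommodates paediatric rates).  The estimated period scales the
duration means of the semi-Markov segmentation models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FRAME_STEP

#: default physiological search range, beats per minute
HR_RANGE_BPM = (30.0, 180.0)

#: reject a candidate period when doubling the lag raises the autocorrelation
#: by more than this factor (half-period ambiguity: S1<->S2 spacing)
HALF_PERIOD_TOL = 1.05


@dataclass
class HeartRateEstimate:
    bpm: float
    period_s: float
    peak_lag: int  # frames
    search_range: tuple[float, float] = HR_RANGE_BPM


def not_diastole_series(probs: np.ndarray) -> np.ndarray:
    """1 - P(diastole): summed posterior of S1, systole, S2 and murmur."""
    from .io_formats import STATE_ORDER

    return 1.0 - probs[:, STATE_ORDER.index("diastole")]


def autocorrelation(series: np.ndarray) -> np.ndarray:
    """Biased autocorrelation of the mean-removed series, normalised to 1 at lag 0."""
    x = np.asarray(series, dtype=np.float64)
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom == 0.0:
        raise ValueError("constant series: no periodicity to estimate")
    full = np.correlate(x, x, mode="full")
    ac = full[len(x) - 1:] / denom
    return ac


def estimate_heart_rate(
    series: np.ndarray,
    frame_step: float = FRAME_STEP,
    hr_range: tuple[float, float] = HR_RANGE_BPM,
) -> HeartRateEstimate:
    """Locate the autocorrelation peak whose lag lies in the bpm search window.

    A peak is a local maximum strictly greater than both neighbours; ties go
    to the smaller lag (higher bpm).  A candidate whose doubled lag carries a
    clearly higher autocorrelation is rejected as a half-period alias.  The
    winning integer-lag peak is refined by parabolic interpolation of the
    autocorrelation around it (the true period rarely lands on the frame
    grid), and the result is clamped into the bpm window.  Raises
    ``ValueError`` when the series is shorter than the longest searched lag
    or contains no peak.
    """
    lo_lag = 60.0 / hr_range[1] / frame_step
    hi_lag = 60.0 / hr_range[0] / frame_step
    if len(series) <= int(hi_lag):
        raise ValueError(
            f"insufficient duration for HR estimation: need > {int(hi_lag)} frames, "
            f"got {len(series)}"
        )
    ac = autocorrelation(series)
    # local maxima over the full autocorrelation, allowing peaks whose integer
    # lag sits just outside the window (interpolation may pull them back in)
    lo_i = max(2, int(np.floor(lo_lag)) - 2)
    hi_i = min(len(ac) - 2, int(np.ceil(hi_lag)) + 2)
    lags = np.arange(lo_i, hi_i + 1)
    is_peak = (ac[lags] > ac[lags - 1]) & (ac[lags] > ac[lags + 1])
    peak_lags = lags[is_peak]
    if peak_lags.size == 0:
        raise ValueError("no autocorrelation peak in the search window")
    order = np.argsort(-ac[peak_lags], kind="stable")  # ties -> smaller lag
    candidates = peak_lags[order]
    chosen = candidates[0]
    for lag in candidates:
        dbl = 2 * lag
        if dbl <= hi_i and ac[dbl] > HALF_PERIOD_TOL * ac[lag]:
            continue  # half-period alias; the true cycle is the doubled lag
        chosen = lag
        break
    # parabolic refinement around the integer peak
    y0, y1, y2 = ac[chosen - 1], ac[chosen], ac[chosen + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
    lag_refined = float(np.clip(chosen + offset, lo_lag, hi_lag))
    period = lag_refined * frame_step
    return HeartRateEstimate(bpm=60.0 / period, period_s=period,
                             peak_lag=int(chosen), search_range=hr_range)


def estimate_heart_rate_from_posteriors(probs: np.ndarray, **kw) -> HeartRateEstimate:
    """Convenience wrapper: posterior matrix -> not-diastole series -> estimate."""
    return estimate_heart_rate(not_diastole_series(probs), **kw)
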