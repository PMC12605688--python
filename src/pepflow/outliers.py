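"""B-point outlier detection and correction on beat-to-beat series.

Outliers are detected on the *stationarized* B-point series: the series is
low-pass filtered (fourth-order Butterworth, 0.1 Hz cutoff, zero-phase) on a
uniform beat grid and the filtered trend subtracted, so slow physiological
drift does not mask beat-level outliers. A beat is an outlier when its
stationarized value lies more than three times the (unscaled) median absolute
deviation from the median. Flagged beats are repaired either by linear
interpolation between the nearest clean neighbours or by averaging forward
and backward autoregressive one-step predictions; a dummy corrector passes
the series through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "stationarize",
    "detect_outliers",
    "correct_linear",
    "correct_autoregressive",
    "correct_dummy",
    "correct_b_points",
    "OUTLIER_METHODS",
]

OUTLIER_METHODS = ("none", "linint", "for18-ar")

MIN_BEATS_FOR_FILTER = 8  # filter warm-up; shorter series pass through


def stationarize(values, timestamps_s=None, fs_beat=None):
    """Detrend a beat series by subtracting its 0.1 Hz low-pass component.

    The beat series is treated as uniformly sampled at
    ``fs_beat = 1/mean(RR)`` (derived from ``timestamps_s`` when given,
    default 1 Hz otherwise). Missing beats (NaN) are filled by linear
    interpolation before filtering and restored afterwards.

    Returns ``(detrended, passthrough_flag)``; series with fewer than
    8 valid beats are passed through unchanged with the flag set.
    """
    x = np.asarray(values, dtype=float)
    valid = np.isfinite(x)
    if valid.sum() < MIN_BEATS_FOR_FILTER:
        return x.copy(), True
    if fs_beat is None:
        if timestamps_s is not None:
            ts = np.asarray(timestamps_s, dtype=float)
            if np.any(np.diff(ts) <= 0):
                raise ValueError("timestamps must be strictly increasing")
            fs_beat = 1.0 / float(np.mean(np.diff(ts)))
        else:
            fs_beat = 1.0
    idx = np.arange(x.size)
    filled = x.copy()
    filled[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    sos = sps.butter(4, 0.1, btype="lowpass", fs=fs_beat, output="sos")
    padlen = min(3 * 2 * 4, x.size - 1)
    trend = sps.sosfiltfilt(sos, filled, padlen=padlen)
    detrended = filled - trend
    detrended[~valid] = np.nan
    return detrended, False


def detect_outliers(detrended, atol_ms: float = 1e-6) -> np.ndarray:
    """MAD rule: outlier iff |x - median(x)| > 3 * MAD(x).

    MAD is the raw (unscaled) median absolute deviation. The threshold is
    floored at ``atol_ms`` so that a degenerate series (MAD = 0 or pure
    floating-point ripple after detrending) flags only genuine deviations: a
    constant series yields an empty mask, while a constant series with one
    spike flags exactly the spike. Missing beats are never flagged.
    """
    x = np.asarray(detrended, dtype=float)
    mask = np.zeros(x.size, dtype=bool)
    valid = np.isfinite(x)
    if valid.sum() == 0:
        return mask
    med = float(np.median(x[valid]))
    mad = float(np.median(np.abs(x[valid] - med)))
    mask[valid] = np.abs(x[valid] - med) > max(3.0 * mad, atol_ms)
    return mask


def _interp_fill(x, fill_at, timestamps=None):
    """Linear interpolation at ``fill_at`` from the remaining points; edge
    positions copy the nearest remaining value."""
    t = np.arange(x.size, dtype=float) if timestamps is None else np.asarray(
        timestamps, dtype=float
    )
    keep = np.isfinite(x) & ~fill_at
    out = x.copy()
    out[fill_at] = np.interp(t[fill_at], t[keep], x[keep])
    return out


def correct_linear(values, mask, timestamps_s=None):
    """Replace outliers by linear interpolation between the nearest
    non-outlier neighbours (in beat time); edge outliers copy the nearest
    non-outlier value. If every beat is an outlier the series is passed
    through with a flag: ``(corrected, passthrough_flag)``."""
    x = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != x.size:
        raise ValueError("mask and series lengths differ")
    keep = np.isfinite(x) & ~mask
    if keep.sum() == 0:
        return x.copy(), True
    return _interp_fill(x, mask & np.isfinite(x), timestamps_s), False


def correct_dummy(values, mask=None):
    """Pass-through corrector (the "no correction" scenario)."""
    return np.asarray(values, dtype=float).copy(), False


def _fit_ar_predict(context: np.ndarray, p: int) -> float | None:
    """Least-squares AR(p) fit on ``context`` (time-ordered), one-step-ahead
    prediction past its end. Returns None when the context is too short."""
    p_eff = min(p, context.size // 2)
    if p_eff < 1 or context.size < 2 * p_eff:
        return None
    rows = context.size - p_eff
    design = np.column_stack(
        [context[p_eff - k - 1 : p_eff - k - 1 + rows] for k in range(p_eff)]
    )
    target = context[p_eff:]
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return float(coef @ context[-1 : -p_eff - 1 : -1])


def correct_autoregressive(values, mask, p: int = 4, context: int = 30):
    """Forward/backward AR(p) outlier correction.

    Each outlier is replaced by the mean of a forward AR(p) one-step
    prediction (fit on up to ``context`` preceding non-outlier beats) and a
    backward prediction (fit on the following non-outlier beats, time
    reversed). If only one side has enough context, it is used alone; if
    neither does, the beat falls back to linear interpolation.

    Returns ``(corrected, passthrough_flag)``.
    """
    x = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    keep = np.isfinite(x) & ~mask
    if keep.sum() == 0:
        return x.copy(), True
    out = x.copy()
    linear, _ = correct_linear(x, mask)
    for i in np.nonzero(mask & np.isfinite(x))[0]:
        before = x[:i][keep[:i]][-context:]
        after = x[i + 1 :][keep[i + 1 :]][:context][::-1]
        preds = [
            pred
            for pred in (_fit_ar_predict(before, p), _fit_ar_predict(after, p))
            if pred is not None
        ]
        out[i] = float(np.mean(preds)) if preds else linear[i]
    return out, False


def correct_b_points(
    b_times_ms,
    r_times_ms,
    method: str = "none",
    *,
    interpolate_missing: bool = True,
    ar_order: int = 4,
):
    """Full correction stage for a pipeline's B-point series.

    The per-beat B-point value that is stationarized, screened and corrected
    is the R-anchored offset ``b - r`` in ms (the physiologically stationary
    quantity; absolute B-point times grow by one RR interval per beat, which
    would swamp the 0.1 Hz detrending filter and make edge interpolation
    copy absolute times across beats). Corrected offsets are re-anchored to
    each beat's R-peak on return.

    With ``interpolate_missing`` (default), beats whose B-point detection
    failed are filled by interpolation as well, so the correction stage can
    only reduce the number of invalid PEPs.

    Returns ``(corrected_b_times_ms, outlier_mask)``.
    """
    if method not in OUTLIER_METHODS:
        raise ValueError(f"unknown outlier-correction method: {method!r}")
    b = np.asarray(b_times_ms, dtype=float)
    r = np.asarray(r_times_ms, dtype=float)
    if method == "none":
        return correct_dummy(b)[0], np.zeros(b.size, dtype=bool)
    offsets = b - r
    detr, passthrough = stationarize(offsets, timestamps_s=r / 1000.0)
    mask = detect_outliers(detr) if not passthrough else np.zeros(b.size, dtype=bool)
    fill = mask.copy()
    if interpolate_missing:
        fill |= ~np.isfinite(offsets)
    keep = np.isfinite(offsets) & ~mask
    if keep.sum() < 2:
        return b.copy(), mask
    if method == "linint":
        out = _interp_fill(offsets, fill, timestamps=r)
    else:  # for18-ar
        out, _ = correct_autoregressive(offsets, mask, p=ar_order)
        missing = (~np.isfinite(offsets)) if interpolate_missing else np.zeros(b.size, bool)
        if missing.any():
            out = _interp_fill(out, missing, timestamps=r)
    return out + r, mask
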