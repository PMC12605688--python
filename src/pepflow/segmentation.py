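"""R-peak detection and cardiac-cycle segmentation.

Cycles are anchored on R-peaks: the cycle of beat *i* starts 35% of the
preceding RR interval before its R-peak and ends where the next beat's cycle
starts, so for constant RR consecutive cycles tile the record exactly. The
first detected R-peak yields no cycle (it has no preceding RR interval).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._utils import round_half_away

__all__ = ["detect_r_peaks", "partition_cycles"]


def detect_r_peaks(ecg, fs, method="adaptive_threshold"):
    """Detect R-peaks; returns strictly increasing 0-based sample indices.

    The default detector is a Pan-Tompkins-style derivative + squaring +
    moving-window-integration front end with an adaptive signal/noise
    threshold, followed by refinement to the local maximum of the input ECG.
    ``method`` may also be a callable ``(ecg, fs) -> indices`` so an external
    detector can be injected.

    An empty or flat signal yields an empty array (not an error).
    """
    if callable(method):
        return np.asarray(method(ecg, fs), dtype=np.int64)
    if method != "adaptive_threshold":
        raise ValueError(f"unknown R-peak detection method: {method!r}")

    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < int(0.5 * fs) or np.ptp(ecg) == 0:
        return np.empty(0, dtype=np.int64)

    # QRS-band emphasis -> derivative -> squaring -> moving-window integration
    sos = sps.butter(2, [5.0, min(30.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, ecg)
    d = np.gradient(f) * fs
    e = d * d
    w = max(3, int(round(0.150 * fs)))
    env = np.convolve(e, np.ones(w) / w, mode="same")

    min_dist = int(round(0.25 * fs))  # refractory period (240 bpm ceiling)
    cand, _ = sps.find_peaks(env, distance=min_dist)
    if cand.size == 0:
        return np.empty(0, dtype=np.int64)

    # adaptive signal/noise levels (Pan-Tompkins running estimates)
    spk = float(np.percentile(env[cand], 90))
    npk = float(np.percentile(env[cand], 10))
    accepted = []
    for i in cand:
        thr = npk + 0.25 * (spk - npk)
        if env[i] > thr:
            accepted.append(i)
            spk = 0.125 * env[i] + 0.875 * spk
        else:
            npk = 0.125 * env[i] + 0.875 * npk
    if not accepted:
        return np.empty(0, dtype=np.int64)

    # refine each detection to the local maximum of the raw ECG (+/- 60 ms)
    half = int(round(0.060 * fs))
    peaks = []
    for i in accepted:
        lo, hi = max(0, i - half), min(ecg.size, i + half + 1)
        peaks.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.unique(np.asarray(peaks, dtype=np.int64))
    # drop duplicates that collapsed closer than the refractory period
    keep = [0]
    for j in range(1, peaks.size):
        if peaks[j] - peaks[keep[-1]] >= min_dist:
            keep.append(j)
    return peaks[keep]


def partition_cycles(r_peaks, fs, n_samples=None) -> pd.DataFrame:
    """Partition a record into per-beat cycles from R-peak indices.

    For each R-peak except the first, the cycle is::

        start = r_peak - round(0.35 * RR_prev)     (round half away from zero)
        end   = start + RR_prev

    so the cycle covers exactly one preceding RR interval and, for constant
    RR, ``end_i == start_{i+1}`` (the 35%/65% split of the preceding RR; the
    end border equals ``r + round(0.65*RR_prev)`` except when 0.35*RR falls
    exactly on a half sample). Cycles are clipped to ``[0, n_samples)`` when
    ``n_samples`` is given.

    Returns a DataFrame with columns ``start, r_peak, end, rr_prev`` (samples).
    """
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if r_peaks.size < 2:
        return pd.DataFrame(columns=["start", "r_peak", "end", "rr_prev"], dtype=np.int64)
    if np.any(np.diff(r_peaks) <= 0):
        raise ValueError("r_peaks must be strictly increasing")
    rr = np.diff(r_peaks)
    r = r_peaks[1:]
    start = r - round_half_away(0.35 * rr)
    end = start + rr
    if n_samples is not None:
        start = np.clip(start, 0, n_samples)
        end = np.clip(end, 0, n_samples)
    return pd.DataFrame(
        {"start": start, "r_peak": r, "end": end, "rr_prev": rr}
    ).astype(np.int64)
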