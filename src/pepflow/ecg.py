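"""Q-peak extraction from the ECG.

Three algorithm families are implemented; all return the Q-wave *peak* (the
trough immediately preceding the R-peak), which is more reliably annotated
than the Q-wave onset and is therefore the PEP start point throughout the
package:

* ``van13`` -- fixed offset: Q-peak = R-peak minus a configurable interval t
  (default 40 ms).
* ``for18`` -- threshold rule: the last sample before the R-peak whose
  amplitude lies below -1.2*R/scaling_factor, where R is the ECG amplitude at
  the R-peak and the scaling factor (default 2000) replaces the sampling rate
  of the original formulation so the threshold is rate-independent.
* ``mar04`` -- discrete-wavelet-transform delineation: an a-trous
  quadratic-spline decomposition locates Q-wave evidence before the R-peak;
  the Q-peak is the most prominent ECG local minimum supported by that
  evidence, and the cycle is marked missing when no wavelet evidence of a
  Q deflection exists.

Results carry one row per cycle with the Q-peak sample index (NaN when
missing) and a failure-reason code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import local_minima, ms_to_samples

__all__ = [
    "qpeak_van_lien",
    "qpeak_forouzanfar",
    "qpeak_martinez_dwt",
    "extract_q_peaks",
    "Q_METHODS",
]

# failure reason codes for Q-peak extraction
CLIPPED_TO_START = "ClippedToStart"
NO_SUB_THRESHOLD = "NoSubThreshold"
NEGATIVE_R_AMPLITUDE = "NegativeRAmplitude"
NO_Q_WAVE = "NoQWaveEvidence"
CYCLE_TOO_SHORT = "CycleTooShort"


def _result(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["q_peak", "reason"])
    df["q_peak"] = df["q_peak"].astype(float)
    return df


def qpeak_van_lien(partition: pd.DataFrame, fs: float, t_ms: float = 40.0) -> pd.DataFrame:
    """Q-peak = R-peak - round(t_ms * fs / 1000) for every cycle (never missing).

    If the offset lands before the cycle start it is clipped to the start and
    the cycle flagged (reason ``ClippedToStart``), still returning a value.
    """
    if t_ms < 0:
        raise ValueError("t_ms must be non-negative")
    off = int(ms_to_samples(t_ms, fs))
    rows = []
    for start, r in zip(partition["start"], partition["r_peak"]):
        q = r - off
        if q < start:
            rows.append((float(start), CLIPPED_TO_START))
        else:
            rows.append((float(q), ""))
    return _result(rows)


def qpeak_forouzanfar(
    ecg: np.ndarray, partition: pd.DataFrame, scaling_factor: float = 2000.0
) -> pd.DataFrame:
    """Last sample before the R-peak below the threshold -1.2*R/scaling_factor.

    R is the (filtered) ECG amplitude at the detected R-peak of the cycle.
    A non-positive R amplitude marks the beat degenerate; a cycle with no
    sub-threshold sample is missing with reason ``NoSubThreshold``.
    """
    if scaling_factor <= 0:
        raise ValueError("scaling_factor must be positive")
    ecg = np.asarray(ecg, dtype=float)
    rows = []
    for start, r in zip(partition["start"], partition["r_peak"]):
        r_amp = ecg[r]
        if r_amp <= 0:
            rows.append((np.nan, NEGATIVE_R_AMPLITUDE))
            continue
        thr = -1.2 * r_amp / scaling_factor
        seg = ecg[start:r]
        below = np.nonzero(seg < thr)[0]
        if below.size == 0:
            rows.append((np.nan, NO_SUB_THRESHOLD))
        else:
            rows.append((float(start + below[-1]), ""))
    return _result(rows)


# --- a-trous quadratic-spline wavelet decomposition -------------------------
#
# Detail coefficients W_k(x) behave like the derivative of x smoothed at scale
# 2^k: a negative ECG trough (the Q-wave) produces a negative modulus maximum
# followed by a positive one, with the trough at the zero crossing in between.

_H = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0  # lowpass (quadratic spline)
_G = np.array([2.0, -2.0])                 # highpass (derivative-like)

# Modulus-maxima acceptance threshold: Q-wave evidence in the pre-R window
# must reach this fraction of the QRS modulus maximum at the same scale.
_Q_EVIDENCE_RATIO = 0.05


def _atrous(x: np.ndarray, n_scales: int = 4):
    """Detail coefficients at scales 2^1..2^n, aligned with the input."""
    details = []
    approx = x
    for k in range(n_scales):
        up = 2 ** k
        g = np.zeros((len(_G) - 1) * up + 1)
        g[::up] = _G
        h = np.zeros((len(_H) - 1) * up + 1)
        h[::up] = _H
        w = np.convolve(np.pad(approx, len(g), mode="edge"), g, mode="same")[
            len(g):-len(g)
        ]
        approx = np.convolve(np.pad(approx, len(h), mode="edge"), h, mode="same")[
            len(h):-len(h)
        ]
        details.append(w)
    return details


def qpeak_martinez_dwt(
    ecg: np.ndarray, partition: pd.DataFrame, fs: float, search_ms: float = 80.0
) -> pd.DataFrame:
    """DWT-based Q-peak delineation.

    Per cycle, the detail signal at scale 2^2 is scanned over the window
    [R - search_ms, R): a negative modulus maximum exceeding the scale's QRS
    evidence threshold marks the Q downslope; the Q-peak is the most
    prominent ECG local minimum between that point and the R-peak. Cycles
    with no wavelet evidence of a Q deflection are missing
    (reason ``NoQWaveEvidence``).
    """
    ecg = np.asarray(ecg, dtype=float)
    w2 = _atrous(ecg, n_scales=2)[1]
    win = int(ms_to_samples(search_ms, fs))
    guard = max(2, int(ms_to_samples(4.0, fs)))  # keep clear of the R upstroke
    rows = []
    for start, r in zip(partition["start"], partition["r_peak"]):
        lo = max(int(start), int(r) - win)
        hi = int(r) - guard
        if hi - lo < 3:
            rows.append((np.nan, CYCLE_TOO_SHORT))
            continue
        seg_w = w2[lo:hi]
        # QRS modulus maximum at this scale (within +/- 60 ms of R)
        qlo = max(int(start), int(r) - int(ms_to_samples(60.0, fs)))
        qhi = min(len(w2), int(r) + int(ms_to_samples(60.0, fs)))
        qrs_mod = np.max(np.abs(w2[qlo:qhi]))
        if qrs_mod == 0:
            rows.append((np.nan, NO_Q_WAVE))
            continue
        # negative modulus maxima = downslope of a trough
        neg_mm = [i for i in local_minima(seg_w) if seg_w[i] < -_Q_EVIDENCE_RATIO * qrs_mod]
        if not neg_mm:
            rows.append((np.nan, NO_Q_WAVE))
            continue
        onset = lo + neg_mm[-1]
        seg = ecg[onset : int(r)]
        mins = local_minima(seg)
        if mins.size == 0:
            # trough may sit exactly at the window edge; widen by the guard
            seg = ecg[max(int(start), onset - guard) : int(r)]
            mins = local_minima(seg)
            onset = max(int(start), onset - guard)
            if mins.size == 0:
                rows.append((np.nan, NO_Q_WAVE))
                continue
        q = onset + mins[np.argmin(seg[mins])]  # most prominent (deepest) minimum
        rows.append((float(q), ""))
    return _result(rows)


Q_METHODS = ("mar04", "van13", "for18")


def extract_q_peaks(method: str, ecg, partition, fs, **params) -> pd.DataFrame:
    """Dispatch a Q-peak extraction by method name ('mar04'|'van13'|'for18')."""
    method = method.lower()
    if method == "van13":
        return qpeak_van_lien(partition, fs, t_ms=params.get("t_ms", 40.0))
    if method == "for18":
        return qpeak_forouzanfar(
            ecg, partition, scaling_factor=params.get("scaling_factor", 2000.0)
        )
    if method == "mar04":
        return qpeak_martinez_dwt(ecg, partition, fs)
    raise ValueError(f"unknown Q-peak method: {method!r}")
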