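"""C-point and B-point extraction from the dZ/dt signal.

The C-point is the within-cycle maximum of dZ/dt (dZ/dt_max); when several
candidate peaks exist, the one whose R-C interval is closest to the mean R-C
interval of the three preceding cycles is chosen. The B-point marks aortic
valve opening and ends the PEP; twelve detection rules from the literature
are implemented, spanning extremum/zero-crossing searches on dZ/dt and its
second/third derivatives, fixed regressions on the R-C interval, a
chord-distance rule, a monotone-segment rule, a multi-stage slope rule, and
a weighted-window transform.

Every cycle either yields a B-point sample index strictly before the C-point
or a single failure-reason code:

===========  ====================================================
InvBWindow   invalid/empty B-point search window after clipping
NegPEP       negative PEP (set at pipeline level, not here)
NoC          no C-point detected for the cycle
NoIsoCross   no isoelectric (cycle-mean) crossing before C
NoLocMin     no local minimum in the search window
NoMonIncr    no usable monotonically increasing segment
NoZCross     no zero crossing before C
===========  ====================================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._utils import local_maxima, local_minima, ms_to_samples
from .io import differentiate

__all__ = [
    "detect_c_points",
    "extract_b_points",
    "B_METHODS",
    "bpoint_stern",
    "bpoint_sherwood",
    "bpoint_debski_sd",
    "bpoint_arbol_ic",
    "bpoint_arbol_sd",
    "bpoint_arbol_td",
    "bpoint_lozano",
    "bpoint_drost",
    "bpoint_forouzanfar",
    "bpoint_pale",
    "bpoint_miljkovic",
]

INV_B_WINDOW = "InvBWindow"
NEG_PEP = "NegPEP"
NO_C = "NoC"
NO_ISO_CROSS = "NoIsoCross"
NO_LOC_MIN = "NoLocMin"
NO_MON_INCR = "NoMonIncr"
NO_Z_CROSS = "NoZCross"

REASON_CODES = (
    INV_B_WINDOW, NEG_PEP, NO_C, NO_ISO_CROSS, NO_LOC_MIN, NO_MON_INCR, NO_Z_CROSS,
)


def _result(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["b_point", "reason"])
    df["b_point"] = df["b_point"].astype(float)
    return df


# --------------------------------------------------------------------------
# C-point
# --------------------------------------------------------------------------

def detect_c_points(
    dzdt: np.ndarray,
    partition: pd.DataFrame,
    fs: float,
    prominence_frac: float = 0.05,
) -> pd.DataFrame:
    """Detect the C-point of each cycle.

    Candidate peaks of dZ/dt after the R-peak are found with
    ``scipy.signal.find_peaks`` (prominence >= ``prominence_frac`` of the
    cycle's peak-to-peak range). Among multiple candidates the peak whose R-C
    interval is closest to the mean R-C interval of up to three preceding
    cycles is selected; without history the highest peak wins. A cycle with
    no candidate peak is missing (reason ``NoC``).

    Returns a DataFrame with columns ``c_point`` (float, NaN = missing),
    ``rc_ms`` and ``reason``.
    """
    dzdt = np.asarray(dzdt, dtype=float)
    rows = []
    history: list[float] = []
    for start, r, end in zip(partition["start"], partition["r_peak"], partition["end"]):
        seg = dzdt[int(r) + 1 : int(end)]
        if seg.size < 3 or np.ptp(seg) == 0:
            rows.append((np.nan, np.nan, NO_C))
            continue
        peaks, _ = sps.find_peaks(seg, prominence=prominence_frac * np.ptp(seg))
        if peaks.size == 0:
            rows.append((np.nan, np.nan, NO_C))
            continue
        cand = peaks + int(r) + 1
        rc_cand = (cand - int(r)) * 1000.0 / fs
        if history:
            target = float(np.mean(history[-3:]))
            c = cand[np.argmin(np.abs(rc_cand - target))]
        else:
            c = cand[np.argmax(dzdt[cand])]
        rc = (c - int(r)) * 1000.0 / fs
        history.append(rc)
        rows.append((float(c), rc, ""))
    df = pd.DataFrame(rows, columns=["c_point", "rc_ms", "reason"])
    df["c_point"] = df["c_point"].astype(float)
    return df


def _iter_cycles(partition: pd.DataFrame, cpoints: pd.DataFrame):
    for (_, cyc), (_, cp) in zip(partition.iterrows(), cpoints.iterrows()):
        yield int(cyc["start"]), int(cyc["r_peak"]), int(cyc["end"]), int(cyc["rr_prev"]), cp


# --------------------------------------------------------------------------
# extremum / zero-crossing family
# --------------------------------------------------------------------------

def bpoint_stern(dzdt, partition, cpoints, fs=None) -> pd.DataFrame:
    """Last local minimum of dZ/dt before the C-point (reason ``NoLocMin``)."""
    dzdt = np.asarray(dzdt, dtype=float)
    rows = []
    for start, _r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        mins = local_minima(dzdt[start:c])
        rows.append((float(start + mins[-1]), "") if mins.size else (np.nan, NO_LOC_MIN))
    return _result(rows)


def bpoint_sherwood(dzdt, partition, cpoints, fs=None) -> pd.DataFrame:
    """Last negative-to-nonnegative zero crossing of dZ/dt before the C-point.

    B is the first nonnegative sample of the crossing (sample-level, no
    sub-sample interpolation); reason ``NoZCross`` if none exists.
    """
    dzdt = np.asarray(dzdt, dtype=float)
    rows = []
    for start, _r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        seg = dzdt[start:c]
        cross = np.nonzero((seg[:-1] < 0) & (seg[1:] >= 0))[0]
        rows.append(
            (float(start + cross[-1] + 1), "") if cross.size else (np.nan, NO_Z_CROSS)
        )
    return _result(rows)


def bpoint_debski_sd(dzdt, partition, cpoints, fs) -> pd.DataFrame:
    """Last local minimum of d2Z/dt2 before the C-point (reason ``NoLocMin``)."""
    d2 = differentiate(dzdt, fs, order=2)
    rows = []
    for start, _r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        mins = local_minima(d2[start:c])
        rows.append((float(start + mins[-1]), "") if mins.size else (np.nan, NO_LOC_MIN))
    return _result(rows)


def bpoint_arbol_ic(dzdt, partition, cpoints, fs=None) -> pd.DataFrame:
    """Last crossing of dZ/dt through the within-cycle mean ("isoelectric
    crossing") before the C-point; B = first sample on the far side of the
    crossing. Reason ``NoIsoCross`` when the segment never crosses its mean."""
    dzdt = np.asarray(dzdt, dtype=float)
    rows = []
    for start, _r, end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        iso = float(np.mean(dzdt[start:end]))
        seg = dzdt[start:c] - iso
        cross = np.nonzero(np.sign(seg[:-1]) * np.sign(seg[1:]) < 0)[0]
        rows.append(
            (float(start + cross[-1] + 1), "") if cross.size else (np.nan, NO_ISO_CROSS)
        )
    return _result(rows)


def _clip_window(lo, hi, start):
    lo = max(lo, start)
    return lo, hi, (hi - lo) >= 2


def bpoint_arbol_sd(dzdt, partition, cpoints, fs) -> pd.DataFrame:
    """Maximum of d2Z/dt2 in the 50 ms window starting 150 ms before the
    C-point ([C-150 ms, C-100 ms]); windows clipped to the cycle start,
    reason ``InvBWindow`` when fewer than 2 samples remain."""
    d2 = differentiate(dzdt, fs, order=2)
    w150 = int(ms_to_samples(150.0, fs))
    w100 = int(ms_to_samples(100.0, fs))
    rows = []
    for start, _r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        lo, hi, ok = _clip_window(c - w150, c - w100, start)
        if not ok:
            rows.append((np.nan, INV_B_WINDOW))
            continue
        rows.append((float(lo + int(np.argmax(d2[lo : hi + 1]))), ""))
    return _result(rows)


def bpoint_arbol_td(dzdt, partition, cpoints, fs) -> pd.DataFrame:
    """Maximum of d3Z/dt3 within 300 ms before the C-point ([C-300 ms, C));
    reason ``InvBWindow`` when the clipped window is empty."""
    d3 = differentiate(dzdt, fs, order=3)
    w300 = int(ms_to_samples(300.0, fs))
    rows = []
    for start, _r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        lo, hi, ok = _clip_window(c - w300, c, start)
        if not ok:
            rows.append((np.nan, INV_B_WINDOW))
            continue
        rows.append((float(lo + int(np.argmax(d3[lo:hi]))), ""))
    return _result(rows)


# --------------------------------------------------------------------------
# regression family
# --------------------------------------------------------------------------

LOZANO_LINEAR = (0.55, 4.45)
LOZANO_QUADRATIC = (-0.0032, 1.233, -31.59)


def lozano_b_offset_ms(rc_ms: float, form: str = "linear") -> float:
    """Predicted R-to-B offset in ms from the R-C interval (fixed coefficients,
    never refit): linear B = 0.55*RC + 4.45; quadratic
    B = -0.0032*RC^2 + 1.233*RC - 31.59."""
    if form == "linear":
        a, b = LOZANO_LINEAR
        return a * rc_ms + b
    if form == "quadratic":
        a, b, c = LOZANO_QUADRATIC
        return a * rc_ms**2 + b * rc_ms + c
    raise ValueError(f"form must be 'linear' or 'quadratic', got {form!r}")


def bpoint_lozano(partition, cpoints, fs, form: str = "linear") -> pd.DataFrame:
    """Regression B-point: B index = R + round(B_ms * fs/1000), with B_ms the
    linear/quadratic prediction from the R-C interval. The predicted index
    must lie in [cycle start, C); otherwise missing (``InvBWindow``)."""
    rows = []
    for start, r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        rc_ms = (c - r) * 1000.0 / fs
        b = r + int(ms_to_samples(lozano_b_offset_ms(rc_ms, form), fs))
        if b >= c or b < start:
            rows.append((np.nan, INV_B_WINDOW))
        else:
            rows.append((float(b), ""))
    return _result(rows)


# --------------------------------------------------------------------------
# chord distance (Drost)
# --------------------------------------------------------------------------

def bpoint_drost(dzdt, partition, cpoints, fs) -> pd.DataFrame:
    """Maximum vertical distance between dZ/dt and the chord from the point
    150 ms before the C-point to the C-point; ties resolved to the latest
    index. Window clipped to the cycle start (``InvBWindow`` if < 2 samples)."""
    dzdt = np.asarray(dzdt, dtype=float)
    w150 = int(ms_to_samples(150.0, fs))
    rows = []
    for start, _r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        lo = max(start, c - w150)
        if c - lo < 2:
            rows.append((np.nan, INV_B_WINDOW))
            continue
        k = np.arange(lo, c + 1)
        line = dzdt[lo] + (dzdt[c] - dzdt[lo]) * (k - lo) / (c - lo)
        dist = line - dzdt[lo : c + 1]
        b = lo + (dist.size - 1 - int(np.argmax(dist[::-1])))  # latest argmax
        rows.append((float(b), ""))
    return _result(rows)


# --------------------------------------------------------------------------
# monotone-segment rule (Forouzanfar)
# --------------------------------------------------------------------------

def _increasing_runs(x: np.ndarray):
    """Maximal runs of strictly increasing samples as (start, stop) with
    stop inclusive; runs of length >= 2 samples."""
    d = np.diff(x) > 0
    runs = []
    i = 0
    while i < d.size:
        if d[i]:
            j = i
            while j < d.size and d[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def bpoint_forouzanfar(dzdt, partition, cpoints, fs) -> pd.DataFrame:
    """Monotone-segment rule.

    A-point = last local minimum of dZ/dt in [C - RR_prev/3, C); among the
    maximal monotonically increasing runs of dZ/dt in [A, C] the most
    significant one is selected (longest, ties by amplitude gain, then by
    later onset). Within the first third of that run, B is the last zero
    crossing of d3Z/dt3 (first sample on the far side), falling back to the
    last local maximum of d3Z/dt3; with the chain exhausted the cycle is
    missing (``NoMonIncr``). No A-point -> ``NoLocMin``.
    """
    dzdt = np.asarray(dzdt, dtype=float)
    d3 = differentiate(dzdt, fs, order=3)
    rows = []
    for start, _r, _end, rr_prev, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        a_lo = max(start, c - int(round(rr_prev / 3)))
        if c - a_lo < 2:
            rows.append((np.nan, INV_B_WINDOW))
            continue
        mins = local_minima(dzdt[a_lo:c])
        if mins.size == 0:
            rows.append((np.nan, NO_LOC_MIN))
            continue
        a = a_lo + int(mins[-1])
        seg = dzdt[a : c + 1]
        runs = _increasing_runs(seg)
        if not runs:
            rows.append((np.nan, NO_MON_INCR))
            continue
        runs.sort(key=lambda r_: (r_[1] - r_[0], seg[r_[1]] - seg[r_[0]], r_[0]))
        s, e = runs[-1]
        third_end = s + max(1, (e - s) // 3)
        lo, hi = a + s, a + third_end  # absolute, inclusive
        sub = d3[lo : hi + 1]
        cross = np.nonzero(np.sign(sub[:-1]) * np.sign(sub[1:]) < 0)[0]
        if cross.size:
            rows.append((float(lo + cross[-1] + 1), ""))
            continue
        maxs = local_maxima(sub)
        if maxs.size:
            rows.append((float(lo + maxs[-1]), ""))
        else:
            rows.append((np.nan, NO_MON_INCR))
    return _result(rows)


# --------------------------------------------------------------------------
# multi-stage slope rule (Pale)
# --------------------------------------------------------------------------

def bpoint_pale(dzdt, partition, cpoints, fs) -> pd.DataFrame:
    """Multi-stage search in [C - 150 ms, C).

    Stage 1: the local minimum closest to the C-point, else the first sample
    whose forward slope exceeds theta = 0.5*(dZ/dt(C) - window minimum)/150 ms
    (the threshold scales with the C-wave amplitude). Stage 2 repeats with
    theta/2. Stage 3 falls back to the global minimum of dZ/dt in
    [cycle start, C). Invalid window -> ``InvBWindow``.
    """
    dzdt = np.asarray(dzdt, dtype=float)
    w150 = int(ms_to_samples(150.0, fs))
    rows = []
    for start, _r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        lo = max(start, c - w150)
        if c - lo < 2:
            rows.append((np.nan, INV_B_WINDOW))
            continue
        win = dzdt[lo:c]
        theta = 0.5 * (dzdt[c] - float(np.min(win))) / 150.0  # units per ms
        slope = np.diff(win) * fs / 1000.0                    # units per ms
        b = np.nan
        for thr in (theta, theta / 2.0):
            mins = local_minima(win)
            if mins.size:
                b = lo + int(mins[-1])  # closest local minimum to C
                break
            above = np.nonzero(slope > thr)[0]
            if above.size:
                b = lo + int(above[0])
                break
        if np.isnan(b):
            b = start + int(np.argmin(dzdt[start:c]))  # stage 3: global minimum
        rows.append((float(b), ""))
    return _result(rows)


# --------------------------------------------------------------------------
# weighted-window transform (Miljkovic)
# --------------------------------------------------------------------------

def bpoint_miljkovic(dzdt, partition, cpoints, fs, weight_fn=None) -> pd.DataFrame:
    """Weighted-window transform of the 300 ms segment before the C-point.

    The segment is multiplied by a monotone weight rising from ~0 to 1
    (default w(k) = (k/N)^2), which suppresses early-cycle content and
    amplifies the B-point region; B is the last local minimum of the
    transformed signal before C, falling back to its argmin. Empty window ->
    ``InvBWindow``. ``weight_fn(N) -> array of length N`` overrides the weight.
    """
    dzdt = np.asarray(dzdt, dtype=float)
    w300 = int(ms_to_samples(300.0, fs))
    rows = []
    for start, _r, _end, _rr, cp in _iter_cycles(partition, cpoints):
        if np.isnan(cp["c_point"]):
            rows.append((np.nan, NO_C))
            continue
        c = int(cp["c_point"])
        lo = max(start, c - w300)
        n = c - lo
        if n < 2:
            rows.append((np.nan, INV_B_WINDOW))
            continue
        w = weight_fn(n) if weight_fn is not None else (np.arange(1, n + 1) / n) ** 2
        y = w * dzdt[lo:c]
        mins = local_minima(y)
        b = lo + int(mins[-1]) if mins.size else lo + int(np.argmin(y))
        rows.append((float(b), ""))
    return _result(rows)


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

B_METHODS = (
    "ste85", "she90", "deb93sd", "loz07lr", "loz07qr", "arb17ic",
    "arb17sd", "arb17td", "for18", "pal21", "dro22", "mil22",
)


def extract_b_points(method, dzdt, partition, cpoints, fs, **params) -> pd.DataFrame:
    """Dispatch a B-point extraction by method name (see ``B_METHODS``)."""
    method = method.lower()
    if method == "ste85":
        return bpoint_stern(dzdt, partition, cpoints, fs)
    if method == "she90":
        return bpoint_sherwood(dzdt, partition, cpoints, fs)
    if method == "deb93sd":
        return bpoint_debski_sd(dzdt, partition, cpoints, fs)
    if method == "loz07lr":
        return bpoint_lozano(partition, cpoints, fs, form="linear")
    if method == "loz07qr":
        return bpoint_lozano(partition, cpoints, fs, form="quadratic")
    if method == "arb17ic":
        return bpoint_arbol_ic(dzdt, partition, cpoints, fs)
    if method == "arb17sd":
        return bpoint_arbol_sd(dzdt, partition, cpoints, fs)
    if method == "arb17td":
        return bpoint_arbol_td(dzdt, partition, cpoints, fs)
    if method == "for18":
        return bpoint_forouzanfar(dzdt, partition, cpoints, fs)
    if method == "pal21":
        return bpoint_pale(dzdt, partition, cpoints, fs)
    if method == "dro22":
        return bpoint_drost(dzdt, partition, cpoints, fs)
    if method == "mil22":
        return bpoint_miljkovic(dzdt, partition, cpoints, fs, **params)
    raise ValueError(f"unknown B-point method: {method!r}")
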