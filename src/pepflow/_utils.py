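"""Shared low-level helpers: rounding and extremum conventions.

The sample-index conventions used across the package:

* 0-based sample indices, half-open cycle intervals ``[start, end)``.
* ``round_half_away`` is used wherever a time in ms is converted to a sample
  count, so results are bit-exact across platforms (numpy's banker rounding
  would make e.g. 0.35 * RR platform-consistent but surprising).
* "local minimum/maximum" means a strict three-point extremum; plateaus of
  equal samples are resolved to the *last* plateau sample.
"""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Round half away from zero, elementwise; returns int64."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(np.int64) if out.ndim else int(out)


def ms_to_samples(ms, fs):
    """Convert a duration in ms to a sample count (round half away from zero)."""
    return round_half_away(np.asarray(ms, dtype=float) * fs / 1000.0)


def samples_to_ms(n, fs):
    return np.asarray(n, dtype=float) * 1000.0 / fs


def local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima of ``x``; plateau minima resolved to the
    last sample of the plateau. Endpoints are never extrema."""
    return _local_extrema(np.asarray(x, dtype=float), sign=-1)


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (plateaus -> last plateau sample)."""
    return _local_extrema(np.asarray(x, dtype=float), sign=+1)


def _local_extrema(x: np.ndarray, sign: int) -> np.ndarray:
    n = x.size
    if n < 3:
        return np.empty(0, dtype=np.int64)
    d = np.diff(x)
    # rising/falling state ignoring zero steps: propagate last nonzero slope
    s = np.sign(d)
    idx = np.where(s != 0, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    prev = np.where(idx >= 0, s[np.clip(idx, 0, None)], 0.0)
    out = []
    for i in range(1, s.size):
        if s[i] != 0 and prev[i - 1] == sign and s[i] == -sign:
            out.append(i)  # last sample of the (possibly flat) trough/crest
    return np.asarray(out, dtype=np.int64)
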