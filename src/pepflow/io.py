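"""Recording/annotation I/O, band-pass preprocessing, and derivatives.

Signal CSV dialect: columns ``t_s, ecg, dzdt`` (configurable names). The
sampling rate comes from the caller or a YAML sidecar. Annotation CSV dialect:
``cycle_id,start,r_peak,end,q_peak,b_point,artifact,participant,condition,phase``
with empty cells denoting missing fiducials. All sample indices are 0-based;
cycle intervals are half-open ``[start, end)``.

Preprocessing follows the benchmark's filter design: ECG through a fifth-order
Butterworth band-pass (0.67-45 Hz), dZ/dt through a fourth-order Butterworth
band-pass (0.5-25 Hz). Both are applied forward-backward (zero-phase): causal
filtering would shift fiducial timings and bias every PEP estimate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from ._utils import ms_to_samples

__all__ = [
    "Recording",
    "FormatError",
    "load_recording",
    "save_recording",
    "load_annotations",
    "save_annotations",
    "preprocess_ecg",
    "preprocess_dzdt",
    "differentiate",
]

ANNOTATION_COLUMNS = [
    "cycle_id", "start", "r_peak", "end", "q_peak", "b_point",
    "artifact", "participant", "condition", "phase",
]


class FormatError(ValueError):
    """Malformed recording or annotation file (names the offending field)."""


@dataclass
class Recording:
    """Synchronized ECG and dZ/dt channels sharing one sampling rate."""

    ecg: np.ndarray
    dzdt: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.dzdt = np.asarray(self.dzdt, dtype=float)
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        if not (np.all(np.isfinite(self.ecg)) and np.all(np.isfinite(self.dzdt))):
            raise FormatError("non-finite sample values in recording")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _resample_to(x: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Polyphase rational resampling (avoids aliasing near the ICG band edge)."""
    if fs_from == fs_to:
        return x
    frac = Fraction(fs_to / fs_from).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def load_recording(
    path,
    *,
    ecg_column: str = "ecg",
    dzdt_column: str = "dzdt",
    fs_ecg: float | None = None,
    fs_dzdt: float | None = None,
    config_path=None,
) -> Recording:
    """Read a columnar signal CSV into a Recording with harmonized rates.

    The sampling rates come either from the keyword arguments or from a YAML
    sidecar (``config_path``; keys ``fs_ecg``, ``fs_dzdt``, and optionally
    ``ecg_column``/``dzdt_column``). If the two channels were sampled at
    different rates, the higher-rate channel is resampled down so both end up
    at the lower rate.
    """
    if config_path is not None:
        cfg = yaml.safe_load(Path(config_path).read_text()) or {}
        ecg_column = cfg.get("ecg_column", ecg_column)
        dzdt_column = cfg.get("dzdt_column", dzdt_column)
        fs_ecg = cfg.get("fs_ecg", fs_ecg)
        fs_dzdt = cfg.get("fs_dzdt", fs_dzdt)
    if fs_ecg is None:
        raise FormatError("sampling rate missing: fs_ecg")
    if fs_dzdt is None:
        fs_dzdt = fs_ecg

    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse signal file {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"empty signal file: {path}")
    for col in (ecg_column, dzdt_column):
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
        if not np.issubdtype(pd.to_numeric(df[col], errors="coerce").dtype, np.number) or \
                pd.to_numeric(df[col], errors="coerce").isna().any():
            raise FormatError(f"non-numeric sample in column: {col}")

    ecg = df[ecg_column].to_numpy(dtype=float)
    dzdt = df[dzdt_column].to_numpy(dtype=float)
    fs = min(fs_ecg, fs_dzdt)
    ecg = _resample_to(ecg, fs_ecg, fs)
    dzdt = _resample_to(dzdt, fs_dzdt, fs)
    m = min(len(ecg), len(dzdt))  # rational resampling may differ by one sample
    return Recording(ecg=ecg[:m], dzdt=dzdt[:m], fs=fs)


def save_recording(recording: Recording, path) -> None:
    t = np.arange(recording.n_samples) / recording.fs
    pd.DataFrame({"t_s": t, "ecg": recording.ecg, "dzdt": recording.dzdt}).to_csv(
        path, index=False
    )


def load_annotations(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse annotation file {path}: {exc}") from exc
    missing = [c for c in ("start", "r_peak", "end") if c not in df.columns]
    if missing:
        raise FormatError(f"missing column: {missing[0]}")
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if "artifact" in df.columns:
        df["artifact"] = df["artifact"].fillna(False).astype(bool)
    return df[ANNOTATION_COLUMNS]


def save_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, index=False)


def _bandpass(x, fs, low, high, order):
    if fs <= 2 * high:
        raise ValueError(
            f"fs={fs} Hz too low for a {high} Hz band edge (Nyquist limit)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def preprocess_ecg(ecg, fs):
    """Fifth-order Butterworth band-pass 0.67-45 Hz, zero-phase."""
    return _bandpass(np.asarray(ecg, dtype=float), fs, 0.67, 45.0, 5)


def preprocess_dzdt(dzdt, fs):
    """Fourth-order Butterworth band-pass 0.5-25 Hz, zero-phase."""
    return _bandpass(np.asarray(dzdt, dtype=float), fs, 0.5, 25.0, 4)


def differentiate(x, fs, order: int = 1):
    """Estimate the order-th time derivative (units/s^order), same length.

    Each pass smooths with a short moving average (window round(5*fs/1000),
    minimum 3 samples) before central differencing: repeated raw differencing
    of 500-1000 Hz signals amplifies noise and destroys the higher-derivative
    extrema the B-point searches rely on.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    x = np.asarray(x, dtype=float)
    if x.size <= 2 * order:
        raise ValueError(f"input too short for order-{order} derivative")
    w = max(3, int(ms_to_samples(5.0, fs)))
    kernel = np.ones(w) / w
    y = x
    for _ in range(order):
        pad = w // 2
        yp = np.pad(y, pad, mode="edge")
        y = np.convolve(yp, kernel, mode="same")[pad:-pad]
        y = np.gradient(y) * fs
    return y
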