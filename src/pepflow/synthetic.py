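"""Synthetic ECG + dZ/dt beat trains with exact fiducial ground truth.

Every downstream stage of the package (R-peak detection, cycle segmentation,
Q-peak / C-point / B-point extraction, outlier correction, evaluation) is
testable against this generator without any external recording: the generator
places the Q-peak, R-peak, B-point and C-point at known sample indices by
construction and returns them alongside the signals.

Waveform model
--------------
The ECG beat is a sum of Gaussian bumps for the P, Q, R, S and T waves, with
the Q bump a narrow negative deflection peaking exactly at the ground-truth
Q-peak sample. The dZ/dt beat is a piecewise cubic Hermite spline through
knots that realize one of four B-point morphology classes commonly
distinguished by human annotators:

* ``notch``       -- an incisive local minimum exactly at the B-point,
* ``plateau``     -- a zero-slope shelf of ~15 ms starting at the B-point,
* ``inflection``  -- a curvature sign change at the B-point with no extremum,
* ``featureless`` -- a purely monotone rise through the B-point region.

In all classes the C-point is the global within-beat maximum of dZ/dt and the
A-wave is a local minimum preceding the B-point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from ._utils import ms_to_samples

__all__ = ["SynthConfig", "NoiseConfig", "synth_beat_kernel", "synth_recording"]

MORPHOLOGIES = ("notch", "plateau", "inflection", "featureless")


class ConfigurationError(ValueError):
    """Raised for physiologically or numerically infeasible configurations."""


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbances applied after beat concatenation.

    Amplitudes are in signal units (the clean R-peak and C-wave amplitudes
    are both 1.0, so e.g. ``gaussian_sd=0.1`` is 10% of the R amplitude).
    """

    gaussian_sd: float = 0.0
    baseline_drift_amp: float = 0.0
    baseline_drift_freq: float = 0.2   # Hz
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0       # Hz


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic synchronized ECG/dZ/dt recording.

    Defaults reflect a resting adult: 60 bpm, PEP of 100 ms (well inside the
    60-170 ms physiological range), Q-R gap of 40 ms and an R-C interval of
    150 ms.
    """

    duration_s: float = 60.0
    fs: float = 1000.0
    heart_rate_bpm: float = 60.0
    rr_jitter_frac: float = 0.0        # i.i.d. Gaussian SD as fraction of mean RR, truncated at +/-20%
    pep_ms: float = 100.0              # Q-peak -> B-point
    pep_jitter_ms: float = 0.0         # i.i.d. Gaussian SD of the per-beat PEP
    q_r_gap_ms: float = 40.0           # Q-peak -> R-peak
    rc_ms: float = 150.0               # R-peak -> C-point
    b_morphology: str = "notch"
    q_amplitude: float = 0.12          # 0 synthesizes beats without a Q deflection
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.fs < 250:
            raise ConfigurationError("fs must be >= 250 Hz")
        if not 40 <= self.heart_rate_bpm <= 180:
            raise ConfigurationError("heart_rate_bpm must be in [40, 180]")
        if not 0 < self.pep_ms < self.rc_ms:
            raise ConfigurationError(
                f"need 0 < pep_ms < rc_ms, got pep={self.pep_ms}, rc={self.rc_ms}"
            )
        if not 0 < self.q_r_gap_ms < self.pep_ms:
            raise ConfigurationError("need 0 < q_r_gap_ms < pep_ms (B-point after R-peak)")
        if self.b_morphology not in MORPHOLOGIES:
            raise ConfigurationError(f"b_morphology must be one of {MORPHOLOGIES}")
        if not 0 <= self.rr_jitter_frac <= 0.2:
            raise ConfigurationError("rr_jitter_frac must be in [0, 0.2]")
        if self.pep_jitter_ms < 0:
            raise ConfigurationError("pep_jitter_ms must be non-negative")


def _gauss(t, center, sigma, amp):
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _ecg_beat(t, r_time, q_time, q_amplitude):
    """Sum of Gaussian bumps for P, Q, R, S, T, evaluated at times ``t`` (s)."""
    y = _gauss(t, r_time - 0.160, 0.025, 0.15)       # P
    if q_amplitude > 0:
        y += _gauss(t, q_time, 0.005, -q_amplitude)  # Q (narrow negative dip)
    y += _gauss(t, r_time, 0.009, 1.0)               # R
    y += _gauss(t, r_time + 0.030, 0.007, -0.25)     # S
    y += _gauss(t, r_time + 0.250, 0.050, 0.30)      # T
    return y


def _dzdt_knots(r_time, b_time, c_time, morphology, rr_prev_s):
    """Knot list (time, value, derivative) for the Hermite dZ/dt beat.

    The systolic complex spans [A-wave, C + 160 ms]: baseline -> A-wave trough
    -> morphology-specific B feature -> steep upslope -> C-wave peak ->
    downstroke -> baseline. The upslope accelerates quickly after the B-point
    (slope well above the B-to-C chord slope within a few ms), which is what
    makes the B-point the onset of the "rapid rise" annotators look for.

    The featureless class has no A-wave inside the cycle window: the rise
    starts 40% of the preceding RR interval before the R-peak (just outside
    the cycle border at 35%), so dZ/dt is monotone from the cycle start to C.
    """
    if morphology == "featureless":
        t0 = r_time - 0.40 * rr_prev_s            # outside the -35% cycle border
        knots = [(t0 - 0.050, 0.0, 0.0), (t0, -0.20, 0.0)]
    else:
        a_time = b_time - 0.060                   # A-point: local min 60 ms before B
        knots = [(a_time - 0.040, 0.0, 0.0), (a_time, -0.30, 0.0)]
        if morphology == "notch":
            # small ridge between A and B, an incisive local min exactly at B,
            # then a fast acceleration into the C upslope
            knots += [
                ((a_time + b_time) / 2, 0.05, 0.0),
                (b_time, -0.05, 0.0),
                (b_time + 0.012, 0.12, 30.0),
            ]
        elif morphology == "plateau":
            # zero-slope shelf of 15 ms starting at B
            knots += [
                (b_time, 0.00, 0.0),
                (b_time + 0.015, 0.01, 0.0),
                (b_time + 0.027, 0.15, 30.0),
            ]
        elif morphology == "inflection":
            # positive but locally minimal slope at B (curvature sign change)
            knots += [(b_time, 0.05, 1.5)]
        else:  # pragma: no cover - guarded by SynthConfig
            raise ConfigurationError(f"unknown morphology {morphology!r}")
    knots += [(c_time, 1.0, 0.0), (c_time + 0.080, -0.10, 0.0), (c_time + 0.160, 0.0, 0.0)]
    return knots


def synth_beat_kernel(
    config: SynthConfig,
    r_time_s: float,
    rr_prev_s: float | None = None,
    pep_ms: float | None = None,
):
    """Synthesize one beat and its exact fiducials.

    Parameters
    ----------
    config
        Generator configuration; ``pep_ms``/``rc_ms``/``q_r_gap_ms`` define
        the beat timing.
    r_time_s
        Absolute R-peak time in seconds from recording start.
    rr_prev_s
        Preceding RR interval in seconds (defaults to the configured mean RR);
        only the featureless morphology uses it, to anchor its rise onset just
        outside the cycle border.
    pep_ms
        Per-beat PEP override in ms (defaults to ``config.pep_ms``); used by
        :func:`synth_recording` when ``pep_jitter_ms`` > 0.

    Returns
    -------
    (ecg_fn, dzdt_fn, truth) where the first two are callables mapping a time
    vector (s) to the beat waveform and ``truth`` is a dict of exact fiducial
    sample indices (``q_peak``, ``r_peak``, ``b_point``, ``c_point``) plus the
    true PEP in ms.
    """
    fs = config.fs
    if rr_prev_s is None:
        rr_prev_s = 60.0 / config.heart_rate_bpm
    if pep_ms is None:
        pep_ms = config.pep_ms
    r_idx = int(round(r_time_s * fs))
    q_idx = r_idx - int(ms_to_samples(config.q_r_gap_ms, fs))
    b_idx = q_idx + int(ms_to_samples(pep_ms, fs))
    c_idx = r_idx + int(ms_to_samples(config.rc_ms, fs))
    if not (q_idx < r_idx < b_idx < c_idx):
        raise ConfigurationError("infeasible beat timing (require q < r < b < c)")

    q_t, b_t, c_t = q_idx / fs, b_idx / fs, c_idx / fs
    r_t = r_idx / fs
    knots = _dzdt_knots(r_t, b_t, c_t, config.b_morphology, rr_prev_s)
    kt = np.array([k[0] for k in knots])
    kv = np.array([k[1] for k in knots])
    kd = np.array([k[2] for k in knots])
    spline = CubicHermiteSpline(kt, kv, kd)

    def dzdt_fn(t):
        y = np.zeros_like(t)
        m = (t >= kt[0]) & (t <= kt[-1])
        y[m] = spline(t[m])
        return y

    def ecg_fn(t):
        return _ecg_beat(t, r_t, q_t, config.q_amplitude)

    truth = {
        "r_peak": r_idx,
        "q_peak": q_idx,
        "b_point": b_idx,
        "c_point": c_idx,
        "pep_ms": (b_idx - q_idx) * 1000.0 / fs,
    }
    return ecg_fn, dzdt_fn, truth


def _r_times(config: SynthConfig, rng: np.random.Generator):
    rr_mean = 60.0 / config.heart_rate_bpm
    # first beat needs room for the P wave and the pre-R cycle border
    t = max(0.45, 0.35 * rr_mean + 0.05)
    times = []
    tail = 0.35  # leave room for the T wave / dZ/dt downstroke of the last beat
    while t < config.duration_s - tail:
        times.append(t)
        jitter = 0.0
        if config.rr_jitter_frac > 0:
            jitter = float(np.clip(rng.normal(0.0, config.rr_jitter_frac), -0.2, 0.2))
        t += rr_mean * (1.0 + jitter)
    return np.asarray(times)


def synth_recording(config: SynthConfig):
    """Generate a full synchronized recording.

    Returns
    -------
    recording : pepflow.io.Recording
        ECG and dZ/dt channels at ``config.fs``.
    truth : pandas.DataFrame
        One row per beat: exact ``q_peak``, ``r_peak``, ``b_point``,
        ``c_point`` sample indices and the true ``pep_ms``.
    annotations : pandas.DataFrame
        Per-cycle reference table in the package's annotation CSV dialect
        (first beat carries no cycle because it has no preceding RR interval).
    """
    from .io import Recording

    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    ecg = np.zeros(n)
    dzdt = np.zeros(n)

    r_times = _r_times(config, rng)
    rr_mean = 60.0 / config.heart_rate_bpm
    rows = []
    for k, r_time in enumerate(r_times):
        rr_prev = r_times[k] - r_times[k - 1] if k > 0 else rr_mean
        pep_k = config.pep_ms
        if config.pep_jitter_ms > 0:
            # keep the B-point strictly between the R-peak and the C-wave
            pep_k = float(
                np.clip(
                    rng.normal(config.pep_ms, config.pep_jitter_ms),
                    config.q_r_gap_ms + 10.0,
                    config.rc_ms - 10.0,
                )
            )
        ecg_fn, dzdt_fn, truth = synth_beat_kernel(config, r_time, rr_prev, pep_ms=pep_k)
        lo = max(0, truth["r_peak"] - int((0.45 * rr_prev + 0.15) * config.fs))
        hi = min(n, truth["c_point"] + int(0.45 * config.fs))
        ecg[lo:hi] += ecg_fn(t[lo:hi])
        dzdt[lo:hi] += dzdt_fn(t[lo:hi])
        rows.append(truth)
    truth_df = pd.DataFrame(rows)

    noise = config.noise
    for sig in (ecg, dzdt):
        if noise.gaussian_sd > 0:
            sig += rng.normal(0.0, noise.gaussian_sd, size=n)
        if noise.baseline_drift_amp > 0:
            sig += noise.baseline_drift_amp * np.sin(
                2 * np.pi * noise.baseline_drift_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.powerline_amp > 0:
            sig += noise.powerline_amp * np.sin(
                2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
            )

    recording = Recording(ecg=ecg, dzdt=dzdt, fs=config.fs)

    annotations = _annotations_from_truth(truth_df, config.fs, n)
    return recording, truth_df, annotations


def _annotations_from_truth(truth: pd.DataFrame, fs: float, n_samples: int) -> pd.DataFrame:
    from .segmentation import partition_cycles

    part = partition_cycles(truth["r_peak"].to_numpy(), fs, n_samples=n_samples)
    # partition drops the first beat (no preceding RR); align truth accordingly
    aligned = truth.set_index("r_peak").loc[part["r_peak"]].reset_index()
    ann = pd.DataFrame(
        {
            "cycle_id": np.arange(len(part)),
            "start": part["start"].to_numpy(),
            "r_peak": part["r_peak"].to_numpy(),
            "end": part["end"].to_numpy(),
            "q_peak": aligned["q_peak"].to_numpy(),
            "b_point": aligned["b_point"].to_numpy(),
            "artifact": False,
            "participant": "SYNTH",
            "condition": "synthetic",
            "phase": "synthetic",
        }
    )
    return ann
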