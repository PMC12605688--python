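"""PEP extraction pipelines: stage composition and pipeline enumeration.

A pipeline chains: cycle segmentation -> C-point extraction -> (Q-peak from
the ECG in parallel with B-point from dZ/dt) -> optional B-point outlier
correction -> per-cycle PEP, where

    PEP [ms] = (b_point - q_peak) / fs * 1000

The Q and B stages operate independently on their signals, so a B-point can
land before the Q-peak; the ``negative_pep_policy`` decides whether such
cycles become missing (``"nan"``, default, reason ``NegPEP``) or are set to 0
(``"zero"``). Either fiducial stream can be replaced by a reference
annotation table (reference injection), which is how individual algorithms
are evaluated in isolation: with reference Q-peaks injected, any PEP error is
exactly the B-point error, and symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd
import yaml

from .ecg import Q_METHODS, extract_q_peaks
from .icg import B_METHODS, NEG_PEP, detect_c_points, extract_b_points
from .io import Recording, preprocess_dzdt, preprocess_ecg
from .outliers import OUTLIER_METHODS, correct_b_points
from .segmentation import detect_r_peaks, partition_cycles
from ._utils import round_half_away

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "compute_pep",
    "run_pipeline",
    "enumerate_pipelines",
    "VAN_LIEN_T_GRID",
]

VAN_LIEN_T_GRID = (32, 34, 36, 38, 40, 42)  # ms

NO_Q = "NoQ"  # Q-peak stage returned missing (carries the stage's own reason too)


@dataclass(frozen=True)
class PipelineConfig:
    """Fully specified PEP extraction pipeline."""

    q_method: str = "van13"
    q_params: dict = field(default_factory=dict)
    b_method: str = "dro22"
    b_params: dict = field(default_factory=dict)
    outlier_method: str = "none"
    negative_pep_policy: str = "nan"
    interpolate_missing_b: bool = True

    def __post_init__(self):
        if self.q_method not in Q_METHODS:
            raise ValueError(f"unknown Q method {self.q_method!r}")
        if self.b_method not in B_METHODS:
            raise ValueError(f"unknown B method {self.b_method!r}")
        if self.outlier_method not in OUTLIER_METHODS:
            raise ValueError(f"unknown outlier method {self.outlier_method!r}")
        if self.negative_pep_policy not in ("nan", "zero"):
            raise ValueError("negative_pep_policy must be 'nan' or 'zero'")

    def label(self) -> str:
        q = self.q_method
        if self.q_method == "van13":
            q += f"(t={self.q_params.get('t_ms', 40)})"
        return f"{q}+{self.b_method}+{self.outlier_method}"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class PipelineResult:
    """Per-cycle PEP series plus retained stage intermediates."""

    pep: pd.DataFrame                  # cycle_id,start,r_peak,end,q_peak,c_point,b_point,pep_ms,valid,reason
    partition: pd.DataFrame | None = None
    cpoints: pd.DataFrame | None = None
    q_result: pd.DataFrame | None = None
    b_result: pd.DataFrame | None = None
    b_uncorrected: np.ndarray | None = None
    outlier_mask: np.ndarray | None = None


def compute_pep(q_peak, b_point, fs, policy: str = "nan"):
    """Per-cycle PEP in ms from fiducial sample indices.

    Vectorized; NaN in either fiducial propagates. ``b <= q`` yields NaN
    (policy ``"nan"``) or 0.0 (policy ``"zero"``).

    Returns ``(pep_ms, neg_pep_mask)``.
    """
    if policy not in ("nan", "zero"):
        raise ValueError("policy must be 'nan' or 'zero'")
    q = np.asarray(q_peak, dtype=float)
    b = np.asarray(b_point, dtype=float)
    pep = (b - q) * 1000.0 / fs
    neg = np.isfinite(pep) & (pep <= 0)
    pep = np.where(neg, np.nan if policy == "nan" else 0.0, pep)
    return pep, neg


def _inject_reference(partition: pd.DataFrame, reference: pd.DataFrame, column: str):
    """Map a reference annotation column onto detected cycles: each cycle takes
    the reference fiducial that falls inside its [start, end) interval."""
    vals = np.full(len(partition), np.nan)
    ref = reference.dropna(subset=[column])
    pos = ref[column].to_numpy(dtype=float)
    for i, (s, e) in enumerate(zip(partition["start"], partition["end"])):
        inside = pos[(pos >= s) & (pos < e)]
        if inside.size:
            vals[i] = inside[0]
    return pd.DataFrame({column: vals, "reason": np.where(np.isfinite(vals), "", "NoRef")})


def run_pipeline(
    recording: Recording,
    config: PipelineConfig,
    *,
    r_peaks=None,
    q_reference: pd.DataFrame | None = None,
    b_reference: pd.DataFrame | None = None,
    preprocess: bool = True,
    keep_intermediates: bool = True,
) -> PipelineResult:
    """Execute a full PEP extraction pipeline on a recording.

    ``q_reference`` / ``b_reference`` are annotation tables whose ``q_peak`` /
    ``b_point`` columns replace the corresponding automated stage (reference
    injection). ``r_peaks`` overrides R-peak detection (e.g. reference
    R-peaks, so detected cycles align with annotated ones).
    """
    fs = recording.fs
    ecg = preprocess_ecg(recording.ecg, fs) if preprocess else recording.ecg
    dzdt = preprocess_dzdt(recording.dzdt, fs) if preprocess else recording.dzdt

    if r_peaks is None:
        r_peaks = detect_r_peaks(ecg, fs)
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    empty = pd.DataFrame(
        columns=[
            "cycle_id", "start", "r_peak", "end", "q_peak", "c_point",
            "b_point", "pep_ms", "valid", "reason",
        ]
    )
    if r_peaks.size < 2:
        return PipelineResult(pep=empty)

    partition = partition_cycles(r_peaks, fs, n_samples=recording.n_samples)
    if partition.empty:
        return PipelineResult(pep=empty)

    cpoints = detect_c_points(dzdt, partition, fs)

    if q_reference is not None:
        q_res = _inject_reference(partition, q_reference, "q_peak")
    else:
        q_res = extract_q_peaks(config.q_method, ecg, partition, fs, **config.q_params)

    if b_reference is not None:
        b_res = _inject_reference(partition, b_reference, "b_point")
    else:
        b_res = extract_b_points(
            config.b_method, dzdt, partition, cpoints, fs, **config.b_params
        )

    # outlier correction operates on B-point times in ms from recording start
    b_idx = b_res["b_point"].to_numpy(dtype=float)
    b_uncorrected = b_idx.copy()
    outlier_mask = np.zeros(b_idx.size, dtype=bool)
    if config.outlier_method != "none":
        b_ms = b_idx * 1000.0 / fs
        r_ms = partition["r_peak"].to_numpy(dtype=float) * 1000.0 / fs
        corrected_ms, outlier_mask = correct_b_points(
            b_ms,
            r_ms,
            method=config.outlier_method,
            interpolate_missing=config.interpolate_missing_b,
        )
        b_idx = np.where(
            np.isfinite(corrected_ms),
            round_half_away(np.nan_to_num(corrected_ms) * fs / 1000.0).astype(float),
            np.nan,
        )

    q_idx = q_res.iloc[:, 0].to_numpy(dtype=float)
    pep_ms, neg = compute_pep(q_idx, b_idx, fs, policy=config.negative_pep_policy)

    reason = np.array([""] * len(partition), dtype=object)
    b_reasons = b_res["reason"].to_numpy(dtype=object)
    q_reasons = q_res["reason"].to_numpy(dtype=object)
    missing_b = ~np.isfinite(b_idx)
    missing_q = ~np.isfinite(q_idx)
    reason[missing_b] = [br if br else "NoB" for br in b_reasons[missing_b]]
    reason[missing_q] = [qr if qr else NO_Q for qr in q_reasons[missing_q]]
    reason[neg] = NEG_PEP

    valid = np.isfinite(pep_ms) & (pep_ms > 0)
    pep = pd.DataFrame(
        {
            "cycle_id": np.arange(len(partition)),
            "start": partition["start"].to_numpy(),
            "r_peak": partition["r_peak"].to_numpy(),
            "end": partition["end"].to_numpy(),
            "q_peak": q_idx,
            "c_point": cpoints["c_point"].to_numpy(dtype=float),
            "b_point": b_idx,
            "pep_ms": pep_ms,
            "valid": valid,
            "reason": reason,
        }
    )
    if not keep_intermediates:
        return PipelineResult(pep=pep)
    return PipelineResult(
        pep=pep,
        partition=partition,
        cpoints=cpoints,
        q_result=q_res,
        b_result=b_res,
        b_uncorrected=b_uncorrected,
        outlier_mask=outlier_mask,
    )


def enumerate_pipelines(
    q_methods=Q_METHODS,
    b_methods=B_METHODS,
    outlier_methods=OUTLIER_METHODS,
    expand_van_lien: bool = False,
    negative_pep_policy: str = "nan",
) -> list[PipelineConfig]:
    """Cartesian product of the algorithm registry.

    The default registry (3 Q methods x 12 B methods x 3 outlier methods)
    yields 108 pipelines; expanding the fixed-offset Q method over its
    t in {32,...,42} ms grid replaces 1 Q method with 6 variants (8 Q variants
    total) and yields 288 pipelines.
    """
    q_variants: list[tuple[str, dict]] = []
    for q in q_methods:
        if q == "van13" and expand_van_lien:
            q_variants += [("van13", {"t_ms": float(t)}) for t in VAN_LIEN_T_GRID]
        else:
            q_variants.append((q, {}))
    return [
        PipelineConfig(
            q_method=q,
            q_params=params,
            b_method=b,
            outlier_method=o,
            negative_pep_policy=negative_pep_policy,
        )
        for (q, params), b, o in product(q_variants, b_methods, outlier_methods)
    ]
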