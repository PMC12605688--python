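"""Evaluation engine: cycle matching, error metrics, aggregation, ICC.

Estimated cardiac cycles are matched one-to-one to reference (annotated)
cycles when both the start and end borders agree within a 100 ms tolerance
centered on the reference borders (i.e. +/-50 ms per border). Unmatched
estimated cycles are false positives and excluded; unmatched reference cycles
are reported separately. On matched cycles with a valid estimate,

    E   = PEP_ref - PEP_est        (ms)
    AE  = |E|                      (ms)
    ARE = AE / PEP_ref             (fraction; reported as percent)

Two aggregation levels are computed: *per datapoint* (mean within each
grouping-key combination, e.g. participant x condition x phase) and
*per sample* (mean and SD over every matched cycle, weighting each cycle
equally). Invalid PEPs are counted overall and per failure reason.

Inter-rater agreement uses the two-way mixed, absolute-agreement,
average-measures intraclass correlation ICC(3,2) with an F-based 95%
confidence interval (McGraw & Wong conventions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ms_to_samples

__all__ = [
    "MatchResult",
    "match_cycles",
    "per_sample_errors",
    "aggregate",
    "AggregateReport",
    "icc_3_2",
    "ICCResult",
    "invalid_counts",
]


@dataclass
class MatchResult:
    pairs: list            # (ref_index, est_index) positional pairs
    false_negatives: list  # reference indices missed by the estimator
    false_positives: list  # estimated indices with no reference cycle


def match_cycles(ref: pd.DataFrame, est: pd.DataFrame, fs: float, tol_ms: float = 100.0) -> MatchResult:
    """Greedy in-order one-to-one matching of cycles on (start, end) borders.

    A pair is accepted iff |start_ref - start_est| <= tol/2 and
    |end_ref - end_est| <= tol/2 (the 100 ms tolerance is centered on each
    border). With border tolerances of 50 ms and cycles several hundred ms
    long, matches cannot cross, so the greedy sweep is optimal.
    """
    tol = ms_to_samples(tol_ms, fs) / 2.0
    rs = ref["start"].to_numpy(dtype=float)
    re_ = ref["end"].to_numpy(dtype=float)
    es = est["start"].to_numpy(dtype=float)
    ee = est["end"].to_numpy(dtype=float)
    pairs, fn, fp = [], [], []
    i = j = 0
    while i < len(rs) and j < len(es):
        if abs(rs[i] - es[j]) <= tol and abs(re_[i] - ee[j]) <= tol:
            pairs.append((i, j))
            i += 1
            j += 1
        elif es[j] < rs[i]:
            fp.append(j)
            j += 1
        else:
            fn.append(i)
            i += 1
    fn.extend(range(i, len(rs)))
    fp.extend(range(j, len(es)))
    return MatchResult(pairs=pairs, false_negatives=fn, false_positives=fp)


def per_sample_errors(
    match: MatchResult,
    ref: pd.DataFrame,
    est: pd.DataFrame,
    *,
    ref_pep_column: str = "pep_ms",
    est_pep_column: str = "pep_ms",
    group_columns: tuple = (),
) -> pd.DataFrame:
    """One error row per matched cycle with a valid estimated PEP.

    Matched cycles whose estimate is missing are excluded from the error rows
    (they are counted as invalid by :func:`invalid_counts`). Rows whose
    reference PEP is non-positive are rejected with a data-quality flag
    column rather than silently dropped.
    """
    rows = []
    for ri, ei in match.pairs:
        pep_ref = float(ref.iloc[ri][ref_pep_column])
        pep_est = float(est.iloc[ei][est_pep_column])
        if not np.isfinite(pep_est):
            continue
        row = {
            "ref_cycle": ri,
            "est_cycle": ei,
            "pep_ref": pep_ref,
            "pep_est": pep_est,
        }
        if not np.isfinite(pep_ref) or pep_ref <= 0:
            row.update(error=np.nan, abs_error=np.nan, abs_rel_error=np.nan, rejected=True)
        else:
            e = pep_ref - pep_est
            row.update(error=e, abs_error=abs(e), abs_rel_error=abs(e) / pep_ref, rejected=False)
        for col in group_columns:
            row[col] = ref.iloc[ri][col]
        rows.append(row)
    return pd.DataFrame(rows)


def invalid_counts(match: MatchResult, est: pd.DataFrame, pep_column: str = "pep_ms") -> dict:
    """Invalid-PEP bookkeeping over matched cycles: total, per reason, and the
    unmatched-reference count (kept separate from the invalid total)."""
    idx = [ei for _, ei in match.pairs]
    sub = est.iloc[idx] if idx else est.iloc[:0]
    missing = ~np.isfinite(sub[pep_column].to_numpy(dtype=float))
    reasons = sub["reason"].to_numpy(dtype=object) if "reason" in sub else np.array([])
    per_reason: dict = {}
    for r in reasons[missing]:
        key = r if r else "Unspecified"
        per_reason[key] = per_reason.get(key, 0) + 1
    return {
        "total": int(len(sub)),
        "invalid": int(missing.sum()),
        "valid": int(len(sub) - missing.sum()),
        "per_reason": per_reason,
        "unmatched_ref": len(match.false_negatives),
    }


@dataclass
class AggregateReport:
    per_datapoint: pd.DataFrame       # one row per grouping-key combination
    per_datapoint_mean: dict          # mean of the per-datapoint ME/MAE/MARE
    per_sample: dict                  # mean/SD over all cycles
    n_rows: int
    invalid: dict = field(default_factory=dict)


def aggregate(rows: pd.DataFrame, group_columns=(), invalid: dict | None = None) -> AggregateReport:
    """Aggregate error rows on the per-datapoint and per-sample levels.

    Per-datapoint: ME/MAE/MARE as the mean over all cycles of each grouping
    key combination (a *datapoint*), then averaged across datapoints with
    equal weight. Per-sample: mean and SD directly over all cycles, weighting
    each cycle equally. Rejected rows (non-positive reference PEP) are
    excluded from both.
    """
    if rows.empty:
        empty = {"me": np.nan, "mae": np.nan, "mare": np.nan}
        return AggregateReport(
            per_datapoint=pd.DataFrame(),
            per_datapoint_mean=dict(empty),
            per_sample={**empty, "me_sd": np.nan, "mae_sd": np.nan, "mare_sd": np.nan},
            n_rows=0,
            invalid=invalid or {},
        )
    ok = rows[~rows["rejected"]] if "rejected" in rows else rows
    per_sample = {
        "me": float(ok["error"].mean()),
        "me_sd": float(ok["error"].std(ddof=1)) if len(ok) > 1 else np.nan,
        "mae": float(ok["abs_error"].mean()),
        "mae_sd": float(ok["abs_error"].std(ddof=1)) if len(ok) > 1 else np.nan,
        "mare": float(ok["abs_rel_error"].mean()),
        "mare_sd": float(ok["abs_rel_error"].std(ddof=1)) if len(ok) > 1 else np.nan,
    }
    group_columns = list(group_columns)
    if group_columns:
        g = ok.groupby(group_columns, sort=False)
        per_dp = g.agg(
            me=("error", "mean"),
            mae=("abs_error", "mean"),
            mare=("abs_rel_error", "mean"),
            n=("error", "size"),
        ).reset_index()
    else:
        per_dp = pd.DataFrame(
            [{"me": per_sample["me"], "mae": per_sample["mae"],
              "mare": per_sample["mare"], "n": len(ok)}]
        )
    per_dp_mean = {
        "me": float(per_dp["me"].mean()),
        "mae": float(per_dp["mae"].mean()),
        "mare": float(per_dp["mare"].mean()),
    }
    return AggregateReport(
        per_datapoint=per_dp,
        per_datapoint_mean=per_dp_mean,
        per_sample=per_sample,
        n_rows=int(len(ok)),
        invalid=invalid or {},
    )


@dataclass
class ICCResult:
    value: float
    ci_low: float
    ci_high: float
    df1: float
    df2: float
    degenerate: bool = False


def icc_3_2(rater1, rater2, alpha: float = 0.05) -> ICCResult:
    """Two-way mixed, absolute-agreement, average-measures ICC for two raters.

    Computed from the two-way ANOVA mean squares (n targets x k=2 raters):

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    The 95% CI follows the single-measure absolute-agreement F bounds with a
    Satterthwaite denominator df, transformed to average measures via
    Spearman-Brown. Requires n >= 5 complete pairs; a series with no
    between-target variance is degenerate (ICC undefined, flagged).
    """
    x = np.asarray(rater1, dtype=float)
    y = np.asarray(rater2, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete paired cases")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (msc - mse) / n
    if denom <= 0 or np.isclose(msr, 0) and np.isclose(denom, 0):
        return ICCResult(np.nan, np.nan, np.nan, n - 1, (n - 1) * (k - 1), degenerate=True)
    icc_ak = (msr - mse) / denom

    # single-measure absolute-agreement bounds (F with Satterthwaite df)
    icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc_a1 / (n * (1 - icc_a1)) if icc_a1 < 1 else np.inf
    b = 1 + k * icc_a1 * (n - 1) / (n * (1 - icc_a1)) if icc_a1 < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        nu = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, nu)
        f_u = stats.f.ppf(1 - alpha / 2, nu, n - 1)
        lo1 = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        sb = lambda r: k * r / (1 + (k - 1) * r)  # Spearman-Brown step-up
        lo, hi = sb(lo1), sb(hi1)
    else:
        nu = (n - 1) * (k - 1)
        lo = hi = np.nan if not np.isclose(icc_ak, 1.0) else 1.0
        if np.isclose(icc_ak, 1.0):
            lo = hi = 1.0
    return ICCResult(float(icc_ak), float(lo), float(hi), float(n - 1), float(nu), False)
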