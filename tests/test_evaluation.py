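import numpy as np
import pandas as pd
import pytest

from pepflow.evaluation import (
    aggregate,
    icc_3_2,
    invalid_counts,
    match_cycles,
    per_sample_errors,
)


def _cycles(starts, ends, **extra):
    df = pd.DataFrame({"start": starts, "end": ends})
    for k, v in extra.items():
        df[k] = v
    return df


class TestMatchCycles:
    def test_identical_tables_all_matched(self):
        ref = _cycles([0, 1000, 2000], [1000, 2000, 3000])
        m = match_cycles(ref, ref.copy(), fs=1000.0)
        assert len(m.pairs) == 3
        assert not m.false_negatives and not m.false_positives

    def test_within_half_tolerance_matched(self):
        ref = _cycles([1000], [2000])
        est = _cycles([1049], [1970])  # +49 ms start, -30 ms end
        m = match_cycles(ref, est, fs=1000.0)
        assert len(m.pairs) == 1

    def test_beyond_half_tolerance_unmatched(self):
        ref = _cycles([1000], [2000])
        est = _cycles([1060], [2000])  # +60 ms start
        m = match_cycles(ref, est, fs=1000.0)
        assert not m.pairs
        assert m.false_negatives == [0]
        assert m.false_positives == [0]

    def test_symmetry_up_to_label_exchange(self):
        ref = _cycles([0, 1000, 2500], [1000, 2000, 3500])
        est = _cycles([10, 2490], [1010, 3490])
        fwd = match_cycles(ref, est, fs=1000.0)
        rev = match_cycles(est, ref, fs=1000.0)
        assert [(b, a) for a, b in fwd.pairs] == rev.pairs
        assert fwd.false_negatives == rev.false_positives
        assert fwd.false_positives == rev.false_negatives


class TestPerSampleErrors:
    def _rows(self, ref_pep, est_pep):
        n = len(ref_pep)
        ref = _cycles(np.arange(n) * 1000, np.arange(1, n + 1) * 1000, pep_ms=ref_pep)
        est = _cycles(np.arange(n) * 1000, np.arange(1, n + 1) * 1000, pep_ms=est_pep)
        m = match_cycles(ref, est, fs=1000.0)
        return per_sample_errors(m, ref, est)

    def test_error_sign_and_are(self):
        rows = self._rows([100.0, 88.0], [90.0, 100.0])
        assert rows.loc[0, "error"] == 10.0
        assert rows.loc[0, "abs_error"] == 10.0
        assert rows.loc[0, "abs_rel_error"] == pytest.approx(0.10)
        assert rows.loc[1, "error"] == -12.0
        assert rows.loc[1, "abs_rel_error"] == pytest.approx(12.0 / 88.0)

    def test_perfect_estimate_zero_errors(self):
        rows = self._rows([100.0], [100.0])
        assert rows.loc[0, "error"] == 0.0

    def test_missing_estimate_excluded_and_counted(self):
        ref = _cycles([0, 1000], [1000, 2000], pep_ms=[100.0, 100.0])
        est = _cycles([0, 1000], [1000, 2000], pep_ms=[np.nan, 90.0], reason=["NoC", ""])
        m = match_cycles(ref, est, fs=1000.0)
        rows = per_sample_errors(m, ref, est)
        assert len(rows) == 1
        counts = invalid_counts(m, est)
        assert counts["invalid"] == 1
        assert counts["per_reason"] == {"NoC": 1}
        assert counts["valid"] + counts["invalid"] == counts["total"]

    def test_nonpositive_reference_rejected_flag(self):
        rows = self._rows([0.0], [90.0])
        assert rows.loc[0, "rejected"]


class TestAggregate:
    def test_single_datapoint_mae(self):
        rows = pd.DataFrame(
            {"error": [10.0, 20.0, 30.0], "abs_error": [10.0, 20.0, 30.0],
             "abs_rel_error": [0.1, 0.2, 0.3], "rejected": False, "dp": "a"}
        )
        rep = aggregate(rows, group_columns=["dp"])
        assert rep.per_sample["mae"] == 20.0
        assert rep.per_datapoint_mean["mae"] == 20.0

    def test_unequal_groups_weighting_distinction(self):
        """Datapoints of sizes 1 and 3 with AEs {10} and {30,30,30}:
        per-datapoint MAE mean is 20, per-sample MAE is 25."""
        rows = pd.DataFrame(
            {
                "error": [10.0, 30.0, 30.0, 30.0],
                "abs_error": [10.0, 30.0, 30.0, 30.0],
                "abs_rel_error": [0.1, 0.3, 0.3, 0.3],
                "rejected": False,
                "dp": ["a", "b", "b", "b"],
            }
        )
        rep = aggregate(rows, group_columns=["dp"])
        assert rep.per_datapoint_mean["mae"] == 20.0
        assert rep.per_sample["mae"] == 25.0

    def test_equal_groups_levels_agree(self):
        rng = np.random.default_rng(2)
        ae = rng.uniform(0, 30, size=12)
        rows = pd.DataFrame(
            {"error": ae, "abs_error": ae, "abs_rel_error": ae / 100.0,
             "rejected": False, "dp": np.repeat(["a", "b", "c"], 4)}
        )
        rep = aggregate(rows, group_columns=["dp"])
        assert rep.per_datapoint_mean["mae"] == pytest.approx(rep.per_sample["mae"])

    def test_mae_bounds_me(self):
        rng = np.random.default_rng(5)
        e = rng.normal(0, 10, size=40)
        rows = pd.DataFrame(
            {"error": e, "abs_error": np.abs(e), "abs_rel_error": np.abs(e) / 100.0,
             "rejected": False}
        )
        rep = aggregate(rows)
        assert rep.per_sample["mae"] >= abs(rep.per_sample["me"])

    def test_empty_input(self):
        rep = aggregate(pd.DataFrame())
        assert rep.n_rows == 0
        assert np.isnan(rep.per_sample["mae"])


def _icc_bruteforce(x, y):
    """Independent ANOVA-table oracle for the two-way absolute-agreement
    average-measures ICC (explicit loops, no shared code path)."""
    n = len(x)
    k = 2
    data = [[x[i], y[i]] for i in range(n)]
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(x) / n, sum(y) / n]
    msr = sum((m - grand) ** 2 for m in row_means) * k / (n - 1)
    msc = sum((m - grand) ** 2 for m in col_means) * n / (k - 1)
    sse = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestICC:
    def test_identical_raters_unity(self):
        r = icc_3_2(np.arange(10.0), np.arange(10.0))
        assert r.value == pytest.approx(1.0)

    def test_shifted_raters_against_anova_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 1.0
        r = icc_3_2(x, y)
        assert r.value == pytest.approx(_icc_bruteforce(x, y), abs=1e-12)
        assert r.ci_low <= r.value <= r.ci_high

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(17)
        r = icc_3_2(rng.normal(size=100), rng.normal(size=100))
        assert abs(r.value) < 0.3

    def test_matches_pingouin_absolute_agreement_average(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        x = rng.normal(100, 15, size=30)
        y = x + rng.normal(0, 5, size=30)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(30), 2),
                "raters": np.repeat(["A", "B"], 30),
                "scores": np.concatenate([x, y]),
            }
        )
        table = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        mask = table["Type"].isin(["ICC2k", "ICC(A,k)"])
        row = table[mask].iloc[0]
        ours = icc_3_2(x, y)
        assert ours.value == pytest.approx(row["ICC"], abs=1e-6)
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        lo, hi = row[ci_col]
        assert ours.ci_low == pytest.approx(lo, abs=0.006)  # pingouin rounds to 2 dp
        assert ours.ci_high == pytest.approx(hi, abs=0.006)

    def test_degenerate_no_between_target_variance(self):
        r = icc_3_2(np.full(8, 5.0), np.full(8, 5.0))
        assert r.degenerate

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_3_2([1.0, 2.0], [1.0, 2.0])
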