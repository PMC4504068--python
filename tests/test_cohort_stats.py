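import itertools
import math

import numpy as np
import pandas as pd
import pytest

from isoratio import (
    CohortError,
    SimConfig,
    estimate_isoform_ratio,
    estimates_to_frame,
    fisher_exact,
    km_logrank,
    paired_log2_difference,
    read_sample_sheet,
    run_cohort_analysis,
    simulate_cohort,
    wilcoxon_rank_sum,
    write_report,
)
from isoratio.cohort_stats import NO_EVENTS, _bh_adjust

from oracles import fisher_2xk_enum_p, km_by_hand, wilcoxon_enum_p


def _estimates(rows):
    df = pd.DataFrame(rows)
    df["flags"] = df["flags"].fillna("") if "flags" in df.columns else ""
    if "log2R" not in df.columns:
        df["log2R"] = np.log2(df["R"] + 1e-6)
    return df


def _sheet(rows):
    base = {"er": "unknown", "her2": "unknown", "pr": "unknown",
            "grade": "unknown", "tp53": "unknown", "rfs_time": np.nan,
            "event": "unknown", "positivity": "unknown"}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestPairedDifference:
    def test_identical_ratio_gives_zero(self):
        est = _estimates([
            {"sample_id": "t", "R": 1.5}, {"sample_id": "n", "R": 1.5},
        ])
        sheet = _sheet([
            {"sample_id": "t", "pair_id": "p1", "tissue": "tumor"},
            {"sample_id": "n", "pair_id": "p1", "tissue": "normal"},
        ])
        deltas, skipped = paired_log2_difference(est, sheet)
        assert len(deltas) == 1 and not skipped
        assert deltas[0].delta == 0.0

    def test_fourfold_ratio_gives_two(self):
        est = _estimates([
            {"sample_id": "t", "R": 2.0}, {"sample_id": "n", "R": 0.5},
        ])
        sheet = _sheet([
            {"sample_id": "t", "pair_id": "p1", "tissue": "tumor"},
            {"sample_id": "n", "pair_id": "p1", "tissue": "normal"},
        ])
        deltas, _ = paired_log2_difference(est, sheet)
        assert deltas[0].delta == pytest.approx(2.0, abs=1e-5)

    def test_undefined_member_skipped(self):
        est = _estimates([
            {"sample_id": "t", "R": 2.0},
            {"sample_id": "n", "R": np.inf, "log2R": np.inf,
             "flags": "R_UNDEFINED_ZERO_F0"},
        ])
        sheet = _sheet([
            {"sample_id": "t", "pair_id": "p1", "tissue": "tumor"},
            {"sample_id": "n", "pair_id": "p1", "tissue": "normal"},
        ])
        deltas, skipped = paired_log2_difference(est, sheet)
        assert not deltas
        assert skipped == ["p1"]

    def test_duplicate_tissue_rejected(self):
        est = _estimates([
            {"sample_id": "t1", "R": 1}, {"sample_id": "t2", "R": 1},
        ])
        sheet = _sheet([
            {"sample_id": "t1", "pair_id": "p1", "tissue": "tumor"},
            {"sample_id": "t2", "pair_id": "p1", "tissue": "tumor"},
        ])
        with pytest.raises(CohortError, match="duplicate tissue"):
            paired_log2_difference(est, sheet)


class TestWilcoxon:
    def test_extreme_small_split(self):
        """A={1,2}, B={3,4}: W=3 is the minimum; two-sided p = 2 * 1/6."""
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.statistic == 3.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_complete_separation_n10(self):
        res = wilcoxon_rank_sum(list(range(1, 6)), list(range(6, 11)))
        assert res.p_value == pytest.approx(2 / 252)

    def test_same_multiset_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_all_identical_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            res = wilcoxon_rank_sum([5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(CohortError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n_a,n_b", [(1, 3), (2, 2), (3, 4), (4, 4), (5, 5)])
    def test_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1, n_a + n_b + 1, dtype=float))
            a, b = pooled[:n_a], pooled[n_a:]
            res = wilcoxon_rank_sum(a, b, mode="exact")
            assert res.p_value == pytest.approx(float(wilcoxon_enum_p(a, b)))

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        res = wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "asymptotic"
        assert 0 < res.p_value <= 1


class TestFisher:
    def test_worked_example(self):
        assert fisher_exact([[3, 1], [1, 3]]).p_value == pytest.approx(34 / 70)

    def test_perfect_independence(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_diagonal_extremes(self):
        assert fisher_exact([[4, 0], [0, 4]]).p_value == pytest.approx(2 / 70)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = fisher_exact([[0, 0], [3, 4]])
        assert res.p_value == 1.0

    def test_odds_ratio_reported_2x2_only(self):
        assert fisher_exact([[3, 1], [1, 3]]).odds_ratio == pytest.approx(9.0)
        assert fisher_exact([[3, 1, 2], [1, 3, 4]]).odds_ratio is None

    def test_random_2x2_match_exact_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert fisher_exact(t).p_value == pytest.approx(
                float(fisher_2xk_enum_p(t)), rel=1e-9
            )

    @pytest.mark.parametrize("table", [
        [[3, 1, 2], [1, 3, 4]],
        [[10, 5, 2], [3, 8, 9]],
        [[20, 15, 8], [10, 18, 25]],
        [[1, 0, 5], [4, 4, 0]],
    ])
    def test_2x3_matches_exact_enumeration(self, table):
        assert fisher_exact(table).p_value == pytest.approx(
            float(fisher_2xk_enum_p(table)), rel=1e-9
        )

    def test_bad_shape(self):
        with pytest.raises(CohortError):
            fisher_exact([[1, 2, 3, 4], [1, 2, 3, 4]])


def _surv_frame(times, events, positivity=None):
    n = len(times)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "rfs_time": times,
        "event": ["relapse" if e else "censored" for e in events],
        "positivity": positivity or ["positive"] * n,
    })


class TestSurvival:
    def test_product_limit_by_hand(self):
        """Events at 1, 2, 3 with no censoring: S = 2/3, 1/3, 0."""
        res = km_logrank(_surv_frame([1, 2, 3], [1, 1, 1]))
        curve = res.curves[0]
        surv_at = dict(zip(curve.times, curve.survival))
        assert surv_at[1.0] == pytest.approx(2 / 3)
        assert surv_at[2.0] == pytest.approx(1 / 3)
        assert surv_at[3.0] == pytest.approx(0.0)

    def test_matches_hand_km_with_censoring(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=40).round(2)
        events = rng.random(40) < 0.6
        res = km_logrank(_surv_frame(times, events))
        t_hand, s_hand = km_by_hand(times, events)
        curve = res.curves[0]
        surv_at = dict(zip(curve.times, curve.survival))
        for t, s in zip(t_hand, s_hand):
            assert surv_at[t] == pytest.approx(s, rel=1e-9)

    def test_survival_monotone_nonincreasing(self):
        rng = np.random.default_rng(9)
        res = km_logrank(
            _surv_frame(rng.exponential(10, 60).round(1), rng.random(60) < 0.5,
                        ["positive"] * 30 + ["negative"] * 30)
        )
        for c in res.curves:
            assert np.all(np.diff(c.survival) <= 1e-12)
            assert c.survival[0] <= 1.0

    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        pos = ["positive"] * 4 + ["negative"] * 4
        # make the two strata literally identical
        df = pd.concat([
            _surv_frame(times[:4], events[:4], ["positive"] * 4),
            _surv_frame(times[:4], events[:4], ["negative"] * 4),
        ])
        res = km_logrank(df)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_all_censored_flat_curve(self):
        res = km_logrank(_surv_frame([5, 6, 7], [0, 0, 0]))
        assert NO_EVENTS in res.flags
        assert math.isnan(res.p_value)
        np.testing.assert_allclose(res.curves[0].survival, 1.0)

    def test_no_survival_data_rejected(self):
        df = _surv_frame([], [])
        with pytest.raises(CohortError):
            km_logrank(df)


class TestBenjaminiHochberg:
    def test_adjustment_matches_definition(self):
        p = {"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.5}
        adj = _bh_adjust(p)
        assert adj["a"] == pytest.approx(0.04)
        assert adj["b"] == pytest.approx(0.04)
        assert adj["c"] == pytest.approx(0.04)
        assert adj["d"] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def default_cohort():
    cohort = simulate_cohort(SimConfig(seed=1))
    ests = [
        estimate_isoform_ratio(c, cohort.model)
        for c in cohort.counts.values()
    ]
    return cohort, estimates_to_frame(ests)


class TestCohortReport:
    def test_identical_tumor_normal_deltas_zero(self):
        rows, est_rows = [], []
        for i in range(5):
            for tissue, suffix in (("tumor", "T"), ("normal", "N")):
                sid = f"p{i}_{suffix}"
                rows.append({"sample_id": sid, "pair_id": f"p{i}", "tissue": tissue})
                est_rows.append({"sample_id": sid, "R": 0.7})
        report = run_cohort_analysis(_estimates(est_rows), _sheet(rows))
        assert report.n_pairs == 5
        assert np.allclose(report.paired["delta"], 0.0)
        assert report.n_pairs_delta_gt1 == 0

    def test_full_report_sections_nonempty(self, default_cohort, tmp_path):
        cohort, est = default_cohort
        report = run_cohort_analysis(est, cohort.sheet)
        assert report.n_pairs == 87
        assert len(report.wilcoxon) == 2
        assert set(report.fisher) == {"grade", "er", "pr", "tp53"}
        assert "all" in report.survival
        assert report.summary
        write_report(report, tmp_path / "bundle")
        for name in ("paired_differences.tsv", "wilcoxon.tsv", "fisher.tsv",
                     "survival_curves.tsv", "summary.txt"):
            assert (tmp_path / "bundle" / name).exists()

    def test_positivity_derived_when_sheet_unknown(self, default_cohort):
        cohort, est = default_cohort
        sheet = cohort.sheet.copy()
        sheet["positivity"] = "unknown"
        # survival columns only exist for tumor rows; positivity is recalled
        report = run_cohort_analysis(est, sheet, positivity_threshold=0.1)
        assert set(report.fisher) == {"grade", "er", "pr", "tp53"}

    def test_unknown_covariates_excluded_per_test(self, default_cohort):
        cohort, est = default_cohort
        sheet = cohort.sheet.copy()
        tumor_idx = sheet.index[sheet["tissue"] == "tumor"][:10]
        sheet.loc[tumor_idx, "tp53"] = "unknown"
        report = run_cohort_analysis(est, sheet)
        assert report.exclusions["fisher_tp53_unknown"] == 10

    def test_bh_switch(self, default_cohort):
        cohort, est = default_cohort
        report = run_cohort_analysis(est, cohort.sheet, bh_correction=True)
        assert report.fisher_bh is not None
        for k, adj in report.fisher_bh.items():
            assert adj >= report.fisher[k].p_value - 1e-12


class TestSampleSheetIO:
    def test_round_trip_and_validation(self, tmp_path):
        cohort = simulate_cohort(SimConfig(seed=3, n_pairs=5))
        from isoratio import write_cohort

        write_cohort(cohort, tmp_path)
        sheet = read_sample_sheet(tmp_path / "sample_sheet.tsv")
        assert len(sheet) == 10
        assert set(sheet["tissue"]) == {"tumor", "normal"}

    def test_bad_token_rejected(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        header = "\t".join([
            "sample_id", "pair_id", "tissue", "er", "her2", "pr", "grade",
            "tp53", "rfs_time", "event", "positivity",
        ])
        row = "s1\tp1\tTUMOR\tpos\tneg\tpos\t2\tWT\t\tunknown\tunknown"
        path.write_text(header + "\n" + row + "\n")
        with pytest.raises(CohortError, match="tissue"):
            read_sample_sheet(path)

    def test_time_without_event_rejected(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        header = "\t".join([
            "sample_id", "pair_id", "tissue", "er", "her2", "pr", "grade",
            "tp53", "rfs_time", "event", "positivity",
        ])
        row = "s1\tp1\ttumor\tpos\tneg\tpos\t2\tWT\t12.5\tunknown\tunknown"
        path.write_text(header + "\n" + row + "\n")
        with pytest.raises(CohortError, match="rfs_time"):
            read_sample_sheet(path)
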