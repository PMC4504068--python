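"""Cohort-level analyses around the isoform ratio.

Four analyses, mirroring how alternate-transcript biomarkers are
typically evaluated in a tumor/normal cohort:

* paired tumor − normal differences in log2 R,
* Wilcoxon rank-sum comparison of R between receptor-defined subgroups,
* Fisher exact association of variant positivity with clinical factors,
* Kaplan–Meier relapse-free survival stratified by positivity, with a
  two-group log-rank test.

All tests are two-sided.  Samples with an unknown value in a tested
covariate are excluded from that test only, never imputed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


class CohortError(ValueError):
    pass


SHEET_COLUMNS = [
    "sample_id", "pair_id", "tissue", "er", "her2", "pr", "grade", "tp53",
    "rfs_time", "event", "positivity",
]

_TOKENS = {
    "tissue": {"tumor", "normal"},
    "er": {"pos", "neg", "unknown"},
    "her2": {"pos", "neg", "unknown"},
    "pr": {"pos", "neg", "unknown"},
    "grade": {"1", "2", "3", "unknown"},
    "tp53": {"WT", "Mut", "unknown"},
    "event": {"relapse", "censored", "unknown"},
    "positivity": {"positive", "negative", "unknown"},
}


@dataclass(frozen=True)
class SampleRecord:
    """Clinical covariates and pairing for one sample."""

    sample_id: str
    tissue: str
    pair_id: str | None = None
    er: str = "unknown"
    her2: str = "unknown"
    pr: str = "unknown"
    grade: str = "unknown"
    tp53: str = "unknown"
    rfs_time: float | None = None
    event: str = "unknown"
    positivity: str = "unknown"


@dataclass(frozen=True)
class PairedDifference:
    pair_id: str
    delta: float  # log2 R(tumor) - log2 R(normal)


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    statistic: float  # rank sum W of the first group
    p_value: float
    method: str


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float | None  # 2x2 tables only
    table: tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class SurvivalCurve:
    label: str
    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray


@dataclass(frozen=True)
class SurvivalResult:
    curves: tuple[SurvivalCurve, ...]
    logrank_statistic: float
    p_value: float
    flags: frozenset[str] = frozenset()


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical sample sheet (TSV, header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(
            f"sample sheet {path} lacks column(s): {', '.join(sorted(missing))}"
        )
    df = df.fillna("unknown")
    for col, allowed in _TOKENS.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            val = df.loc[bad, col].iloc[0]
            raise CohortError(
                f"sample sheet {path}: invalid {col!r} value {val!r} "
                f"(allowed: {', '.join(sorted(allowed))})"
            )
    df["rfs_time"] = pd.to_numeric(df["rfs_time"].replace("unknown", np.nan))
    has_time = df["rfs_time"].notna()
    has_event = df["event"] != "unknown"
    if (has_time ^ has_event).any():
        sid = df.loc[has_time ^ has_event, "sample_id"].iloc[0]
        raise CohortError(
            f"sample sheet {path}: sample {sid!r} has rfs_time without event "
            "status (or vice versa)"
        )
    if (df.loc[has_time, "rfs_time"] < 0).any():
        raise CohortError(f"sample sheet {path}: negative rfs_time")
    return df


# ---------------------------------------------------------------------------
# paired differences


def paired_log2_difference(
    estimates: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[list[PairedDifference], list[str]]:
    """log2 R(tumor) − log2 R(normal) per pair.

    Returns the computable differences and the pair ids that were
    skipped (a member missing an estimate, or a member whose ratio is
    the undefined sentinel).  Pairs with a duplicated tissue raise.
    """
    est = estimates.set_index("sample_id")
    deltas: list[PairedDifference] = []
    skipped: list[str] = []
    paired = sheet[(sheet["pair_id"] != "unknown") & sheet["pair_id"].notna()]
    for pair_id, grp in paired.groupby("pair_id", sort=True):
        tumors = grp[grp["tissue"] == "tumor"]["sample_id"].tolist()
        normals = grp[grp["tissue"] == "normal"]["sample_id"].tolist()
        if len(tumors) > 1 or len(normals) > 1:
            raise CohortError(f"pair {pair_id!r}: duplicate tissue within pair")
        if len(tumors) != 1 or len(normals) != 1:
            skipped.append(str(pair_id))
            continue
        t_id, n_id = tumors[0], normals[0]
        if t_id not in est.index or n_id not in est.index:
            skipped.append(str(pair_id))
            continue
        log2s = []
        undefined = False
        for sid in (t_id, n_id):
            row = est.loc[sid]
            flags = str(row.get("flags", "") or "")
            if "R_UNDEFINED_ZERO_F0" in flags or not math.isfinite(row["log2R"]):
                undefined = True
                break
            log2s.append(float(row["log2R"]))
        if undefined:
            skipped.append(str(pair_id))
            continue
        deltas.append(PairedDifference(pair_id=str(pair_id), delta=log2s[0] - log2s[1]))
    return deltas, skipped


# ---------------------------------------------------------------------------
# rank-sum test

#: largest combined n for which the exact null distribution is used in auto mode
EXACT_WILCOXON_MAX_N = 12


def wilcoxon_rank_sum(
    values_a, values_b, mode: str = "auto", labels: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    ``mode='auto'`` uses the exact permutation null when the combined
    sample is small (<= 12) and tie-free, otherwise the normal
    approximation with tie and continuity corrections.  The statistic
    reported is the rank sum W of the first group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CohortError("wilcoxon_rank_sum: both groups must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise CohortError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        W = float(stats.rankdata(pooled)[: a.size].sum())
        return GroupComparison(labels, (a.size, b.size), W, 1.0, "degenerate")
    if mode == "exact" or (mode == "auto" and not has_ties
                           and a.size + b.size <= EXACT_WILCOXON_MAX_N):
        method = "exact"
        if has_ties:
            warnings.warn("ties present; exact rank-sum p-values ignore ties")
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    W = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return GroupComparison(labels, (a.size, b.size), W, float(res.pvalue), method)


# ---------------------------------------------------------------------------
# Fisher exact test, 2 x k by full enumeration


def _log_table_prob(table: np.ndarray, log_col_fact: float, log_n_fact: float) -> float:
    """Log multivariate hypergeometric probability of a 2xk table with fixed margins."""
    row = table.sum(axis=1)
    return (
        gammaln(row[0] + 1) + gammaln(row[1] + 1) + log_col_fact - log_n_fact
        - gammaln(table + 1.0).sum()
    )


def fisher_exact(table) -> FisherResult:
    """Exact two-sided Fisher test for a 2x2 or 2x3 contingency table.

    The p-value sums the probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    (enumeration; cohort-scale margins keep this cheap).  For 2x2 tables
    the conditional odds ratio is reported.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise CohortError(f"fisher_exact expects a 2x2 or 2x3 table, got {t.shape}")
    if (t < 0).any():
        raise CohortError("fisher_exact: negative cell count")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    table_tuple = tuple(tuple(int(x) for x in r) for r in t)
    if (row == 0).any() or (col == 0).any():
        warnings.warn("zero margin; Fisher p = 1")
        return FisherResult(p_value=1.0, odds_ratio=None, table=table_tuple)

    odds_ratio = None
    if t.shape[1] == 2:
        res = stats.fisher_exact(t)
        odds_ratio = float(res.statistic)

    log_col_fact = float(gammaln(col + 1.0).sum())
    log_n_fact = float(gammaln(n + 1))
    obs_logp = _log_table_prob(t.astype(float), log_col_fact, log_n_fact)
    # enumerate the first row; the second is fixed by the column margins
    ranges = [range(int(min(row[0], c)) + 1) for c in col[:-1]]
    total_p = 0.0
    for first_cells in itertools.product(*ranges):
        last = row[0] - sum(first_cells)
        if last < 0 or last > col[-1]:
            continue
        top = np.array([*first_cells, last], dtype=float)
        cand = np.vstack([top, col - top])
        logp = _log_table_prob(cand, log_col_fact, log_n_fact)
        if logp <= obs_logp + 1e-9:  # tolerance for float ties
            total_p += math.exp(logp)
    return FisherResult(p_value=min(total_p, 1.0), odds_ratio=odds_ratio,
                        table=table_tuple)


# ---------------------------------------------------------------------------
# survival

NO_EVENTS = "NO_EVENTS"


def km_logrank(records: pd.DataFrame, strata_col: str = "positivity") -> SurvivalResult:
    """Kaplan–Meier curves per stratum plus the log-rank test.

    ``records`` must carry ``rfs_time`` (months), ``event``
    (relapse/censored) and the stratifying column.  At equal times
    events precede censorings, the standard product-limit convention.
    """
    df = records[
        records["rfs_time"].notna()
        & (records["event"] != "unknown")
        & (records[strata_col] != "unknown")
    ].copy()
    if df.empty:
        raise CohortError("km_logrank: no records with survival data")
    df["observed"] = (df["event"] == "relapse").astype(int)
    labels = sorted(df[strata_col].unique())
    if any((df[strata_col] == lab).sum() == 0 for lab in labels):
        raise CohortError("km_logrank: empty stratum")

    curves = []
    for lab in labels:
        sub = df[df[strata_col] == lab]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["rfs_time"], event_observed=sub["observed"], label=str(lab))
        tab = kmf.event_table
        curves.append(
            SurvivalCurve(
                label=str(lab),
                times=tab.index.to_numpy(dtype=float),
                at_risk=tab["at_risk"].to_numpy(dtype=int),
                events=tab["observed"].to_numpy(dtype=int),
                survival=kmf.survival_function_[str(lab)].to_numpy(dtype=float),
            )
        )

    flags: set[str] = set()
    if df["observed"].sum() == 0 or len(labels) < 2:
        if df["observed"].sum() == 0:
            flags.add(NO_EVENTS)
        return SurvivalResult(tuple(curves), math.nan, math.nan, frozenset(flags))
    lr = multivariate_logrank_test(df["rfs_time"], df[strata_col], df["observed"])
    return SurvivalResult(
        tuple(curves), float(lr.test_statistic), float(lr.p_value), frozenset(flags)
    )


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CohortReport:
    paired: pd.DataFrame
    n_pairs: int
    n_pairs_delta_gt1: int
    skipped_pairs: list[str]
    wilcoxon: dict[str, GroupComparison]
    fisher: dict[str, FisherResult]
    fisher_bh: dict[str, float] | None
    survival: dict[str, SurvivalResult]
    exclusions: dict[str, int]
    summary: str = ""


def _bh_adjust(pvals: dict[str, float]) -> dict[str, float]:
    keys = list(pvals)
    p = np.array([pvals[k] for k in keys])
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, p[i] * m / (rank_pos + 1))
        adj[i] = running
    return dict(zip(keys, adj.tolist()))


def run_cohort_analysis(
    estimates: pd.DataFrame,
    sheet: pd.DataFrame,
    *,
    positivity_threshold: float = 0.1,
    delta_cutoff: float = 1.0,
    bh_correction: bool = False,
) -> CohortReport:
    """Full cohort report: paired deltas, subgroup rank tests, clinical
    associations of positivity, and survival stratified by positivity.

    Positivity comes from the sample sheet when annotated there (the
    assay-based call); otherwise it is derived from each tumor's R at
    ``positivity_threshold``.
    """
    est = estimates.set_index("sample_id")
    sheet = sheet.copy()
    exclusions: dict[str, int] = {}

    # paired tumor/normal differences
    deltas, skipped = paired_log2_difference(estimates, sheet)
    paired_df = pd.DataFrame(
        [{"pair_id": d.pair_id, "delta": d.delta} for d in deltas],
        columns=["pair_id", "delta"],
    )
    n_gt1 = int((paired_df["delta"] > delta_cutoff).sum()) if len(paired_df) else 0
    exclusions["paired_skipped"] = len(skipped)

    # attach R and positivity to tumor records
    tumors = sheet[sheet["tissue"] == "tumor"].copy()
    tumors["R"] = [
        float(est.loc[s, "R"]) if s in est.index else np.nan
        for s in tumors["sample_id"]
    ]
    if (tumors["positivity"] == "unknown").all():
        def _call(row):
            if not np.isfinite(row["R"]):
                sid = row["sample_id"]
                if sid in est.index and "R_UNDEFINED_ZERO_F0" in str(
                    est.loc[sid].get("flags", "")
                ):
                    return "positive"
                return "unknown"
            return "positive" if row["R"] >= positivity_threshold else "negative"
        tumors["positivity"] = tumors.apply(_call, axis=1)

    # receptor-subgroup rank tests on R (inf-sentinel samples excluded)
    wilcoxon: dict[str, GroupComparison] = {}
    testable = tumors[np.isfinite(tumors["R"])]
    exclusions["wilcoxon_nonfinite_R"] = int(len(tumors) - len(testable))
    contrasts = {
        "ERpos_Her2neg_vs_ERneg_Her2neg": (
            (testable["er"] == "pos") & (testable["her2"] == "neg"),
            (testable["er"] == "neg") & (testable["her2"] == "neg"),
            ("ER+/Her2-", "ER-/Her2-"),
        ),
        "ERneg_Her2pos_vs_ERneg_Her2neg": (
            (testable["er"] == "neg") & (testable["her2"] == "pos"),
            (testable["er"] == "neg") & (testable["her2"] == "neg"),
            ("ER-/Her2+", "ER-/Her2-"),
        ),
    }
    for name, (mask_a, mask_b, labs) in contrasts.items():
        va, vb = testable.loc[mask_a, "R"], testable.loc[mask_b, "R"]
        if len(va) and len(vb):
            wilcoxon[name] = wilcoxon_rank_sum(va, vb, labels=labs)

    # Fisher association of positivity with clinical factors
    fisher: dict[str, FisherResult] = {}
    called = tumors[tumors["positivity"] != "unknown"]
    exclusions["positivity_unknown"] = int(len(tumors) - len(called))
    factor_levels = {"grade": ["1", "2", "3"], "er": ["pos", "neg"],
                     "pr": ["pos", "neg"], "tp53": ["WT", "Mut"]}
    for factor, levels in factor_levels.items():
        sub = called[called[factor].isin(levels)]
        exclusions[f"fisher_{factor}_unknown"] = int(len(called) - len(sub))
        if sub.empty:
            continue
        tab = np.array(
            [
                [int(((sub["positivity"] == pos_neg) & (sub[factor] == lev)).sum())
                 for lev in levels]
                for pos_neg in ("positive", "negative")
            ]
        )
        fisher[factor] = fisher_exact(tab)
    fisher_bh = (
        _bh_adjust({k: v.p_value for k, v in fisher.items()}) if bh_correction else None
    )

    # survival by positivity: overall and within ER subsets
    survival: dict[str, SurvivalResult] = {}
    surv_base = called[
        called["rfs_time"].notna() & (called["event"] != "unknown")
    ]
    exclusions["survival_missing"] = int(len(called) - len(surv_base))
    subsets = {
        "all": surv_base,
        "ER_pos": surv_base[surv_base["er"] == "pos"],
        "ER_neg": surv_base[surv_base["er"] == "neg"],
    }
    for name, sub in subsets.items():
        if len(sub) and sub["positivity"].nunique() == 2:
            survival[name] = km_logrank(sub)

    report = CohortReport(
        paired=paired_df,
        n_pairs=len(paired_df),
        n_pairs_delta_gt1=n_gt1,
        skipped_pairs=skipped,
        wilcoxon=wilcoxon,
        fisher=fisher,
        fisher_bh=fisher_bh,
        survival=survival,
        exclusions=exclusions,
    )
    report.summary = _format_summary(report, delta_cutoff)
    return report


def _format_summary(report: CohortReport, delta_cutoff: float) -> str:
    lines = ["# Cohort analysis summary", ""]
    lines.append(
        f"Paired tumor/normal: {report.n_pairs} pairs analyzed, "
        f"{len(report.skipped_pairs)} skipped; log2-ratio difference > "
        f"{delta_cutoff:g} in {report.n_pairs_delta_gt1} of {report.n_pairs} pairs."
    )
    for name, gc in report.wilcoxon.items():
        lines.append(
            f"Wilcoxon {gc.group_labels[0]} (n={gc.n_per_group[0]}) vs "
            f"{gc.group_labels[1]} (n={gc.n_per_group[1]}): W={gc.statistic:.1f}, "
            f"p={gc.p_value:.3g} ({gc.method})"
        )
    for factor, fr in report.fisher.items():
        or_txt = f", OR={fr.odds_ratio:.3g}" if fr.odds_ratio is not None else ""
        lines.append(f"Fisher exact, positivity vs {factor}: p={fr.p_value:.3g}{or_txt}")
        if report.fisher_bh:
            lines[-1] += f" (BH-adjusted p={report.fisher_bh[factor]:.3g})"
    for name, sr in report.survival.items():
        ns = {c.label: int(c.at_risk[0]) for c in sr.curves}
        lines.append(
            f"Log-rank ({name}): chi2={sr.logrank_statistic:.3g}, p={sr.p_value:.3g}; "
            f"n per stratum {ns}"
        )
    lines.append("")
    lines.append("Per-stage exclusions: "
                 + ", ".join(f"{k}={v}" for k, v in report.exclusions.items()))
    return "\n".join(lines)


def write_report(report: CohortReport, out_dir: str | Path, *, plots: bool = False) -> None:
    """Write the report bundle: TSV tables, a plain-text summary, optional SVG plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.paired.to_csv(out / "paired_differences.tsv", sep="\t", index=False)
    rows = [
        {"contrast": k, "group_a": v.group_labels[0], "group_b": v.group_labels[1],
         "n_a": v.n_per_group[0], "n_b": v.n_per_group[1], "W": v.statistic,
         "p_value": v.p_value, "method": v.method}
        for k, v in report.wilcoxon.items()
    ]
    pd.DataFrame(rows).to_csv(out / "wilcoxon.tsv", sep="\t", index=False)
    rows = [
        {"factor": k, "p_value": v.p_value,
         "bh_p": report.fisher_bh[k] if report.fisher_bh else "",
         "odds_ratio": "" if v.odds_ratio is None else v.odds_ratio,
         "table": str(v.table)}
        for k, v in report.fisher.items()
    ]
    pd.DataFrame(rows).to_csv(out / "fisher.tsv", sep="\t", index=False)
    rows = []
    for name, sr in report.survival.items():
        for c in sr.curves:
            for t, r, d, s in zip(c.times, c.at_risk, c.events, c.survival):
                rows.append({"subset": name, "stratum": c.label, "time": t,
                             "at_risk": r, "events": d, "survival": s})
    pd.DataFrame(rows).to_csv(out / "survival_curves.tsv", sep="\t", index=False)
    (out / "summary.txt").write_text(report.summary + "\n")
    if plots:
        _plot_km(report, out)


def _plot_km(report: CohortReport, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, sr in report.survival.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        for c in sr.curves:
            ax.step(np.r_[0, c.times], np.r_[1.0, c.survival], where="post",
                    label=f"{c.label} (n={int(c.at_risk[0])})")
        ax.set_xlabel("time (months)")
        ax.set_ylabel("relapse-free survival")
        ax.set_ylim(0, 1.05)
        ax.legend()
        ax.set_title(f"{name}: log-rank p={sr.p_value:.3g}")
        fig.tight_layout()
        fig.savefig(out / f"km_{name}.svg")
        plt.close(fig)
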