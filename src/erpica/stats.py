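"""Student's t comparisons between the two groups.

Three entry points: the pooled two-sample t computed from printed
summary statistics (mean, sd, n per group), the same test from raw
per-subject values, and a pointwise t along a component time course
with a p < alpha significance mask (uncorrected, matching the
reference analysis style).

Pooled-variance (classic Student) rather than Welch throughout: the
reference cohort reports df = 146 = 74 + 74 - 2, which implies pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "TTestResult",
    "ttest_from_summary",
    "ttest_from_raw",
    "ttest_pointwise",
    "ADHD_PSYCHOMETRIC_TABLE",
    "VCPT_PERFORMANCE_TABLE",
    "REFERENCE_T_VALUES",
]


@dataclass(frozen=True)
class SummaryStats:
    """Printed per-group summary: mean (sd), n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def ttest_from_summary(a: SummaryStats, b: SummaryStats) -> TTestResult:
    """Pooled two-sample t from group summaries.

    t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b)), with the
    pooled variance s_p^2 weighting each group's sd^2 by its degrees of
    freedom; df = n_a + n_b - 2.  Two equal-mean degenerate groups give
    t = 0; unequal means with zero pooled variance are an error.
    """
    df = a.n + b.n - 2
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means: t is infinite")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return TTestResult(t=float(t), df=df, p=float(p))


def ttest_from_raw(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Pooled two-sample t from raw per-subject values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = SummaryStats(float(x.mean()), float(x.std(ddof=1)), x.size)
    b = SummaryStats(float(y.mean()), float(y.std(ddof=1)), y.size)
    return ttest_from_summary(a, b)


def ttest_pointwise(
    dataset,
    model,
    component: int,
    channel: str,
    condition: str = "NOGO",
    alpha: float = 0.05,
    groups: tuple[str, str] = ("case", "control"),
):
    """Pointwise group comparison along one component's time course.

    At every time sample, the component back-projection value at the
    given electrode is compared between groups with the pooled t-test.
    Returns (t, p, mask) arrays; mask = (p < alpha), uncorrected.
    """
    ch = list(model.channel_order).index(channel)
    per_group: dict[str, list[np.ndarray]] = {g: [] for g in groups}
    for sid in dataset.subject_ids:
        g = dataset.group_of(sid)
        if g in per_group:
            erp = dataset.get(sid, condition)
            per_group[g].append(model.project(component, erp.data)[ch])
    for g, traces in per_group.items():
        if len(traces) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects in condition {condition!r}")
    A = np.stack(per_group[groups[0]])
    B = np.stack(per_group[groups[1]])
    t, p = sps.ttest_ind(A, B, axis=0, equal_var=True)
    return np.asarray(t), np.asarray(p), np.asarray(p) < alpha


# ---------------------------------------------------------------------------
# reference summary tables of the adult ADHD / control cohort (n = 74 + 74),
# used as worked-example inputs: variable -> (case group, control group)
# ---------------------------------------------------------------------------

_N = 74

ADHD_PSYCHOMETRIC_TABLE = {
    "current_inattentive_symptoms": (SummaryStats(6.12, 2.00, _N), SummaryStats(0.07, 0.25, _N)),
    "current_hyperactive_impulsive_symptoms": (SummaryStats(4.51, 2.27, _N), SummaryStats(0.08, 0.28, _N)),
    "current_total_adhd_symptoms": (SummaryStats(10.64, 3.33, _N), SummaryStats(0.15, 0.39, _N)),
    "bsi_general_severity_index": (SummaryStats(1.30, 0.67, _N), SummaryStats(0.17, 0.14, _N)),
}

VCPT_PERFORMANCE_TABLE = {
    "omission_errors_go": (SummaryStats(4.36, 4.93, _N), SummaryStats(1.23, 1.71, _N)),
    "rt_go_ms": (SummaryStats(420.41, 83.81, _N), SummaryStats(419.42, 94.06, _N)),
    "rt_standard_error_ms": (SummaryStats(11.03, 3.83, _N), SummaryStats(8.20, 2.55, _N)),
    "commission_errors_nogo": (SummaryStats(0.64, 1.02, _N), SummaryStats(0.45, 0.80, _N)),
}

#: t(146) values reported for the significant contrasts of the two tables
REFERENCE_T_VALUES = {
    "current_inattentive_symptoms": 25.838,
    "current_hyperactive_impulsive_symptoms": 16.668,
    "current_total_adhd_symptoms": 26.940,
    "bsi_general_severity_index": 14.219,
    "omission_errors_go": 5.125,
    "rt_standard_error_ms": 5.275,
}


def read_summary_table(path) -> dict[str, dict[str, SummaryStats]]:
    """Read a summary-statistics CSV with columns
    group, variable, mean, sd, n into {variable: {group: SummaryStats}}."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"group", "variable", "mean", "sd", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary table lacks columns: {sorted(missing)}")
    out: dict[str, dict[str, SummaryStats]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["variable"]), {})[str(row["group"])] = SummaryStats(
            float(row["mean"]), float(row["sd"]), int(row["n"])
        )
    return out


def write_ttest_results(results: dict[str, TTestResult], path) -> None:
    """Write {variable: TTestResult} as a CSV with columns variable, t, df, p."""
    import pandas as pd

    pd.DataFrame(
        [{"variable": k, "t": r.t, "df": r.df, "p": r.p} for k, r in results.items()]
    ).to_csv(path, index=False)


def reference_table_ttests() -> dict[str, TTestResult]:
    """Recompute the pooled t for every row of the reference tables."""
    out = {}
    for table in (ADHD_PSYCHOMETRIC_TABLE, VCPT_PERFORMANCE_TABLE):
        for name, (case_s, control_s) in table.items():
            out[name] = ttest_from_summary(case_s, control_s)
    return out
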