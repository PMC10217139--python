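"""Group statistics for the imaging readouts.

Per-image measurements are aggregated to per-subject means within each
condition (control / LPS day 1 / day 4 / day 8), then analysed with the
standard workflow for this kind of study: Shapiro–Wilk normality check,
one-way ANOVA — repeated-measures for longitudinal intravital data where
the same animals are imaged across conditions, ordinary for independent
confocal cohorts — followed by Tukey's HSD (paired designs) or Welch's
unequal-variance t tests (independent designs), plus percent-change
summaries against a baseline condition.

Implementation leans on scipy / statsmodels / pingouin; this module fixes
the design mapping, the degenerate-input behaviour and the report shape.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclasses.dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    comparison: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk W and p; requires n ≥ 3 and a non-constant sample."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), (float(len(x)),), float(p))


def anova_oneway(
    groups: dict[str, Sequence[float]], repeated: bool = False
) -> TestResult:
    """One-way ANOVA F test across conditions.

    ``groups`` maps condition label -> per-subject values.  For the
    repeated-measures design the i-th value of every condition must belong
    to the same subject (balanced), and the error term is the
    subject-by-condition interaction.  A zero effect with zero error
    (identical values per subject everywhere) reports F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(a) < 2 for a in arrays.values()):
        raise ValueError("need at least two subjects per condition")
    if not repeated:
        f, p = sps.f_oneway(*arrays.values())
        k = len(arrays)
        n = sum(len(a) for a in arrays.values())
        return TestResult("anova_oneway", float(f), (k - 1.0, n - 1.0 * k), float(p))
    ns = {len(a) for a in arrays.values()}
    if len(ns) > 1:
        raise ValueError("repeated-measures design must be balanced")
    data = np.column_stack(list(arrays.values()))  # subjects × conditions
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    if ss_cond <= 0:
        return TestResult("rm_anova", 0.0, (float(df1), float(df2)), 1.0)
    if ss_err <= 0:
        return TestResult("rm_anova", float("inf"), (float(df1), float(df2)), 0.0)
    f = (ss_cond / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("rm_anova", float(f), (float(df1), float(df2)), p)


def tukey_hsd(groups: dict[str, Sequence[float]]) -> list[TestResult]:
    """All pairwise comparisons with studentized-range adjusted p."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    res = sps.tukey_hsd(*arrays)
    out: list[TestResult] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(
                TestResult(
                    "tukey_hsd",
                    float(res.statistic[i, j]),
                    (float(len(arrays[i])), float(len(arrays[j]))),
                    float(min(max(res.pvalue[i, j], 0.0), 1.0)),
                    comparison=f"{labels[i]} vs {labels[j]}",
                )
            )
    return out


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's two-sided t test with Welch–Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), (float(res.df),), float(res.pvalue))


def percent_change(baseline: float, value: float) -> float:
    """Signed percent change 100·(value − baseline)/baseline, 1-decimal."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (value - baseline) / baseline, 1)


@dataclasses.dataclass(frozen=True)
class Design:
    """Study design declaration for :func:`build_report`."""

    condition_order: tuple[str, ...]
    baseline: str
    paired: bool = False

    def __post_init__(self) -> None:
        if self.baseline not in self.condition_order:
            raise ValueError("baseline must be one of the conditions")


def build_report(
    measurements: pd.DataFrame,
    design: Design,
    value_column: str = "value",
) -> dict[str, object]:
    """Aggregate, test and summarise a measurement table.

    ``measurements`` needs columns ``condition``, ``subject`` and the value
    column; replicate rows per subject are averaged first.  Returns a dict
    with a per-condition summary frame, the omnibus test, pairwise results
    and percent changes versus the baseline condition.
    """
    required = {"condition", "subject", value_column}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    present = set(measurements["condition"])
    missing = [c for c in design.condition_order if c not in present]
    if missing:
        raise ValueError(f"conditions missing from data: {missing}")

    per_subject = (
        measurements.groupby(["condition", "subject"])[value_column]
        .mean()
        .reset_index()
    )
    groups: dict[str, np.ndarray] = {}
    subjects: dict[str, list] = {}
    for cond in design.condition_order:
        sub = per_subject[per_subject["condition"] == cond]
        groups[cond] = sub[value_column].to_numpy()
        subjects[cond] = sorted(sub["subject"])
    if design.paired:
        ref = subjects[design.condition_order[0]]
        if any(subjects[c] != ref for c in design.condition_order[1:]):
            raise ValueError("paired design requires identical subjects per condition")
        # align values by subject order
        for cond in design.condition_order:
            sub = per_subject[per_subject["condition"] == cond]
            groups[cond] = (
                sub.set_index("subject").loc[ref, value_column].to_numpy()
            )

    summary = pd.DataFrame(
        {
            "condition": list(design.condition_order),
            "n": [len(groups[c]) for c in design.condition_order],
            "mean": [float(np.mean(groups[c])) for c in design.condition_order],
            "sd": [
                float(np.std(groups[c], ddof=1)) if len(groups[c]) > 1 else float("nan")
                for c in design.condition_order
            ],
        }
    )
    base_mean = float(np.mean(groups[design.baseline]))
    summary["percent_change_vs_baseline"] = [
        percent_change(base_mean, m) if base_mean > 0 else float("nan")
        for m in summary["mean"]
    ]

    report: dict[str, object] = {"summary": summary, "normality": {}}
    for cond, vals in groups.items():
        if len(vals) >= 3 and np.ptp(vals) > 0:
            report["normality"][cond] = shapiro_wilk(vals)

    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        report["omnibus"] = anova_oneway(groups, repeated=design.paired)
        if design.paired:
            report["pairwise"] = tukey_hsd(groups)
        else:
            report["pairwise"] = [
                dataclasses.replace(
                    welch_t(groups[a], groups[b]), comparison=f"{a} vs {b}"
                )
                for i, a in enumerate(design.condition_order)
                for b in design.condition_order[i + 1 :]
            ]
    else:
        report["omnibus"] = None
        report["pairwise"] = []
        report["warning"] = "fewer than two usable conditions: tests skipped"
    return report


def format_report(report: dict[str, object]) -> str:
    """Human-readable text rendering of :func:`build_report` output."""
    lines = ["Per-condition summary (mean ± SD):"]
    for _, row in report["summary"].iterrows():
        lines.append(
            f"  {row['condition']}: {row['mean']:.4g} ± {row['sd']:.4g} "
            f"(n={int(row['n'])}, {row['percent_change_vs_baseline']:+.1f}% vs baseline)"
        )
    omni = report.get("omnibus")
    if omni is not None:
        lines.append(
            f"{omni.test}: F({omni.df[0]:.0f}, {omni.df[1]:.0f}) = "
            f"{omni.statistic:.4g}, p = {omni.p_value:.4g}"
        )
    for r in report.get("pairwise", []):
        lines.append(f"  {r.comparison}: {r.test} p = {r.p_value:.4g}")
    if "warning" in report:
        lines.append(f"warning: {report['warning']}")
    return "\n".join(lines)
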