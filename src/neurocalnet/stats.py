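"""Normality-driven test dispatch and longitudinal report assembly.

Group comparisons follow the common physiology workflow: check each
sample for normality (Lilliefors-corrected Kolmogorov–Smirnov by
default), then run a t-test (paired or unpaired) when both samples pass,
or the rank-based equivalent (Wilcoxon signed-rank / Mann–Whitney U)
otherwise.  All tests are two-sided at alpha = 0.05; no multiple-testing
correction is applied by default (per-comparison reporting), with a
Benjamini–Hochberg switch available on the longitudinal report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "dispatch_compare", "longitudinal_report"]


@dataclass
class GroupComparison:
    sample_a: np.ndarray
    sample_b: np.ndarray
    paired: bool
    chosen_test: str
    statistic: float
    p_value: float
    normality_p_a: float
    normality_p_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _normality_p(x: np.ndarray, method: str) -> float:
    if np.ptp(x) == 0:
        return 0.0  # a point mass is as non-normal as it gets
    if method == "lilliefors" and x.size < 4:
        method = "ks"  # lilliefors critical values need n >= 4
    if method == "lilliefors":
        return float(lilliefors(x, dist="norm")[1])
    if method == "ks":
        return float(sps.kstest((x - x.mean()) / x.std(ddof=1), "norm").pvalue)
    raise ValueError("normality method must be 'lilliefors' or 'ks'")


def dispatch_compare(
    a,
    b,
    paired: bool = False,
    alpha_norm: float = 0.05,
    normality: str = "lilliefors",
) -> GroupComparison:
    """Compare two samples, choosing the test from a normality pre-check.

    Both samples normal at ``alpha_norm`` -> t-test (paired/unpaired);
    otherwise Wilcoxon signed-rank (paired) or Mann–Whitney U (unpaired).
    Degenerate inputs (zero spread and identical values, or paired with
    all-zero differences) return statistic 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal lengths")
    pa = _normality_p(a, normality)
    pb = _normality_p(b, normality)
    both_normal = pa > alpha_norm and pb > alpha_norm

    if paired and np.all(a == b):
        return GroupComparison(a, b, paired, "degenerate", 0.0, 1.0, pa, pb)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
        return GroupComparison(a, b, paired, "degenerate", 0.0, p, pa, pb)

    if both_normal:
        if paired:
            stat, p = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            stat, p = sps.ttest_ind(a, b)
            name = "unpaired t-test"
    else:
        if paired:
            stat, p = sps.wilcoxon(a, b, zero_method="wilcox")
            name = "Wilcoxon signed-rank"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
    return GroupComparison(a, b, paired, name, float(stat), float(p), pa, pb)


def longitudinal_report(
    data: pd.DataFrame,
    reference_group: str | None = None,
    baseline_timepoint: str = "pre",
    alpha_norm: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Tidy per-timepoint x per-group summary with between-group comparisons.

    ``data`` needs columns ``timepoint``, ``group``, ``value`` (one row
    per session/FOV).  For each timepoint and group the report gives n,
    mean, SEM, the value normalized to that group's baseline-timepoint
    mean, and — against ``reference_group`` (default: first group in
    sorted order) — the dispatched test and p-value.  A group missing at
    a timepoint yields a flagged row, never a dropped one.
    """
    required = {"timepoint", "group", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    groups = sorted(data["group"].unique())
    if reference_group is None:
        reference_group = groups[0]
    timepoints = list(dict.fromkeys(data["timepoint"]))
    baselines = {
        g: data.loc[
            (data["group"] == g) & (data["timepoint"] == baseline_timepoint), "value"
        ].mean()
        for g in groups
    }
    rows = []
    for tp in timepoints:
        ref_vals = data.loc[
            (data["group"] == reference_group) & (data["timepoint"] == tp), "value"
        ].to_numpy()
        for g in groups:
            vals = data.loc[
                (data["group"] == g) & (data["timepoint"] == tp), "value"
            ].to_numpy()
            row = {
                "timepoint": tp,
                "group": g,
                "n": vals.size,
                "mean": vals.mean() if vals.size else np.nan,
                "sem": sps.sem(vals) if vals.size > 1 else np.nan,
                "normalized": (
                    vals.mean() / baselines[g]
                    if vals.size and np.isfinite(baselines[g]) and baselines[g] != 0
                    else np.nan
                ),
                "test": None,
                "statistic": np.nan,
                "p_value": np.nan,
                "flag": "" if vals.size else "missing",
            }
            if (
                g != reference_group
                and vals.size >= 3
                and ref_vals.size >= 3
            ):
                cmp = dispatch_compare(ref_vals, vals, paired=False,
                                       alpha_norm=alpha_norm)
                row["test"] = cmp.chosen_test
                row["statistic"] = cmp.statistic
                row["p_value"] = cmp.p_value
            elif g != reference_group and vals.size:
                row["flag"] = (row["flag"] + ";" if row["flag"] else "") + "too_few_for_test"
            rows.append(row)
    report = pd.DataFrame(rows)
    if bh_correct:
        sel = report["p_value"].notna()
        if sel.any():
            report.loc[sel, "p_adj"] = multipletests(
                report.loc[sel, "p_value"], method="fdr_bh"
            )[1]
        else:
            report["p_adj"] = np.nan
    return report
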