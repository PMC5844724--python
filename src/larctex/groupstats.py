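"""Cohort-level comparisons of texture parameters.

The analysis table ("cohort table") is a long-format DataFrame with one row
per (patient, timepoint, rater) carrying the seven texture features and the
pathological response labels:

* ``trg`` — Mandard tumor regression grade 1-5 scored on the resected
  specimen; ``responder_trg`` is True for TRG 1-2.
* ``pcr`` — pathological complete response (ypT0N0).

Rater measurements are averaged before any group testing (mean across the
configured rater set). Pre- vs early-treatment comparisons are paired
Wilcoxon signed-rank tests (zeros dropped, exact null for small n);
responder vs nonresponder comparisons are two-sided Mann-Whitney U tests
(exact for small tie-free samples). Summaries are reported as
median (Q1-Q3) with linearly interpolated quartiles. No multiple-testing
correction is applied across the 7 parameters x 2 timepoints by default;
Holm correction is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = [
    "GroupComparison",
    "validate_cohort",
    "average_raters",
    "paired_wilcoxon",
    "mann_whitney",
    "summarize_median_iqr",
    "run_group_tables",
    "KEY_COLUMNS",
]

KEY_COLUMNS = ("patient_id", "timepoint", "rater")
LABEL_COLUMNS = ("trg", "responder_trg", "pcr")


@dataclass(frozen=True)
class GroupComparison:
    """One parameter's two-group (or paired) comparison."""

    parameter: str
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float
    q1_a: float
    q3_a: float
    median_b: float
    q1_b: float
    q3_b: float

    def summary(self, which: str = "a") -> str:
        m, q1, q3 = (
            (self.median_a, self.q1_a, self.q3_a)
            if which == "a"
            else (self.median_b, self.q1_b, self.q3_b)
        )
        return f"{m:.2f}({q1:.2f}-{q3:.2f})"


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table contract and return the frame unchanged."""
    missing = [
        c
        for c in (*KEY_COLUMNS, *FEATURE_NAMES, "responder_trg", "pcr")
        if c not in cohort.columns
    ]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    dup = cohort.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        key = cohort.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
        raise ValueError(f"duplicate (patient, timepoint, rater) row: {key}")
    if "trg" in cohort.columns:
        bad = cohort["responder_trg"] != cohort["trg"].le(2)
        if bad.any():
            raise ValueError("responder_trg inconsistent with TRG grade")
    per_patient = cohort.groupby("patient_id")[list(LABEL_COLUMNS)].nunique()
    if (per_patient > 1).any().any():
        raise ValueError("response labels must be constant within patient")
    return cohort


def average_raters(cohort: pd.DataFrame, raters: tuple[str, ...] = ("A", "B")) -> pd.DataFrame:
    """Collapse the rater axis by averaging features across raters.

    Every (patient, timepoint) must carry exactly the configured rater set;
    a missing rater row raises an error naming the offending cell. The
    returned table has one row per (patient, timepoint) with
    ``rater="mean"``.
    """
    validate_cohort(cohort)
    expected = set(raters)
    for (pid, tp), grp in cohort.groupby(["patient_id", "timepoint"], sort=False):
        got = set(grp["rater"])
        if got != expected:
            raise ValueError(
                f"patient {pid!r} timepoint {tp!r}: raters {sorted(got)} "
                f"!= expected {sorted(expected)}"
            )
    meta_cols = [c for c in cohort.columns if c not in FEATURE_NAMES and c != "rater"]
    agg = {name: "mean" for name in FEATURE_NAMES}
    for c in meta_cols:
        if c not in ("patient_id", "timepoint"):
            agg[c] = "first"
    out = (
        cohort.groupby(["patient_id", "timepoint"], sort=False, as_index=False)
        .agg(agg)
    )
    out.insert(2, "rater", "mean")
    return out


def summarize_median_iqr(values) -> tuple[float, float, float]:
    """Median and linearly interpolated 25th/75th percentiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def paired_wilcoxon(pre, early, parameter: str = "") -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test of paired pre vs early values.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for n <= 25 nonzero tie-free differences and the
    tie-corrected normal approximation otherwise. All-zero differences
    give p = 1 with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    early = np.asarray(early, dtype=float)
    if pre.size != early.size:
        raise ValueError("pre and early must be paired (equal length)")
    diffs = early - pre
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1", RuntimeWarning, stacklevel=2)
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(
            pre, early, zero_method="wilcox", alternative="two-sided", method="auto"
        )
        stat, p = float(res.statistic), float(res.pvalue)
    med_a, q1_a, q3_a = summarize_median_iqr(pre)
    med_b, q1_b, q3_b = summarize_median_iqr(early)
    return GroupComparison(
        parameter=parameter,
        test="wilcoxon-signed-rank",
        statistic=stat,
        p_value=p,
        n_a=pre.size,
        n_b=early.size,
        median_a=med_a,
        q1_a=q1_a,
        q3_a=q3_a,
        median_b=med_b,
        q1_b=q1_b,
        q3_b=q3_b,
    )


def mann_whitney(group_a, group_b, parameter: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test of two independent groups.

    Exact when both groups have <= 8 observations and the pooled sample is
    tie-free; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    med_a, q1_a, q3_a = summarize_median_iqr(a)
    med_b, q1_b, q3_b = summarize_median_iqr(b)
    return GroupComparison(
        parameter=parameter,
        test="mann-whitney-u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        median_a=med_a,
        q1_a=q1_a,
        q3_a=q3_a,
        median_b=med_b,
        q1_b=q1_b,
        q3_b=q3_b,
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def run_group_tables(
    cohort_avg: pd.DataFrame,
    label: str = "pcr",
    alpha: float = 0.05,
    holm: bool = False,
) -> dict[str, pd.DataFrame]:
    """Build the study's comparison tables from a rater-averaged cohort.

    Returns two frames:

    * ``"response"`` — responder vs nonresponder (per ``label``:
      ``"pcr"`` or ``"trg"``) Mann-Whitney comparison of each parameter at
      each timepoint, with median (IQR) summaries per group;
    * ``"paired"`` — pre vs early paired Wilcoxon comparison per
      parameter across all patients.

    ``holm`` optionally adds Holm-adjusted p-values across the 14
    parameter x timepoint response tests.
    """
    if label not in ("pcr", "trg"):
        raise ValueError("label must be 'pcr' or 'trg'")
    label_col = "pcr" if label == "pcr" else "responder_trg"
    if cohort_avg["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients for group comparisons")
    if cohort_avg[label_col].nunique() < 2:
        raise ValueError(f"both {label} groups must be present")

    rows = []
    for timepoint in ("pre", "early"):
        sub = cohort_avg[cohort_avg["timepoint"] == timepoint]
        resp = sub[sub[label_col]]
        nonresp = sub[~sub[label_col]]
        for name in FEATURE_NAMES:
            cmp_ = mann_whitney(resp[name], nonresp[name], parameter=f"{timepoint}-{name}")
            rows.append(
                {
                    "parameter": cmp_.parameter,
                    "timepoint": timepoint,
                    "feature": name,
                    "responder": cmp_.summary("a"),
                    "nonresponder": cmp_.summary("b"),
                    "responder_median": cmp_.median_a,
                    "nonresponder_median": cmp_.median_b,
                    "statistic": cmp_.statistic,
                    "p": cmp_.p_value,
                    "n_responder": cmp_.n_a,
                    "n_nonresponder": cmp_.n_b,
                    "significant": cmp_.p_value < alpha,
                }
            )
    response = pd.DataFrame(rows)
    if holm:
        response["p_holm"] = _holm(response["p"].to_numpy())
        response["significant"] = response["p_holm"] < alpha

    wide = cohort_avg.pivot(index="patient_id", columns="timepoint", values=list(FEATURE_NAMES))
    paired_rows = []
    for name in FEATURE_NAMES:
        pre = wide[(name, "pre")].to_numpy()
        early = wide[(name, "early")].to_numpy()
        if np.isnan(pre).any() or np.isnan(early).any():
            raise ValueError(f"missing timepoint rows for parameter {name}")
        cmp_ = paired_wilcoxon(pre, early, parameter=name)
        paired_rows.append(
            {
                "parameter": name,
                "pre": cmp_.summary("a"),
                "early": cmp_.summary("b"),
                "pre_median": cmp_.median_a,
                "early_median": cmp_.median_b,
                "statistic": cmp_.statistic,
                "p": cmp_.p_value,
                "n": cmp_.n_a,
                "significant": cmp_.p_value < alpha,
            }
        )
    paired = pd.DataFrame(paired_rows)
    return {"response": response, "paired": paired}
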