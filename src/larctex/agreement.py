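"""Interobserver agreement of texture parameters between two raters.

Agreement is quantified with the intraclass correlation coefficient under
the two-way random-effects, absolute-agreement, single-measurement model —
ICC(2,1) in the Shrout–Fleiss numbering, ICC(A,1) in McGraw–Wong. Raters
are treated as a random sample of interchangeable readers and systematic
rater offsets count against agreement, which matches the interobserver
question being asked. The 95% CI uses the McGraw–Wong F-distribution
construction with a Satterthwaite-approximated denominator df.

Estimates are labelled with the conventional agreement bands:
0–0.20 poor, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 good,
0.81–1.00 excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ICCResult", "icc_agreement", "classify_agreement", "AGREEMENT_BANDS"]

#: Upper (inclusive) estimate bound per band, in increasing order.
AGREEMENT_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "excellent"),
)


@dataclass(frozen=True)
class ICCResult:
    """ICC point estimate with 95% CI and agreement band."""

    estimate: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    band: str


def classify_agreement(estimate: float) -> str:
    """Map an ICC estimate to its agreement band.

    Bands are half-open on the left so the printed ranges are exhaustive.
    Negative estimates (possible under ICC(2,1)) are bucketed as poor with
    a warning.
    """
    if not np.isfinite(estimate):
        raise ValueError("estimate must be finite")
    if estimate < 0:
        warnings.warn(
            "negative ICC estimate classified as poor agreement",
            RuntimeWarning,
            stacklevel=2,
        )
        return "poor"
    for upper, band in AGREEMENT_BANDS:
        if estimate <= upper + 1e-12:
            return band
    return "excellent"


def icc_agreement(rater_a, rater_b, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1) between two raters' per-subject measurements.

    Parameters are paired by subject; at least 3 subjects are required.
    When all measurements are identical both variance components vanish and
    the estimate is defined as 1 with a degenerate CI (with a warning).
    """
    a = np.asarray(rater_a, dtype=float).ravel()
    b = np.asarray(rater_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("rater vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")

    Y = np.column_stack([a, b])
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    mse = ((Y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )

    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0.0:
        warnings.warn(
            "all measurements identical: ICC defined as 1 with degenerate CI",
            RuntimeWarning,
            stacklevel=2,
        )
        return ICCResult(1.0, 1.0, 1.0, "ICC(2,1)", n, "excellent")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0.0 or icc >= 1.0:
        lo, hi = icc, 1.0
    else:
        # McGraw & Wong CI for ICC(A,1): Satterthwaite df for the
        # denominator mean square, then an F-based inversion.
        aa = k * icc / (n * (1.0 - icc))
        bb = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
        v = (aa * msc + bb * mse) ** 2 / (
            (aa * msc) ** 2 / (k - 1) + (bb * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    lo = float(min(lo, icc))
    hi = float(max(hi, icc))
    return ICCResult(
        estimate=float(icc),
        ci_low=lo,
        ci_high=min(hi, 1.0),
        model="ICC(2,1)",
        n_subjects=n,
        band=classify_agreement(float(icc)),
    )
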