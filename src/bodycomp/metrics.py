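"""Segmentation and measurement evaluation statistics.

Overlap between an automated and a reference mask is summarised by the
Dice coefficient 2*TP/(2*TP + FP + FN) together with false-positive and
false-negative ratios expressed as fractions of the reference pixel
count.  Repeatability of paired measurements is summarised by a
root-mean-square within-pair coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OverlapStats", "overlap", "cv_repeated", "pearson_r", "paired_t", "PairedTResult"]


@dataclass(frozen=True)
class OverlapStats:
    tp: int
    fp: int
    fn: int
    dice: float
    fp_ratio: float
    fn_ratio: float


def overlap(auto: np.ndarray, reference: np.ndarray) -> OverlapStats:
    """Pixel-level overlap statistics of ``auto`` against ``reference``.

    Dice is defined as 1 when both masks are empty (perfect agreement)
    and 0 when exactly one is empty.  The FP/FN ratios are relative to
    the reference pixel count.
    """
    auto = np.asarray(auto, bool)
    reference = np.asarray(reference, bool)
    if auto.shape != reference.shape:
        raise ValueError("masks must have the same shape")
    tp = int(np.count_nonzero(auto & reference))
    fp = int(np.count_nonzero(auto & ~reference))
    fn = int(np.count_nonzero(~auto & reference))
    denom = 2 * tp + fp + fn
    dice = 1.0 if denom == 0 else 2.0 * tp / denom
    ref_n = tp + fn
    if ref_n > 0:
        fp_ratio, fn_ratio = fp / ref_n, fn / ref_n
    else:
        fp_ratio, fn_ratio = (float("inf") if fp else 0.0), 0.0
    return OverlapStats(tp=tp, fp=fp, fn=fn, dice=dice, fp_ratio=fp_ratio, fn_ratio=fn_ratio)


def cv_repeated(pairs, method: str = "rms") -> float:
    """Coefficient of variation (%) of repeated measurements.

    ``rms`` (default): sqrt(mean over pairs of (sd_pair/mean_pair)^2) * 100,
    with the two-point sd |m1 - m2|/sqrt(2).  ``sd_diff``: SD of the
    within-pair differences divided by the grand mean and sqrt(2).
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be an (n, 2) array with n >= 1")
    means = arr.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("all pair means must be positive")
    if method == "rms":
        sds = np.abs(arr[:, 0] - arr[:, 1]) / np.sqrt(2.0)
        return float(np.sqrt(np.mean((sds / means) ** 2)) * 100.0)
    if method == "sd_diff":
        diffs = arr[:, 0] - arr[:, 1]
        return float(np.std(diffs, ddof=1) / means.mean() / np.sqrt(2.0) * 100.0)
    raise ValueError("method must be 'rms' or 'sd_diff'")


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_diff: float
    percent_diff: float
    degenerate: bool


def paired_t(x, y) -> PairedTResult:
    """Two-tailed paired t-test plus mean and percent difference.

    ``percent_diff`` is the mean difference relative to the mean of the
    second (reference) series, in percent.  Zero-variance differences are
    flagged as degenerate (p is 1 when the series are identical,
    undefined otherwise).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    diffs = x - y
    mean_diff = float(diffs.mean())
    percent_diff = float(100.0 * mean_diff / y.mean()) if y.mean() != 0 else float("nan")
    if np.std(diffs, ddof=1) == 0:
        p = 1.0 if mean_diff == 0 else float("nan")
        return PairedTResult(float("nan"), p, mean_diff, percent_diff, True)
    res = stats.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), float(res.pvalue), mean_diff, percent_diff, False)
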