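"""Distribution-level test metrics on % classified LOOCV scores.

Covers the Welch t-test on the two groups' percent-classified
distributions, Cohen's d effect size, two-sample power, the
multiplier-based cut-off lines used to call true/false positives and
negatives, and the resulting confusion-matrix metrics.

Cut-off lines: with group A the higher-scoring group, the multiplier is
M = (mean_A - mean_B) / (SD_A + SD_B); the line for group A is
mean_A - M*SD_A and for group B is mean_B + M*SD_B. When M is computed
from the same four summary numbers, the two lines coincide algebraically;
when a multiplier from a true-pathology comparison is reused on
randomized data, the lines separate (and can cross), and a sample lying
between crossed lines is counted as a true positive and a false negative
at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import special, stats

from .loocv import SampleClassification
from .preprocess import ValidationError


@dataclass
class GroupComparisonStats:
    """Summary statistics and test metrics for one binary comparison."""

    label_A: str
    label_B: str
    mean_A: float
    sd_A: float
    n_A: int
    mean_B: float
    sd_B: float
    n_B: int
    t_stat: float
    df: float
    p_value: float
    tails: str
    effect_d: float
    power: float
    multiplier: float
    cutoff_A: float
    cutoff_B: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    efficiency: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def welch_t(
    xs: Sequence[float] | None = None,
    ys: Sequence[float] | None = None,
    tails: str = "two",
    summary: tuple[float, float, int, float, float, int] | None = None,
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Either pass the two samples ``xs``/``ys``, or ``summary`` as
    ``(mean_x, sd_x, n_x, mean_y, sd_y, n_y)``. Returns ``(t, df, p)``;
    one-tailed p is taken in the observed direction (half the two-tailed
    p), so identical samples give p = 0.5.
    """
    if summary is not None:
        mean_x, sd_x, n_x, mean_y, sd_y, n_y = summary
        var_x, var_y = sd_x**2, sd_y**2
    else:
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        if len(xs) < 2 or len(ys) < 2:
            raise ValidationError("each sample needs length >= 2")
        n_x, n_y = len(xs), len(ys)
        mean_x, mean_y = xs.mean(), ys.mean()
        var_x = xs.var(ddof=1)
        var_y = ys.var(ddof=1)
    if n_x < 2 or n_y < 2:
        raise ValidationError("each sample needs n >= 2")
    se2 = var_x / n_x + var_y / n_y
    if se2 == 0:
        t = 0.0 if mean_x == mean_y else np.inf * np.sign(mean_x - mean_y)
        df = float(n_x + n_y - 2)
        p_two = 1.0 if mean_x == mean_y else 0.0
    else:
        t = (mean_x - mean_y) / np.sqrt(se2)
        df = se2**2 / ((var_x / n_x) ** 2 / (n_x - 1) + (var_y / n_y) ** 2 / (n_y - 1))
        p_two = float(special.betainc(df / 2.0, 0.5, df / (df + t**2)))
    if tails == "two":
        p = p_two
    elif tails == "one":
        p = p_two / 2.0
    else:
        raise ValidationError(f"tails must be 'one' or 'two', got {tails!r}")
    return float(t), float(df), float(p)


def cohens_d(mean_A: float, sd_A: float, mean_B: float, sd_B: float) -> float:
    """Cohen's d from group summary statistics, RMS-pooled SDs.

    d = (mean_A - mean_B) / sqrt((sd_A^2 + sd_B^2) / 2). The root-mean-
    square pooling uses only the printed summary pair, with no sample-size
    weighting.
    """
    if sd_A < 0 or sd_B < 0:
        raise ValidationError("standard deviations must be >= 0")
    if sd_A == 0 and sd_B == 0:
        raise ValidationError("both standard deviations are zero")
    return (mean_A - mean_B) / np.sqrt((sd_A**2 + sd_B**2) / 2.0)


def power_estimate(d: float, n_A: int, n_B: int, alpha: float = 0.05) -> float:
    """Two-sample t-test power for effect size d at the given group sizes.

    Uses the noncentral-t formulation with noncentrality
    d * sqrt(n_A * n_B / (n_A + n_B)) and a two-sided alpha.
    """
    if n_A < 2 or n_B < 2:
        raise ValidationError("group sizes must be >= 2")
    df = n_A + n_B - 2
    nc = abs(d) * np.sqrt(n_A * n_B / (n_A + n_B))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    if np.isnan(power):
        # the noncentral-t tail underflows for extreme noncentrality; the
        # normal approximation is exact to well beyond double precision there
        power = stats.norm.sf(tcrit - nc) + stats.norm.cdf(-tcrit - nc)
    return float(power)


def cutoff_lines(
    mean_A: float,
    sd_A: float,
    mean_B: float,
    sd_B: float,
    multiplier: float | None = None,
) -> tuple[float, float, float]:
    """Multiplier and the two cut-off lines on the % classified scale.

    Convention: A is the higher-% group (mean_A >= mean_B). When
    ``multiplier`` is None it is computed from these four numbers, which
    makes the two lines coincide exactly; a supplied multiplier (the
    randomization control reuses the true-pathology one) generally yields
    two separate, possibly crossed, lines.
    """
    if sd_A + sd_B == 0:
        raise ValidationError("sd_A + sd_B must be > 0")
    if multiplier is None:
        multiplier = (mean_A - mean_B) / (sd_A + sd_B)
    cutoff_A = mean_A - multiplier * sd_A
    cutoff_B = mean_B + multiplier * sd_B
    return float(multiplier), float(cutoff_A), float(cutoff_B)


def confusion_counts(
    classifications: Sequence[SampleClassification],
    cutoff_A: float,
    cutoff_B: float,
    label_A: str,
) -> tuple[int, int, int, int]:
    """TP/FP/TN/FN counts of % classified scores against the cut-off lines.

    Group-A (positive) samples: pct_A >= cutoff_A counts TP, pct_A <=
    cutoff_B counts FN; between crossed lines a sample counts as both.
    A score exactly on coincident lines counts only as correctly
    classified. Mirrored for group-B samples (TN at/below the B line,
    FP at/above the A line).
    """
    crossed = cutoff_B > cutoff_A
    tp = fp = tn = fn = 0
    for c in classifications:
        pct = c.pct_A
        if c.true_group == label_A:
            is_tp = pct >= cutoff_A
            is_fn = pct <= cutoff_B and (not is_tp or crossed)
            tp += is_tp
            fn += is_fn
        else:
            is_tn = pct <= cutoff_B
            is_fp = pct >= cutoff_A and (not is_tn or crossed)
            tn += is_tn
            fp += is_fp
    return tp, fp, tn, fn


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Sensitivity, specificity, predictive values and efficiency.

    A metric whose denominator is zero is reported as None.
    """

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "efficiency": ratio(tp + tn, tp + tn + fp + fn),
    }


def summarize_comparison(
    classifications: Sequence[SampleClassification],
    label_A: str,
    label_B: str,
    tails: str = "two",
    alpha: float = 0.05,
    multiplier: float | None = None,
) -> GroupComparisonStats:
    """Full test-metric summary of a set of LOOCV classifications.

    Computes the group % classified means/SDs, Welch t/p between the two
    groups' score distributions, Cohen's d, power, the cut-off lines
    (reusing ``multiplier`` when given), and the confusion metrics.
    """
    pct_A_scores = [c.pct_A for c in classifications if c.true_group == label_A]
    pct_B_scores = [c.pct_A for c in classifications if c.true_group == label_B]
    if len(pct_A_scores) < 2 or len(pct_B_scores) < 2:
        raise ValidationError("each group needs >= 2 classified samples")
    mean_A = float(np.mean(pct_A_scores))
    mean_B = float(np.mean(pct_B_scores))
    sd_A = float(np.std(pct_A_scores, ddof=1))
    sd_B = float(np.std(pct_B_scores, ddof=1))
    n_A, n_B = len(pct_A_scores), len(pct_B_scores)
    t, df, p = welch_t(pct_A_scores, pct_B_scores, tails=tails)
    d = cohens_d(mean_A, sd_A, mean_B, sd_B)
    power = power_estimate(d, n_A, n_B, alpha=alpha)
    M, cut_A, cut_B = cutoff_lines(mean_A, sd_A, mean_B, sd_B, multiplier)
    tp, fp, tn, fn = confusion_counts(classifications, cut_A, cut_B, label_A)
    conf = confusion_metrics(tp, fp, tn, fn)
    return GroupComparisonStats(
        label_A=label_A, label_B=label_B,
        mean_A=mean_A, sd_A=sd_A, n_A=n_A,
        mean_B=mean_B, sd_B=sd_B, n_B=n_B,
        t_stat=t, df=df, p_value=p, tails=tails,
        effect_d=d, power=power,
        multiplier=M, cutoff_A=cut_A, cutoff_B=cut_B,
        tp=tp, fp=fp, tn=tn, fn=fn, **conf,
    )
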