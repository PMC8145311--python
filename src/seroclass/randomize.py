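"""Randomization (label-shuffle) overfitting control.

The control re-runs the identical LOOCV/PCV analysis after permuting the
group labels among the samples, keeping group sizes and the demographic
composition (sex and age strata) of each group. To rule out the feature
selection itself driving apparent separation, the number of significant
peaks per fold is forced to match the count observed in the
true-pathology run, and the true-pathology cut-off multiplier is reused
when drawing the randomized cut-off lines. On real group differences the
randomized p collapses toward non-significance while the true-pathology
p stays extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .loocv import (
    Cohort,
    DEFAULT_ALPHA,
    DEFAULT_FLOOR_FRACTION,
    SampleClassification,
    run_loocv,
    select_significant_peaks,
)
from .metrics import GroupComparisonStats, summarize_comparison
from .preprocess import ValidationError

logger = logging.getLogger("seroclass")


@dataclass
class RandomizationPlan:
    """A demographically balanced label permutation for one cohort."""

    seed: int
    strata: dict[str, list[str]]
    permuted_labels: dict[str, str]
    n_peaks_target: int | None = None


def _age_tertile(ages: np.ndarray) -> np.ndarray:
    """Cohort-wide age tertile index (0, 1, 2) per sample."""
    q1, q2 = np.quantile(ages, [1 / 3, 2 / 3])
    return np.digitize(ages, [q1, q2], right=True)


def balanced_permutation(cohort: Cohort, seed: int) -> RandomizationPlan:
    """Permute group labels within sex x age-tertile strata.

    Within-stratum shuffling preserves per-group sizes and each group's
    sex/age composition exactly. If any stratum is a singleton (no
    shuffling possible there, unduly constraining the permutation), the
    strata relax to sex only, with a logged warning.
    """
    samples = cohort.samples
    ages = np.array([s.age for s in samples])
    tert = _age_tertile(ages)
    keys = [f"{s.sex}x{t}" for s, t in zip(samples, tert)]
    strata: dict[str, list[str]] = {}
    for s, k in zip(samples, keys):
        strata.setdefault(k, []).append(s.sample_id)
    if any(len(v) == 1 for v in strata.values()):
        logger.warning("singleton sex x age stratum; relaxing to sex-only strata")
        strata = {}
        for s in samples:
            strata.setdefault(s.sex, []).append(s.sample_id)
    rng = np.random.default_rng(seed)
    label_of = {s.sample_id: s.group for s in samples}
    permuted: dict[str, str] = {}
    for ids in strata.values():
        labels = [label_of[i] for i in ids]
        shuffled = list(rng.permutation(labels))
        permuted.update(zip(ids, shuffled))
    return RandomizationPlan(seed=seed, strata=strata, permuted_labels=permuted)


def apply_plan(cohort: Cohort, plan: RandomizationPlan) -> Cohort:
    """A copy of the cohort with the plan's permuted group labels."""
    missing = {s.sample_id for s in cohort.samples} - set(plan.permuted_labels)
    if missing:
        raise ValidationError(f"plan does not cover samples: {sorted(missing)}")
    samples = [replace(s, group=plan.permuted_labels[s.sample_id]) for s in cohort.samples]
    return Cohort(cohort.label_A, cohort.label_B, samples)


def run_randomized_loocv(
    cohort: Cohort,
    plan: RandomizationPlan,
    alpha: float = DEFAULT_ALPHA,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    multiplier: float | None = None,
    tails: str = "two",
) -> tuple[list[SampleClassification], GroupComparisonStats]:
    """The identical LOOCV analysis on the relabeled cohort.

    Each fold's significant-peak listing is forced to exactly
    ``plan.n_peaks_target`` peaks (rank by ascending p, significance
    threshold relaxed as needed), and the supplied true-pathology
    ``multiplier`` is reused for the cut-off lines.
    """
    if plan.n_peaks_target is None or plan.n_peaks_target < 1:
        raise ValidationError("plan.n_peaks_target must be set and >= 1")
    shuffled = apply_plan(cohort, plan)
    classifications = run_loocv(
        shuffled, alpha, floor_fraction, n_peaks_target=plan.n_peaks_target
    )
    stats = summarize_comparison(
        classifications, cohort.label_A, cohort.label_B,
        tails=tails, multiplier=multiplier,
    )
    return classifications, stats


def randomization_control(
    cohort: Cohort,
    seed: int,
    alpha: float = DEFAULT_ALPHA,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    tails: str = "two",
) -> dict:
    """Run the true-pathology analysis and one matched randomization.

    The peak-count target for the randomized run is the median per-fold
    significant-peak count of the true run; the true run's multiplier is
    reused for the randomized cut-off lines. Returns both classification
    lists and both stat summaries.
    """
    true_cls = run_loocv(cohort, alpha, floor_fraction)
    true_stats = summarize_comparison(true_cls, cohort.label_A, cohort.label_B, tails=tails)
    fold_counts = [c.n_peaks_scored for c in true_cls]
    target = int(np.median(fold_counts))
    if target < 1:
        raise ValidationError("true-pathology run selected no significant peaks")
    plan = balanced_permutation(cohort, seed)
    plan.n_peaks_target = target
    rand_cls, rand_stats = run_randomized_loocv(
        cohort, plan, alpha, floor_fraction,
        multiplier=true_stats.multiplier, tails=tails,
    )
    return {
        "true_classifications": true_cls,
        "true_stats": true_stats,
        "plan": plan,
        "randomized_classifications": rand_cls,
        "randomized_stats": rand_stats,
    }
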