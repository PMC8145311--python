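"""Assignment of samples from outside a binary comparison.

Two use cases: (1) a blinded subset held out of one of the two groups,
scored against a training-set peak listing built from the remaining
samples; (2) an unrelated external cohort (e.g., a third condition
acquired on the same platform) scored against the full-cohort peak
listing and tallied by which side of the cut-off lines each sample
falls on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .loocv import (
    Cohort,
    DEFAULT_ALPHA,
    DEFAULT_FLOOR_FRACTION,
    PCVSet,
    SampleClassification,
    SampleRecord,
    build_full_pcv_set,
    classify_sample,
    run_loocv,
)
from .preprocess import ValidationError


@dataclass
class BlindAssignment:
    """Output of a leave-out-blind run."""

    training_pcvs: PCVSet
    training_classifications: list[SampleClassification]
    blind_classifications: list[SampleClassification]


def leave_out_blind(
    cohort: Cohort,
    blind_ids: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
) -> BlindAssignment:
    """Hold out ``blind_ids``, train on the remainder, score the blinds.

    Training-set members get ordinary LOOCV classifications; each blind
    sample is classified once against the full training-set peak listing.
    Blind classifications carry the sample's recorded group for
    bookkeeping but are not assumed correct by any metric.
    """
    ids = {s.sample_id for s in cohort.samples}
    unknown = set(blind_ids) - ids
    if unknown:
        raise ValidationError(f"blind ids not in cohort: {sorted(unknown)}")
    blind_set = set(blind_ids)
    remainder = [s for s in cohort.samples if s.sample_id not in blind_set]
    training = Cohort(cohort.label_A, cohort.label_B, remainder)
    for label in (cohort.label_A, cohort.label_B):
        if len(training.group_ids(label)) < 3:
            raise ValidationError(f"blind set leaves group {label!r} with < 3 samples")
    training_cls = run_loocv(training, alpha, floor_fraction)
    pcvs = build_full_pcv_set(training, alpha, floor_fraction)
    blinds = [s for s in cohort.samples if s.sample_id in blind_set]
    blind_cls = [
        classify_sample(s.areas, pcvs, cohort.label_A, true_group=s.group) for s in blinds
    ]
    return BlindAssignment(pcvs, training_cls, blind_cls)


@dataclass
class ExternalTally:
    """Side-of-cutoff tally for an external sample group."""

    classifications: list[SampleClassification]
    n_side_A: int
    n_side_B: int
    n_between: int


def assign_external(
    external: Sequence[SampleRecord],
    pcvs: PCVSet,
    cutoff_A: float,
    cutoff_B: float,
    label_A: str,
) -> ExternalTally:
    """Score external samples against a fixed peak listing and tally sides.

    Each sample's % classified to group A is compared to the cut-off
    lines: at/above the A line tallies to the A side, at/below the B line
    to the B side; between crossed lines (or in the gap of separated
    lines) a sample is tallied indeterminate rather than forced to a
    side. Sides are mutually exclusive here — a score satisfying both
    line conditions (crossed lines) is indeterminate.
    """
    if len(pcvs) == 0:
        raise ValidationError("cannot assign against an empty PCVSet")
    grid_lo = {s.areas.mz_lo for s in external}
    grid_hi = {s.areas.mz_hi for s in external}
    if external and (len(grid_lo) > 1 or len(grid_hi) > 1):
        raise ValidationError("external samples are on mixed m/z grids")
    cls = [classify_sample(s.areas, pcvs, label_A, true_group=s.group) for s in external]
    n_A = n_B = n_between = 0
    for c in cls:
        on_A = c.pct_A >= cutoff_A
        on_B = c.pct_A <= cutoff_B
        if on_A and not on_B:
            n_A += 1
        elif on_B and not on_A:
            n_B += 1
        else:
            n_between += 1
    return ExternalTally(cls, n_A, n_B, n_between)
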