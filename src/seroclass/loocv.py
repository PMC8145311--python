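"""Leave-one-out cross-validated peak classification (LOOCV/PCV).

The classifier works on averaged, normalized peak-area vectors. For a
binary cohort it (1) selects the unit-mass peaks whose areas differ
between the two groups by a one-tailed unequal-variance (Welch) t-test at
``p < alpha``, subject to a minimum-abundance floor, (2) assigns each
selected peak a peak classification valuation (PCV) — the midpoint of the
two group mean areas — together with the direction (which group has the
larger mean), and (3) scores a held-out sample by the percentage of
selected peaks whose areas fall on each group's side of their PCVs. The
leave-one-out loop rebuilds the peak selection from the remaining N-1
samples for every held-out sample, so a sample never informs its own
significant-peak listing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .preprocess import PeakAreaVector, ValidationError

logger = logging.getLogger("seroclass")

DEFAULT_ALPHA = 0.05
#: Minimum fraction of the dataset's maximum group-mean peak area that a
#: peak's larger group mean must reach to be eligible (0.3%).
DEFAULT_FLOOR_FRACTION = 0.003


@dataclass
class SampleRecord:
    """One serum sample: group label, demographics, averaged peak areas."""

    sample_id: str
    group: str
    sex: str
    age: float
    areas: PeakAreaVector

    def __post_init__(self):
        if self.age <= 0:
            raise ValidationError(f"sample {self.sample_id}: age must be > 0")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sample {self.sample_id}: sex must be 'M' or 'F'")


@dataclass
class Cohort:
    """A binary comparison cohort: two labelled groups of samples."""

    label_A: str
    label_B: str
    samples: list[SampleRecord]

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample_ids in cohort")
        bad = {s.group for s in self.samples} - {self.label_A, self.label_B}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    def group_ids(self, label: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == label]

    def area_matrix(self) -> pd.DataFrame:
        """Samples x unit-m/z matrix of averaged areas, absent peaks = 0."""
        all_mz = sorted({mz for s in self.samples for mz in s.areas.areas})
        data = np.zeros((len(self.samples), len(all_mz)))
        col = {mz: j for j, mz in enumerate(all_mz)}
        for i, s in enumerate(self.samples):
            for mz, a in s.areas.areas.items():
                data[i, col[mz]] = a
        return pd.DataFrame(data, index=[s.sample_id for s in self.samples], columns=all_mz)


@dataclass
class SignificantPeak:
    """One group-discriminatory peak with its PCV decision threshold."""

    mz: int
    p_value: float
    mean_A: float
    mean_B: float
    direction: str
    pcv: float


@dataclass
class PCVSet:
    """The significant-peak listing built from one left-in dataset."""

    peaks: list[SignificantPeak]
    left_in_ids: list[str]
    alpha: float
    floor_fraction: float

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        mzs = [p.mz for p in self.peaks]
        if len(mzs) != len(set(mzs)):
            raise ValidationError("duplicate m/z in PCVSet")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class SampleClassification:
    """A sample's percent of significant peaks classified to each group."""

    sample_id: str
    true_group: str
    n_peaks_scored: int
    pct_A: float
    pct_B: float


def _welch_columns(mat_A: np.ndarray, mat_B: np.ndarray):
    """Per-column Welch t statistics and one-tailed p for two group matrices.

    Degenerate columns (zero variance in both groups): equal means give
    p = NaN (to be skipped); unequal means give p = 0 (kept, maximally
    significant — the groups are perfectly separated there).
    """
    n_A, n_B = mat_A.shape[0], mat_B.shape[0]
    mean_A = mat_A.mean(axis=0)
    mean_B = mat_B.mean(axis=0)
    var_A = mat_A.var(axis=0, ddof=1)
    var_B = mat_B.var(axis=0, ddof=1)
    se2 = var_A / n_A + var_B / n_B
    diff = mean_A - mean_B
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (var_A / n_A) ** 2 / (n_A - 1) + (var_B / n_B) ** 2 / (n_B - 1)
        )
        # one-tailed p in the direction of the observed difference
        p = 0.5 * special.betainc(df / 2.0, 0.5, df / (df + t**2))
    degenerate = se2 == 0
    p = np.where(degenerate & (diff != 0), 0.0, p)
    p = np.where(degenerate & (diff == 0), np.nan, p)
    return t, df, p, mean_A, mean_B


def select_significant_peaks(
    cohort: Cohort,
    alpha: float = DEFAULT_ALPHA,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    left_out: str | None = None,
    n_peaks_target: int | None = None,
) -> PCVSet:
    """Select group-discriminatory peaks and build their PCVs.

    Every m/z present in any left-in sample is tested (absent = area 0)
    with a one-tailed Welch t-test; a peak is retained iff p < ``alpha``
    and its larger group mean is at least ``floor_fraction`` of the
    maximum group-mean peak area over all m/z in the left-in data.

    When ``n_peaks_target`` is given (the randomization control), the
    alpha threshold is dropped and exactly that many floor-passing peaks
    are taken in order of ascending p (ties broken by m/z), matching the
    peak count of a true-pathology run.
    """
    mat = cohort.area_matrix()
    ids_A = [i for i in cohort.group_ids(cohort.label_A) if i != left_out]
    ids_B = [i for i in cohort.group_ids(cohort.label_B) if i != left_out]
    if len(ids_A) < 2 or len(ids_B) < 2:
        raise ValidationError(
            f"each group needs >= 2 left-in samples (got {len(ids_A)}, {len(ids_B)})"
        )
    mat_A = mat.loc[ids_A].to_numpy()
    mat_B = mat.loc[ids_B].to_numpy()
    _, _, p, mean_A, mean_B = _welch_columns(mat_A, mat_B)

    floor_base = max(mean_A.max(initial=0.0), mean_B.max(initial=0.0))
    larger_mean = np.maximum(mean_A, mean_B)
    eligible = (
        ~np.isnan(p)
        & (mean_A != mean_B)
        & (larger_mean >= floor_fraction * floor_base)
    )
    mz_values = np.asarray(mat.columns)
    if n_peaks_target is None:
        keep = eligible & (p < alpha)
        order = np.flatnonzero(keep)
    else:
        if n_peaks_target < 1:
            raise ValidationError("n_peaks_target must be >= 1")
        cand = np.flatnonzero(eligible)
        order = cand[np.lexsort((mz_values[cand], p[cand]))][:n_peaks_target]
        if len(order) < n_peaks_target:
            logger.warning(
                "only %d floor-passing peaks available for target %d",
                len(order),
                n_peaks_target,
            )
    peaks = [
        SignificantPeak(
            mz=int(mz_values[j]),
            p_value=float(p[j]),
            mean_A=float(mean_A[j]),
            mean_B=float(mean_B[j]),
            direction=cohort.label_A if mean_A[j] > mean_B[j] else cohort.label_B,
            pcv=float((mean_A[j] + mean_B[j]) / 2.0),
        )
        for j in order
    ]
    return PCVSet(peaks, left_in_ids=ids_A + ids_B, alpha=alpha, floor_fraction=floor_fraction)


def build_full_pcv_set(
    cohort: Cohort,
    alpha: float = DEFAULT_ALPHA,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
) -> PCVSet:
    """Significant-peak listing from the entire cohort (no sample left out)."""
    return select_significant_peaks(cohort, alpha, floor_fraction)


def classify_sample(
    areas: PeakAreaVector,
    pcvs: PCVSet,
    label_A: str,
    true_group: str = "",
) -> SampleClassification:
    """Score a sample's peak areas against a PCV listing.

    For each significant peak, an area strictly above the PCV classifies
    to the peak's direction group; at or below classifies to the opposite
    group. ``pct_A`` is the percentage of peaks classified to ``label_A``.
    """
    if len(pcvs) == 0:
        raise ValidationError("cannot classify against an empty PCVSet")
    n_to_A = 0
    for peak in pcvs.peaks:
        above = areas.area_at(peak.mz) > peak.pcv
        # above the PCV -> the peak's direction group; at/below -> the other
        if (peak.direction == label_A) == above:
            n_to_A += 1
    n = len(pcvs)
    pct_A = 100.0 * n_to_A / n
    return SampleClassification(areas.sample_id, true_group, n, pct_A, 100.0 - pct_A)


def run_loocv(
    cohort: Cohort,
    alpha: float = DEFAULT_ALPHA,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    n_peaks_target: int | None = None,
) -> list[SampleClassification]:
    """Full leave-one-out loop: one classification per cohort sample.

    Each sample's PCVSet is built from the other N-1 samples only. Per-fold
    significant-peak counts are logged at DEBUG level.
    """
    out = []
    for rec in cohort.samples:
        pcvs = select_significant_peaks(
            cohort, alpha, floor_fraction, left_out=rec.sample_id,
            n_peaks_target=n_peaks_target,
        )
        logger.debug("fold %s: %d significant peaks", rec.sample_id, len(pcvs))
        if len(pcvs) == 0:
            out.append(SampleClassification(rec.sample_id, rec.group, 0, np.nan, np.nan))
            continue
        out.append(_classify_against(rec, pcvs, cohort.label_A))
    return out


def _classify_against(rec: SampleRecord, pcvs: PCVSet, label_A: str) -> SampleClassification:
    cls = classify_sample(rec.areas, pcvs, label_A, true_group=rec.group)
    return cls
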