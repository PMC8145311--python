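"""Spectral preprocessing for unit-mass serum ESI-MS profiles.

The processing chain mirrors a standard low-resolution serum profiling
workflow: raw (m/z, intensity) points are collapsed to a nominal (whole
unit) mass grid, each spectrum is locally normalized so that every
non-overlapping 25-m/z segment sums to 100 intensity units, peaks are
centroided valley-to-valley on the unit grid, and triplicate injection
peak areas are averaged per serum sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("seroclass")

#: Default nominal m/z grid of the ion-trap acquisitions (inclusive bounds).
DEFAULT_MZ_LO = 400
DEFAULT_MZ_HI = 2000

#: Width of the local-normalization windows, in m/z units.
DEFAULT_SEGMENT_WIDTH = 25

#: Target summed intensity of each normalization window.
DEFAULT_TARGET_SUM = 100.0


class ValidationError(ValueError):
    """Raised when an input violates a preprocessing precondition."""


def round_half_up(x):
    """Round to the nearest integer, ties away from zero toward +inf.

    Nominal-mass binning and centroid keys both use half-up rounding so
    that e.g. 500.5 maps to bin 501 regardless of parity (numpy's default
    ``round`` is banker's rounding, which is not what vendor nominal-mass
    exports do).
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass
class ReplicateSpectrum:
    """One replicate injection's unit-mass intensity vector.

    Parameters
    ----------
    sample_id : str
        Opaque serum sample identifier.
    replicate_index : int
        1-based replicate number (triplicates in the reference workflow).
    intensities : ndarray
        Non-negative intensity per unit m/z bin, ``mz_hi - mz_lo + 1`` long.
    """

    sample_id: str
    replicate_index: int
    intensities: np.ndarray
    mz_lo: int = DEFAULT_MZ_LO
    mz_hi: int = DEFAULT_MZ_HI

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        n_bins = self.mz_hi - self.mz_lo + 1
        if self.intensities.shape != (n_bins,):
            raise ValidationError(
                f"expected {n_bins} bins for m/z {self.mz_lo}-{self.mz_hi}, "
                f"got shape {self.intensities.shape}"
            )
        if np.any(self.intensities < 0):
            raise ValidationError("negative intensities are not allowed")

    @property
    def mz(self) -> np.ndarray:
        """The unit m/z value of each bin."""
        return np.arange(self.mz_lo, self.mz_hi + 1)


@dataclass
class NormalizedSpectrum(ReplicateSpectrum):
    """A replicate spectrum after 25-m/z segment normalization."""


@dataclass
class PeakAreaVector:
    """Centroided peak areas of one sample keyed by unit m/z.

    Zero-area peaks are absent, not stored; downstream consumers treat a
    missing key as area 0.
    """

    sample_id: str
    areas: dict[int, float] = field(default_factory=dict)
    mz_lo: int = DEFAULT_MZ_LO
    mz_hi: int = DEFAULT_MZ_HI

    def __post_init__(self):
        for mz, area in self.areas.items():
            if not (self.mz_lo <= mz <= self.mz_hi):
                raise ValidationError(f"peak key {mz} outside [{self.mz_lo}, {self.mz_hi}]")
            if area <= 0:
                raise ValidationError(f"non-positive peak area at m/z {mz}")

    def area_at(self, mz: int) -> float:
        return self.areas.get(int(mz), 0.0)


def nominal_bin(
    points: Iterable[tuple[float, float]],
    mz_lo: int = DEFAULT_MZ_LO,
    mz_hi: int = DEFAULT_MZ_HI,
    sample_id: str = "",
    replicate_index: int = 1,
) -> ReplicateSpectrum:
    """Accumulate raw (m/z, intensity) points onto the nominal unit-mass grid.

    Each point adds its intensity to the bin at ``round(m/z)`` (half-up);
    points rounding outside ``[mz_lo, mz_hi]`` are dropped.
    """
    pts = list(points)
    n_bins = mz_hi - mz_lo + 1
    out = np.zeros(n_bins)
    if not pts:
        return ReplicateSpectrum(sample_id, replicate_index, out, mz_lo, mz_hi)
    arr = np.asarray(pts, dtype=float)
    mzs, intens = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(mzs)):
        raise ValidationError("non-finite m/z value in input points")
    if np.any(intens < 0):
        raise ValidationError("negative intensity in input points")
    bins = round_half_up(mzs) - mz_lo
    keep = (bins >= 0) & (bins < n_bins)
    np.add.at(out, bins[keep], intens[keep])
    return ReplicateSpectrum(sample_id, replicate_index, out, mz_lo, mz_hi)


def segment_normalize(
    spec: ReplicateSpectrum,
    segment_width: int = DEFAULT_SEGMENT_WIDTH,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> NormalizedSpectrum:
    """Locally scale each non-overlapping segment to a fixed summed intensity.

    Segments start at ``mz_lo``; a final partial segment is scaled the same
    way. All-zero segments are left as zeros (the scaling is undefined
    there, and leaving them untouched preserves mass conservation).
    """
    if segment_width < 1:
        raise ValidationError("segment_width must be >= 1")
    v = spec.intensities.copy()
    for start in range(0, len(v), segment_width):
        seg = v[start : start + segment_width]
        s = seg.sum()
        if s > 0:
            seg *= target_sum / s
    return NormalizedSpectrum(spec.sample_id, spec.replicate_index, v, spec.mz_lo, spec.mz_hi)


def _valley_mask(v: np.ndarray) -> np.ndarray:
    """Boolean mask of valley bins: zeros, plus strict local minima.

    A plateau (run of equal values) that sits strictly below both of its
    differing neighbours is a minimum; its leftmost bin is taken as the
    valley so the partition is deterministic.
    """
    n = len(v)
    valley = v == 0
    if n < 3:
        return valley
    idx = np.arange(n)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = v[1:] != v[:-1]
    # start index of the plateau containing each bin
    start = np.maximum.accumulate(np.where(change, idx, 0))
    has_left = start > 0
    left_val = np.where(has_left, v[np.maximum(start - 1, 0)], np.inf)
    # end index of the plateau, via the reversed array
    rv = v[::-1]
    rchange = np.empty(n, dtype=bool)
    rchange[0] = True
    rchange[1:] = rv[1:] != rv[:-1]
    rstart = np.maximum.accumulate(np.where(rchange, idx, 0))
    end = (n - 1) - rstart[::-1]
    has_right = end < n - 1
    right_val = np.where(has_right, v[np.minimum(end + 1, n - 1)], np.inf)
    strict_min = change & has_left & has_right & (left_val > v) & (right_val > v)
    return valley | strict_min


def centroid_areas(spec: NormalizedSpectrum) -> PeakAreaVector:
    """Partition a unit-mass spectrum at valleys into centroided peaks.

    Valleys (strict local minima and zero bins) start a new run; each
    maximal run with positive total intensity becomes one peak whose area
    is the summed intensity of the run and whose key is the half-up round
    of the intensity-weighted mean m/z. The partition conserves total
    intensity exactly.
    """
    v = spec.intensities
    mz = spec.mz.astype(float)
    valley = _valley_mask(v)
    starts = np.flatnonzero(valley)
    if len(starts) == 0 or starts[0] != 0:
        starts = np.concatenate(([0], starts))
    sums = np.add.reduceat(v, starts)
    wsums = np.add.reduceat(v * mz, starts)
    areas: dict[int, float] = {}
    for s, w in zip(sums, wsums):
        if s <= 0:
            continue
        key = int(round_half_up(w / s))
        areas[key] = areas.get(key, 0.0) + float(s)
    return PeakAreaVector(spec.sample_id, areas, spec.mz_lo, spec.mz_hi)


def average_replicates(reps: Sequence[PeakAreaVector]) -> PeakAreaVector:
    """Average replicate peak areas per m/z, treating absent peaks as zero.

    The reference workflow acquires triplicates; any count >= 1 is
    accepted with a warning when it is not 3.
    """
    if not reps:
        raise ValidationError("at least one replicate is required")
    ids = {r.sample_id for r in reps}
    if len(ids) != 1:
        raise ValidationError(f"mixed sample_ids in replicates: {sorted(ids)}")
    if len(reps) != 3:
        warnings.warn(
            f"sample {reps[0].sample_id!r}: averaging {len(reps)} replicates (expected 3)",
            stacklevel=2,
        )
    totals: dict[int, float] = {}
    for r in reps:
        for mz, a in r.areas.items():
            totals[mz] = totals.get(mz, 0.0) + a
    n = len(reps)
    areas = {mz: t / n for mz, t in totals.items() if t > 0}
    return PeakAreaVector(reps[0].sample_id, areas, reps[0].mz_lo, reps[0].mz_hi)


def preprocess_replicates(
    replicates: Sequence[ReplicateSpectrum],
    segment_width: int = DEFAULT_SEGMENT_WIDTH,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> dict[str, PeakAreaVector]:
    """Run the full chain (normalize, centroid, average) for many samples.

    Returns one averaged :class:`PeakAreaVector` per sample_id, keyed by
    sample_id, in first-appearance order of the input.
    """
    by_sample: dict[str, list[PeakAreaVector]] = {}
    for rep in replicates:
        norm = segment_normalize(rep, segment_width, target_sum)
        by_sample.setdefault(rep.sample_id, []).append(centroid_areas(norm))
    return {sid: average_replicates(reps) for sid, reps in by_sample.items()}
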