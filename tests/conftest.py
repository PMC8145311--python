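import numpy as np
import pytest

from seroclass.loocv import Cohort, SampleRecord
from seroclass.preprocess import PeakAreaVector


def cohort_from_matrix(X, groups, mz_start=400, label_A="A", label_B="B",
                       sexes=None, ages=None):
    """Build a Cohort from a samples x bins area matrix (row i = sample i).

    ``groups`` is a boolean array, True = group A. Zero cells become
    absent peaks.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    mzs = np.arange(mz_start, mz_start + m)
    samples = []
    for i in range(n):
        areas = {int(mz): float(v) for mz, v in zip(mzs, X[i]) if v > 0}
        samples.append(
            SampleRecord(
                sample_id=f"S{i:03d}",
                group=label_A if groups[i] else label_B,
                sex=(sexes[i] if sexes is not None else ("M" if i % 2 else "F")),
                age=(ages[i] if ages is not None else 60.0 + i),
                areas=PeakAreaVector(f"S{i:03d}", areas),
            )
        )
    return Cohort(label_A, label_B, samples)


def lognormal_null_cohort(seed, n_A=8, n_B=8, n_bins=60, sample_sd=0.4):
    """Label-exchangeable cohort with no group effect."""
    rng = np.random.default_rng(seed)
    mu = rng.normal(2.0, 1.0, n_bins)
    X = np.exp(mu + rng.normal(0.0, sample_sd, (n_A + n_B, n_bins)))
    groups = np.arange(n_A + n_B) < n_A
    return cohort_from_matrix(X, groups)


def separated_cohort(seed, n_A=8, n_B=8, n_bins=60, n_disc=20, shift=2.0,
                     sample_sd=0.4):
    """Cohort with ``n_disc`` planted peaks shifted by ``shift`` x sample SD."""
    rng = np.random.default_rng(seed)
    mu = rng.normal(2.0, 1.0, n_bins)
    logX = mu + rng.normal(0.0, sample_sd, (n_A + n_B, n_bins))
    groups = np.arange(n_A + n_B) < n_A
    disc = rng.choice(n_bins, size=n_disc, replace=False)
    logX[np.ix_(groups, disc)] += shift * sample_sd
    return cohort_from_matrix(np.exp(logX), groups)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
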