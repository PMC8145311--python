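import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seroclass.preprocess import (
    NormalizedSpectrum,
    PeakAreaVector,
    ReplicateSpectrum,
    ValidationError,
    average_replicates,
    centroid_areas,
    nominal_bin,
    segment_normalize,
)


def make_norm(intensities, mz_lo=400):
    v = np.asarray(intensities, dtype=float)
    return NormalizedSpectrum("s", 1, v, mz_lo, mz_lo + len(v) - 1)


class TestNominalBin:
    def test_points_rounding_to_same_bin_accumulate(self):
        spec = nominal_bin([(500.01, 3.0), (500.49, 2.0)])
        assert spec.intensities[500 - 400] == 5.0
        assert spec.intensities.sum() == 5.0

    def test_empty_input_gives_all_zero_vector(self):
        spec = nominal_bin([])
        assert spec.intensities.shape == (1601,)
        assert not spec.intensities.any()

    def test_half_up_rounding_at_bin_boundary(self):
        spec = nominal_bin([(700.5, 1.0), (701.5, 1.0)])
        assert spec.intensities[701 - 400] == 1.0
        assert spec.intensities[702 - 400] == 1.0

    def test_out_of_range_points_dropped(self):
        spec = nominal_bin([(399.4, 1.0), (2000.5, 1.0), (399.5, 2.0)])
        # 399.4 -> 399 dropped; 2000.5 -> 2001 dropped; 399.5 -> 400 kept
        assert spec.intensities.sum() == 2.0
        assert spec.intensities[0] == 2.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            nominal_bin([(500.0, -1.0)])

    def test_matches_per_point_accumulation_oracle(self, rng):
        mzs = rng.uniform(380, 2020, size=10_000)
        intens = rng.exponential(5.0, size=10_000)
        spec = nominal_bin(list(zip(mzs, intens)))
        oracle = np.zeros(1601)
        for m, i in zip(mzs, intens):
            b = int(np.floor(m + 0.5)) - 400
            if 0 <= b < 1601:
                oracle[b] += i
        np.testing.assert_allclose(spec.intensities, oracle, rtol=1e-12)

    def test_point_order_never_changes_output(self, rng):
        pts = list(zip(rng.uniform(400, 2000, 500), rng.exponential(1.0, 500)))
        a = nominal_bin(pts).intensities
        b = nominal_bin(pts[::-1]).intensities
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestSegmentNormalize:
    def test_equal_bins_scale_to_target(self):
        spec = ReplicateSpectrum("s", 1, np.full(25, 7.0), 400, 424)
        out = segment_normalize(spec)
        np.testing.assert_allclose(out.intensities, 4.0)

    def test_segment_summing_to_200_halved(self):
        v = np.zeros(50)
        v[:25] = 8.0  # sums to 200
        spec = ReplicateSpectrum("s", 1, v, 400, 449)
        out = segment_normalize(spec)
        np.testing.assert_allclose(out.intensities[:25], 4.0)

    def test_all_zero_segment_left_untouched(self):
        v = np.zeros(50)
        v[25:] = 1.0
        out = segment_normalize(ReplicateSpectrum("s", 1, v, 400, 449))
        assert not out.intensities[:25].any()
        np.testing.assert_allclose(out.intensities[25:].sum(), 100.0)

    def test_partial_final_segment_scaled_the_same_way(self):
        v = np.ones(30)  # one full segment + 5-bin partial
        out = segment_normalize(ReplicateSpectrum("s", 1, v, 400, 429))
        np.testing.assert_allclose(out.intensities[:25].sum(), 100.0)
        np.testing.assert_allclose(out.intensities[25:].sum(), 100.0)

    def test_bad_segment_width_rejected(self):
        spec = ReplicateSpectrum("s", 1, np.ones(25), 400, 424)
        with pytest.raises(ValidationError):
            segment_normalize(spec, segment_width=0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_idempotent_and_total_is_100_per_nonzero_segment(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.exponential(3.0, size=130)
        v[rng.random(130) < 0.3] = 0.0
        v[50:75] = 0.0  # force an all-zero segment
        spec = ReplicateSpectrum("s", 1, v, 400, 529)
        once = segment_normalize(spec)
        twice = segment_normalize(once)
        np.testing.assert_allclose(once.intensities, twice.intensities, rtol=1e-9)
        n_nonzero_segments = sum(
            1 for i in range(0, 130, 25) if v[i : i + 25].sum() > 0
        )
        np.testing.assert_allclose(
            once.intensities.sum(), 100.0 * n_nonzero_segments, rtol=1e-9
        )


def centroid_oracle(v, mz_lo):
    """Exhaustive valley scan: zero bins and strict local minima (leftmost
    plateau bin) start a new run; positive runs become peaks."""
    n = len(v)

    def is_valley(i):
        if v[i] == 0:
            return True
        if i > 0 and v[i] == v[i - 1]:
            return False  # not the leftmost plateau bin
        left = next((v[j] for j in range(i - 1, -1, -1) if v[j] != v[i]), None)
        right = next((v[j] for j in range(i + 1, n) if v[j] != v[i]), None)
        return left is not None and right is not None and left > v[i] and right > v[i]

    cuts = [i for i in range(n) if is_valley(i)]
    if not cuts or cuts[0] != 0:
        cuts = [0] + cuts
    peaks = {}
    for a, b in zip(cuts, cuts[1:] + [n]):
        run = v[a:b]
        s = run.sum()
        if s > 0:
            center = sum((mz_lo + a + k) * run[k] for k in range(len(run))) / s
            key = int(np.floor(center + 0.5))
            peaks[key] = peaks.get(key, 0.0) + s
    return peaks


class TestCentroidAreas:
    def test_isolated_single_bin_peak(self):
        out = centroid_areas(make_norm([0, 5, 0], mz_lo=700))
        assert out.areas == {701: 5.0}

    def test_flat_zero_spectrum_gives_no_peaks(self):
        out = centroid_areas(make_norm(np.zeros(40)))
        assert out.areas == {}

    def test_two_peaks_split_at_interior_valley(self):
        # valley bin (1.0 at index 3) belongs to the right-hand run
        out = centroid_areas(make_norm([0, 4, 6, 1, 5, 3, 0], mz_lo=500))
        assert len(out.areas) == 2
        assert sum(out.areas.values()) == pytest.approx(19.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_valley_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.exponential(2.0, size=200)
        v[rng.random(200) < 0.35] = 0.0
        out = centroid_areas(make_norm(v))
        assert out.areas == pytest.approx(centroid_oracle(v, 400))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_conserves_total_intensity(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.exponential(2.0, size=120)
        v[rng.random(120) < 0.4] = 0.0
        out = centroid_areas(make_norm(v))
        np.testing.assert_allclose(sum(out.areas.values()), v.sum(), rtol=1e-9)


class TestAverageReplicates:
    def test_identical_vectors_are_a_fixed_point(self):
        v = PeakAreaVector("s", {500: 3.0, 700: 1.5})
        out = average_replicates([v, v, v])
        assert out.areas == pytest.approx(v.areas)

    def test_absent_peak_treated_as_zero(self):
        reps = [
            PeakAreaVector("s", {500: 3.0}),
            PeakAreaVector("s", {}),
            PeakAreaVector("s", {500: 3.0}),
        ]
        out = average_replicates(reps)
        assert out.areas[500] == pytest.approx(2.0)

    def test_mixed_sample_ids_rejected(self):
        with pytest.raises(ValidationError):
            average_replicates(
                [PeakAreaVector("a", {500: 1.0}), PeakAreaVector("b", {500: 1.0})]
            )

    def test_non_triplicate_count_warns(self):
        with pytest.warns(UserWarning):
            average_replicates([PeakAreaVector("s", {500: 1.0})])

    def test_matches_per_key_mean_oracle_and_order_invariance(self, rng):
        reps = []
        for _ in range(3):
            keys = rng.choice(np.arange(400, 450), size=20, replace=False)
            reps.append(
                PeakAreaVector("s", {int(k): float(rng.exponential(2.0) + 0.01) for k in keys})
            )
        out = average_replicates(reps)
        all_keys = set().union(*(r.areas for r in reps))
        oracle = {
            k: sum(r.areas.get(k, 0.0) for r in reps) / 3 for k in all_keys
        }
        oracle = {k: v for k, v in oracle.items() if v > 0}
        assert out.areas == pytest.approx(oracle)
        out_rev = average_replicates(reps[::-1])
        assert out_rev.areas == pytest.approx(out.areas)
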