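"""Difference images, Li thresholding, AAI, trace extraction, peak counting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skimage.filters import threshold_li as skimage_li

from stretchquant import calcium, nuclei, synthetic as syn
from stretchquant.exceptions import (
    DegenerateDataWarning,
    DegenerateImageError,
    ValidationError,
)


def brute_force_li(values):
    """Exhaustive minimization of the Li cross-entropy over all splits.

    Returns the background-class maximum of the best split (foreground is
    strictly above it), computing the objective term-by-term from raw pixels.
    """
    values = np.asarray(values, dtype=float).ravel()
    distinct = np.unique(values)
    best_v, best_obj = None, np.inf
    for v in distinct[:-1]:
        bg, fg = values[values <= v], values[values > v]
        obj = 0.0
        for cls in (bg, fg):
            mu = cls.mean() if cls.size else 0.0
            if mu > 0:
                pos = cls[cls > 0]
                obj += float(np.sum(pos * np.log(pos / mu)))
        if obj < best_obj - 1e-12:
            best_obj, best_v = obj, v
    return best_v


def brute_force_peaks(values, min_prominence, min_height):
    """Count peaks by explicit plateau detection and left/right scans."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    count = 0
    i = 1
    while i < n - 1:
        # candidate plateau [i, j] with equal values
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if j == n - 1:
            break
        if values[i - 1] < values[i] and values[j + 1] < values[i]:
            peak = values[i]
            # left base: min until a strictly higher sample (or the start)
            left = values[:i][::-1]
            stop = np.nonzero(left > peak)[0]
            lmin = left[: stop[0]].min() if stop.size else left.min()
            right = values[j + 1 :]
            stop = np.nonzero(right > peak)[0]
            rmin = right[: stop[0]].min() if stop.size else right.min()
            prominence = peak - max(lmin, rmin)
            if prominence >= min_prominence and peak >= min_height:
                count += 1
        i = j + 1
    return count


class TestDifferenceStack:
    def test_constant_movie_all_zero(self):
        movie = np.full((5, 8, 8), 7.0)
        assert np.all(calcium.difference_stack(movie).frames == 0)

    def test_single_step_recovers_increment(self, rng):
        a = rng.uniform(0, 10, (8, 8))
        b = np.abs(rng.uniform(0, 3, (8, 8)))
        ds = calcium.difference_stack(np.stack([a, a + b]))
        assert ds.frames.shape == (1, 8, 8)
        np.testing.assert_allclose(ds.frames[0], b)

    def test_decreasing_movie_clamped_to_zero(self):
        movie = np.stack([np.full((4, 4), v) for v in (9.0, 5.0, 1.0)])
        assert np.all(calcium.difference_stack(movie).frames == 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            calcium.difference_stack(np.zeros((1, 4, 4)))


class TestLiThreshold:
    def test_two_level_image_threshold_between_modes(self):
        image = np.array([10.0] * 900 + [200.0] * 100).reshape(25, 40)
        t = calcium.li_threshold(image)
        assert 10 < t < 200
        assert (image > t).sum() == 100

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateImageError):
            calcium.li_threshold(np.full((8, 8), 5.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_8bit(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, 256).astype(float)
        t = calcium.li_threshold(img)
        v = brute_force_li(img)
        np.testing.assert_array_equal(img > t, img > v)

    def test_agrees_with_skimage_on_separated_modes(self, rng):
        img = np.concatenate(
            [rng.normal(20, 2, 3000), rng.normal(180, 5, 1000)]
        ).clip(0, None)
        ours = calcium.li_threshold(img)
        ref = skimage_li(img)
        np.testing.assert_array_equal(img > ours, img > ref)

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            calcium.li_threshold(np.array([-1.0, 2.0, 3.0]))


class TestSegmentTransients:
    def test_single_square_counted(self):
        frame = np.zeros((32, 32))
        frame[5:15, 5:15] = 9.0
        assert calcium.segment_transients(frame, 1.0, min_size=20) == [100]

    def test_size_filter_drops_speck(self):
        frame = np.zeros((32, 32))
        frame[5:15, 5:15] = 9.0
        frame[25, 25:30] = 9.0
        assert calcium.segment_transients(frame, 1.0, min_size=20) == [100]

    def test_empty_mask(self):
        assert calcium.segment_transients(np.zeros((8, 8)), 0.5) == []


class TestComputeAAI:
    def test_constant_movie_zero_aai(self):
        res = calcium.compute_aai(np.full((10, 32, 32), 5.0))
        assert res.aai == 0.0
        assert all(a == 0 for a in res.per_pair_area)

    def test_noiseless_boxcar_exact_recovery(self, somata_map):
        trs = [
            syn.TransientSpec(cell_id=c, onset_frame=2 + 4 * i, duration=2,
                              footprint_area=30 + 5 * i, amplitude=20.0)
            for i, c in enumerate([1, 3, 5, 7])
        ]
        movie, _ = syn.make_calcium_movie(somata_map.labels, trs, T=30)
        res = calcium.compute_aai(movie, min_size=4)
        assert res.aai == sum(t.footprint_area for t in trs)

    def test_offset_invariance(self, somata_map):
        trs = [syn.TransientSpec(2, 3, 2, 40, 15.0)]
        movie, _ = syn.make_calcium_movie(somata_map.labels, trs, T=10)
        a = calcium.compute_aai(movie, min_size=4).aai
        b = calcium.compute_aai(movie + 123.4, min_size=4).aai
        assert a == b

    def test_fixed_threshold_monotone_in_planted_activity(self, somata_map):
        base = [syn.TransientSpec(1, 2, 2, 40, 15.0)]
        extra = base + [syn.TransientSpec(4, 6, 2, 60, 15.0)]
        m1, _ = syn.make_calcium_movie(somata_map.labels, base, T=12)
        m2, _ = syn.make_calcium_movie(somata_map.labels, extra, T=12)
        a1 = calcium.compute_aai(m1, min_size=4, fixed_threshold=7.0).aai
        a2 = calcium.compute_aai(m2, min_size=4, fixed_threshold=7.0).aai
        assert a2 >= a1

    def test_pixel_size_scales_units(self, somata_map):
        trs = [syn.TransientSpec(2, 3, 2, 40, 15.0)]
        movie, _ = syn.make_calcium_movie(somata_map.labels, trs, T=10)
        px = calcium.compute_aai(movie, min_size=4)
        um = calcium.compute_aai(movie, min_size=4, pixel_size=0.5)
        assert um.units == "um^2"
        assert um.aai == pytest.approx(px.aai * 0.25)


class TestExtractTraces:
    def test_uniform_movie_constant_traces(self, somata_map):
        movie = np.full((6,) + somata_map.labels.shape, 3.5)
        traces = calcium.extract_traces(movie, somata_map)
        assert len(traces) == somata_map.n_objects
        for tr in traces:
            np.testing.assert_allclose(tr.values, 3.5)

    def test_boxcar_transient_steps_trace(self, somata_map):
        area = int((somata_map.labels == 2).sum())
        tr = syn.TransientSpec(2, 3, 2, area, 8.0)  # footprint = whole ROI
        movie, _ = syn.make_calcium_movie(somata_map.labels, [tr], T=8, baseline=10.0)
        trace = [t for t in calcium.extract_traces(movie, somata_map) if t.cell_id == 2][0]
        np.testing.assert_allclose(trace.values[3:5], 18.0)
        np.testing.assert_allclose(trace.values[:3], 10.0)

    def test_roi_locality(self, somata_map):
        movie = np.zeros((4,) + somata_map.labels.shape)
        movie[:, somata_map.labels == 1] = 99.0
        traces = {t.cell_id: t for t in calcium.extract_traces(movie, somata_map)}
        np.testing.assert_allclose(traces[1].values, 99.0)
        np.testing.assert_allclose(traces[2].values, 0.0)

    def test_empty_roi_warns(self):
        with pytest.warns(DegenerateDataWarning):
            out = calcium.extract_traces(
                np.zeros((3, 8, 8)), np.zeros((8, 8), dtype=np.int32)
            )
        assert out == []


class TestCountPeaks:
    def test_hand_countable(self):
        assert calcium.count_peaks([0, 1, 0, 2, 0], 0.5, 0.0) == 2

    def test_monotone_trace(self):
        assert calcium.count_peaks(np.arange(10.0), 0.0, 0.0) == 0

    def test_plateau_counts_once(self):
        assert calcium.count_peaks([0, 3, 3, 3, 0], 1.0, 0.0) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        trace = np.round(rng.uniform(0, 10, 50), 1)
        for prom, height in [(0.5, 0.0), (2.0, 5.0), (4.0, 8.0)]:
            ours = calcium.count_peaks(trace, prom, height)
            oracle = brute_force_peaks(trace, prom, height)
            assert ours == oracle

    def test_offset_invariance_in_relative_mode(self, rng):
        trace = rng.uniform(0, 5, 40)
        a = calcium.count_peaks(trace, 1.0, 2.0, height_mode="relative_min")
        b = calcium.count_peaks(trace + 57.0, 1.0, 2.0, height_mode="relative_min")
        assert a == b

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            calcium.count_peaks([1.0, 2.0], 0.1, 0.0)

    @given(st.lists(st.integers(0, 20), min_size=3, max_size=60))
    def test_oracle_equivalence_property(self, values):
        trace = np.asarray(values, dtype=float)
        assert calcium.count_peaks(trace, 1.0, 0.0) == brute_force_peaks(
            trace, 1.0, 0.0
        )


class TestDeltaPeakCount:
    def test_identical_traces_zero_delta(self, rng):
        v = rng.uniform(0, 5, 30)
        pre = calcium.CellTrace(1, v)
        post = calcium.CellTrace(1, v.copy())
        res = calcium.delta_peak_count(pre, post, {"min_prominence": 1, "min_height": 0})
        assert res.delta == 0

    def test_planted_transients_counted(self, somata_map):
        area = 30
        mk = lambda onsets: syn.make_calcium_movie(
            somata_map.labels,
            [syn.TransientSpec(3, o, 2, area, 25.0) for o in onsets],
            T=40, baseline=10.0,
        )[0]
        pre_movie, post_movie = mk([10]), mk([5, 14, 23, 32])
        pre = [t for t in calcium.extract_traces(pre_movie, somata_map) if t.cell_id == 3][0]
        post = [t for t in calcium.extract_traces(post_movie, somata_map) if t.cell_id == 3][0]
        params = {"min_prominence": 0.5, "min_height": 10.2}
        res = calcium.delta_peak_count(pre, post, params)
        assert (res.pre_count, res.post_count, res.delta) == (1, 4, 3)

    def test_flat_traces(self):
        flat = calcium.CellTrace(2, np.full(20, 4.0))
        res = calcium.delta_peak_count(flat, flat, {"min_prominence": 1, "min_height": 0})
        assert (res.pre_count, res.post_count, res.delta) == (0, 0, 0)

    def test_mismatched_cell_ids_rejected(self):
        a = calcium.CellTrace(1, np.zeros(5))
        b = calcium.CellTrace(2, np.zeros(5))
        with pytest.raises(ValidationError):
            calcium.delta_peak_count(a, b, {"min_prominence": 1, "min_height": 0})
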