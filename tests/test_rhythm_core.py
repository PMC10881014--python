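import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishrhythm.rhythm_core import (
    best_fit_beat,
    coefficient_of_variation,
    compute_iois,
    goodness_of_fit,
    ioi_histogram,
    summarize_sequence,
)
from fishrhythm.sequence_builder import CallSequence
from fishrhythm.selection_io import ElementRecord
from fishrhythm.synthetic_data import generate_isochronous_sequence

from oracles import brute_force_beat


class TestComputeIois:
    @pytest.mark.parametrize(
        "onsets, expected",
        [
            ([0, 1, 3], [1, 2]),
            ([5, 5.2, 5.4, 5.6], [0.2, 0.2, 0.2]),  # one element every 200 ms
        ],
    )
    def test_successive_differences(self, onsets, expected):
        assert compute_iois(onsets).values_s == pytest.approx(expected)

    @pytest.mark.parametrize("onsets", [[0, 0], [3, 2, 4], [1.0]])
    def test_invalid_onsets_rejected(self, onsets):
        with pytest.raises(ValueError):
            compute_iois(onsets)


class TestCoefficientOfVariation:
    def test_zero_dispersion(self):
        assert coefficient_of_variation([2, 2, 2]) == 0.0

    def test_hand_computed_value(self):
        # mean 2, sample SD sqrt(2)
        assert coefficient_of_variation([1, 3]) == pytest.approx(np.sqrt(2) / 2)

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        base = np.array([1.0, 3.0, 2.0, 2.5])
        assert coefficient_of_variation(c * base) == pytest.approx(
            coefficient_of_variation(base)
        )

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])


class TestIoiHistogram:
    def test_hand_binning(self):
        counts, edges = ioi_histogram([0.1, 0.15, 0.35], bin_width_s=0.2)
        assert counts.tolist() == [2, 1]
        assert edges == pytest.approx([0.0, 0.2, 0.4])

    def test_empty_series(self):
        counts, _ = ioi_histogram([], bin_width_s=0.2)
        assert counts.size == 0

    @given(st.lists(st.floats(0.01, 30.0), min_size=1, max_size=60))
    def test_counts_conserved(self, values):
        counts, edges = ioi_histogram(values, bin_width_s=0.37)
        assert counts.sum() == len(values)
        assert len(edges) == len(counts) + 1

    def test_non_positive_width_rejected(self):
        with pytest.raises(ValueError):
            ioi_histogram([0.5], bin_width_s=0.0)


class TestGoodnessOfFit:
    def test_perfect_grid_is_zero(self):
        onsets = np.arange(10) * 0.2
        assert goodness_of_fit(onsets, beat_hz=5.0, phase_s=0.0) == pytest.approx(0.0)

    def test_midpoint_onset_is_one(self):
        # An onset exactly midway between grid points is maximally off-grid.
        assert goodness_of_fit([0.1], beat_hz=5.0, phase_s=0.0) == pytest.approx(1.0)

    def test_gaussian_grid_jitter_matches_closed_form(self, rng):
        # Onsets jittered about a fixed grid with SD = 5% of the period give a
        # mean deviation of E|N(0, 0.05 T)| / (T/2) = 0.1 * sqrt(2/pi).
        period = 2.0
        onsets = np.arange(2000) * period + rng.normal(0.0, 0.05 * period, 2000)
        expected = 0.1 * np.sqrt(2 / np.pi)
        assert goodness_of_fit(onsets, 1 / period, 0.0) == pytest.approx(expected, rel=0.05)

    def test_non_positive_beat_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([0.0, 1.0], beat_hz=0.0)


class TestBestFitBeat:
    def test_five_hz_worked_example(self):
        # One element every 200 ms <-> a 5 Hz metronomic grid, fit exactly.
        fit = best_fit_beat([0.0, 0.2, 0.4, 0.6, 0.8])
        assert fit.beat_hz == pytest.approx(5.0, abs=1e-12)
        assert fit.deviation == pytest.approx(0.0, abs=1e-9)

    def test_slow_train_recovers_reciprocal_period(self):
        fit = best_fit_beat([0.0, 2.78, 5.56, 8.34])
        assert fit.beat_hz == pytest.approx(1 / 2.78, abs=1e-3)
        assert fit.deviation == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(-50.0, 50.0))
    def test_translation_invariance(self, shift):
        onsets = np.array([0.0, 2.7, 5.5, 8.1, 11.0]) + 60.0
        base = best_fit_beat(onsets)
        moved = best_fit_beat(onsets + shift)
        assert moved.beat_hz == pytest.approx(base.beat_hz, abs=1e-12)
        assert moved.deviation == pytest.approx(base.deviation, abs=1e-9)

    @pytest.mark.parametrize("c", [0.5, 2.0, 3.7])
    def test_scale_covariance(self, c):
        # Stretching time by c divides the best beat by c (at matched resolution).
        onsets = np.array([0.0, 2.7, 5.5, 8.1, 11.0])
        base = best_fit_beat(onsets, resolution_hz=0.001)
        scaled = best_fit_beat(onsets * c, resolution_hz=0.001 / c)
        assert scaled.beat_hz == pytest.approx(base.beat_hz / c, rel=1e-9)
        assert scaled.deviation == pytest.approx(base.deviation, abs=1e-9)

    def test_noiseless_recovery_within_resolution(self, rng):
        for _ in range(10):
            beat = rng.uniform(0.1, 3.0)
            onsets = np.arange(8) / beat
            assert best_fit_beat(onsets).beat_hz == pytest.approx(beat, abs=0.001)

    def test_matches_brute_force_oracle_on_small_sequences(self, rng):
        """Spot check against the exhaustive finer-grid oracle (the full
        200-sequence sweep runs in the acceptance suite)."""
        for _ in range(10):
            beat = rng.uniform(0.25, 0.7)
            jitter = rng.uniform(0.0, 0.3)
            n = int(rng.integers(3, 13))
            els = generate_isochronous_sequence(beat, jitter, n, rng=rng)
            onsets = [e.begin_s for e in els]
            fit = best_fit_beat(onsets)
            oracle_f, _ = brute_force_beat(onsets)
            assert fit.beat_hz == pytest.approx(oracle_f, abs=0.001)

    def test_deviation_increases_with_jitter(self, rng):
        """Mean goodness-of-fit deviation grows monotonically with the
        generator's IOI jitter."""
        mean_devs = []
        for jitter in (0.0, 0.05, 0.1, 0.2):
            devs = []
            for k in range(30):
                sub = np.random.default_rng(1000 + k)  # same seed batch per jitter
                els = generate_isochronous_sequence(0.36, jitter, 21, rng=sub)
                devs.append(best_fit_beat([e.begin_s for e in els]).deviation)
            mean_devs.append(np.mean(devs))
        assert all(a < b for a, b in zip(mean_devs, mean_devs[1:]))

    def test_too_few_onsets_rejected(self):
        with pytest.raises(ValueError):
            best_fit_beat([0.0, 1.0])

    def test_degenerate_onsets_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            best_fit_beat([0.0, 1e-12, 2e-12])


class TestSummarizeSequence:
    def make_sequence(self, onsets):
        elements = tuple(
            ElementRecord(selection_id=i + 1, begin_s=t, end_s=t + 0.2,
                          low_hz=100, high_hz=500, source_id="rec")
            for i, t in enumerate(onsets)
        )
        return CallSequence(elements=elements, source_id="rec")

    def test_noiseless_sequence_identity(self):
        onsets = np.arange(21) / 0.36
        summary = summarize_sequence(self.make_sequence(onsets))
        assert summary.cv == pytest.approx(0.0, abs=1e-12)
        assert summary.fit.beat_hz == pytest.approx(0.36, abs=0.001)
        assert summary.n_elements == 21

    def test_one_minute_span_at_pooled_beat(self):
        # 21 elements at 0.36 Hz span (21-1)/0.36 ~ 55.6 s: fits a 1-minute file.
        onsets = np.arange(21) / 0.36
        assert onsets[-1] == pytest.approx(55.6, abs=0.1)

    def test_jittered_sequence_cv_tracks_generator(self, rng):
        cvs = []
        for _ in range(200):
            els = generate_isochronous_sequence(0.36, 0.18, 21, rng=rng)
            cvs.append(summarize_sequence_cv(els))
        assert np.mean(cvs) == pytest.approx(0.18, abs=0.02)


def summarize_sequence_cv(elements):
    return coefficient_of_variation(compute_iois([e.begin_s for e in elements]))
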