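"""Stride detector: prior, peak detection, repairs, stance segmentation."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from gaitreliab.config import RunConfig
from gaitreliab.errors import DetectionError, PriorEstimationError
from gaitreliab.stride_detection import (RepairLog, StridePrior,
                                         detect_foot_contacts,
                                         estimate_stride_prior,
                                         height_threshold,
                                         repair_false_negatives,
                                         segment_stance_swing)

FS = 100.0


def _bump_train(contact_times, heights, fs=FS, duration=None, width_s=0.06):
    duration = duration or (max(contact_times) + 2.0)
    n = int(duration * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for c, h in zip(contact_times, heights):
        x += h * np.exp(-0.5 * ((t - c) / (width_s / 2.355)) ** 2)
    return x


class TestStridePrior:
    def test_pure_sinusoid_gives_reciprocal(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 0.8 * t)
        prior = estimate_stride_prior(x, FS)
        assert prior.average_stride_time_s == pytest.approx(1.25, abs=0.01)
        assert prior.dominant_frequency_hz == pytest.approx(0.8, abs=0.01)

    def test_synthetic_walk_prior_matches_ground_truth(self, preprocessed,
                                                       oriented):
        span = preprocessed.walk_bounds_per_sensor["left_foot"]
        ml = oriented["left_foot"].accel_ml[span[0]:span[1]]
        prior = estimate_stride_prior(ml, FS)
        assert prior.average_stride_time_s == pytest.approx(1.2, abs=0.05)

    def test_white_noise_is_rejected(self, rng):
        x = rng.normal(size=int(40 * FS))
        with pytest.raises(PriorEstimationError):
            estimate_stride_prior(x, FS)

    def test_too_short_signal_rejected(self):
        with pytest.raises(PriorEstimationError):
            estimate_stride_prior(np.sin(np.arange(500) * 0.05), FS)

    def test_reciprocal_invariant(self):
        with pytest.raises(ValueError):
            StridePrior(average_stride_time_s=1.0, dominant_frequency_hz=0.5)


class TestDetectContacts:
    def test_constant_signal_has_no_peaks(self):
        prior = StridePrior(1.2, 1 / 1.2)
        assert detect_foot_contacts(np.ones(2000), prior, FS).size == 0

    def test_close_peaks_keep_only_the_higher(self):
        """Two peaks 0.5 x prior apart: distance pruning keeps the higher,
        as a brute-force pruning oracle confirms."""
        prior = StridePrior(1.2, 1 / 1.2)
        x = _bump_train([2.0, 2.6, 4.4], [5.0, 8.0, 8.0], duration=6.0)
        got = detect_foot_contacts(x, prior, FS)

        # oracle: all local maxima above mean+SD, greedily pruned by height
        h = height_threshold(x)
        raw, _ = find_peaks(x, height=h)
        keep = []
        for p in sorted(raw, key=lambda i: -x[i]):
            if all(abs(p - q) >= 0.75 * 1.2 * FS for q in keep):
                keep.append(p)
        assert sorted(got.tolist()) == sorted(keep)
        assert int(2.6 * FS) in got.tolist()
        assert int(2.0 * FS) not in got.tolist()

    def test_fixture_walk_contacts_match_ground_truth(self, default_walk,
                                                      foot_events):
        _, truth = default_walk
        for placement in ("left_foot", "right_foot"):
            det = foot_events[placement].contact_times() + 2.0
            tt = truth.foot_contacts[placement]
            matched = sum(1 for c in tt if np.min(np.abs(det - c)) <= 0.05)
            assert matched / len(tt) >= 0.95

    def test_detection_invariant_to_signal_gain(self, oriented, preprocessed):
        """Mean+SD thresholds scale with the signal, so doubling the
        accelerometer gain leaves contact indices unchanged."""
        span = preprocessed.walk_bounds_per_sensor["left_foot"]
        vt = oriented["left_foot"].accel_vt
        prior = StridePrior(1.2, 1 / 1.2)
        a = detect_foot_contacts(vt, prior, FS, span)
        b = detect_foot_contacts(2.0 * vt, prior, FS, span)
        np.testing.assert_array_equal(a, b)


class TestRepairFalseNegatives:
    def _train(self, attenuated=0.6):
        contacts = np.arange(2.0, 26.0, 1.2)
        heights = np.full(contacts.size, 10.0)
        heights[8] *= attenuated
        x = _bump_train(contacts, heights, duration=28.0)
        return x, contacts

    def test_attenuated_impact_recovered(self):
        """An impact attenuated below the mean+SD threshold (but above 0.75 x
        that threshold) is invisible to the first pass and recovered by the
        false-negative pass."""
        contacts = np.arange(2.0, 26.0, 1.2)
        clean = _bump_train(contacts, np.full(contacts.size, 10.0),
                            duration=28.0)
        thr = height_threshold(clean)
        heights = np.full(contacts.size, 10.0)
        heights[8] = 0.9 * thr
        x = _bump_train(contacts, heights, duration=28.0)
        prior = StridePrior(1.2, 1 / 1.2)
        first = detect_foot_contacts(x, prior, FS)
        missed = contacts[8]
        assert np.min(np.abs(first / FS - missed)) > 0.1  # first pass missed it
        log = RepairLog()
        repaired = repair_false_negatives(first, x, prior, FS, repair_log=log)
        assert np.min(np.abs(repaired / FS - missed)) <= 0.05
        assert log.false_negative_insertions == 1

    def test_no_op_when_gaps_are_small(self):
        x, _ = self._train(attenuated=1.0)
        prior = StridePrior(1.2, 1 / 1.2)
        first = detect_foot_contacts(x, prior, FS)
        repaired = repair_false_negatives(first, x, prior, FS)
        np.testing.assert_array_equal(first, repaired)

    def test_noise_only_gap_gets_no_insertion(self, rng):
        contacts = np.arange(2.0, 26.0, 1.2)
        heights = np.full(contacts.size, 10.0)
        heights[8] = 0.0  # a genuinely absent impact
        x = _bump_train(contacts, heights, duration=28.0)
        x += rng.normal(0, 0.05, x.size)  # noise floor << 0.75 x threshold
        prior = StridePrior(1.2, 1 / 1.2)
        first = detect_foot_contacts(x, prior, FS)
        repaired = repair_false_negatives(first, x, prior, FS)
        assert repaired.size == first.size


class TestStanceSwing:
    def test_fixture_stance_durations(self, default_spec, foot_events):
        stance_s = default_spec.stance_fraction * 1.2
        for ev in foot_events.values():
            assert ev.stance_durations().mean() == pytest.approx(stance_s,
                                                                 abs=0.05)

    def test_stance_swing_tile_the_detected_span(self, foot_events):
        for ev in foot_events.values():
            intervals = sorted(ev.stance_intervals + ev.swing_intervals)
            assert intervals[0][0] == ev.contact_samples[0]
            assert intervals[-1][1] == ev.contact_samples[-1]
            for (s0, e0), (s1, e1) in zip(intervals[:-1], intervals[1:]):
                assert e0 == s1  # contiguous, no overlap

    def test_clean_walk_needs_no_repairs(self, foot_events):
        for ev in foot_events.values():
            assert ev.repair_log.false_negative_insertions == 0
            assert ev.repair_log.false_positive_removals == 0

    def test_left_right_stride_counts_close(self, foot_events):
        assert abs(foot_events["left_foot"].n_strides
                   - foot_events["right_foot"].n_strides) <= 1

    def test_spurious_mid_swing_peak_removed(self, rng):
        fs = FS
        contacts = np.arange(2.0, 20.0, 1.2)
        x = _bump_train(contacts, np.full(contacts.size, 10.0), duration=22.0)
        n = x.size
        gyro = np.zeros(n)
        for c in contacts:  # quiescent stance after each contact
            swing0 = int((c + 0.72) * fs)
            swing1 = int((c + 1.2) * fs)
            gyro[swing0:swing1] = 150.0
            x[swing0:swing1] += 3.0 * rng.normal(size=swing1 - swing0)
        # inject a spurious contact candidate mid-swing
        cands = np.sort(np.append((contacts * fs).astype(int),
                                  int((contacts[5] + 0.9) * fs)))
        log = RepairLog()
        ev = segment_stance_swing(cands, np.abs(x), gyro, fs, foot="left",
                                  repair_log=log)
        assert log.false_positive_removals >= 1
        assert ev.contact_samples.size == contacts.size

    def test_continuous_motion_raises_detection_failure(self, rng):
        n = 3000
        accel_mag = np.abs(rng.normal(10, 2, n))   # never quiescent
        gyro_mag = np.abs(rng.normal(100, 10, n))
        cands = np.arange(200, 2800, 120)
        with pytest.raises(DetectionError):
            segment_stance_swing(cands, accel_mag, gyro_mag, FS, foot="left")

    def test_needs_two_contacts(self):
        with pytest.raises(DetectionError):
            segment_stance_swing(np.array([100]), np.zeros(500),
                                 np.zeros(500), FS)
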