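"""Lumbar event chain: filtering, first contact, lateralisation, matching."""

import numpy as np
import pytest

from gaitreliab import (detect_gait_events, estimate_stride_prior, orient,
                        preprocess)
from gaitreliab.config import RunConfig
from gaitreliab.errors import LowBackDetectionError, ValidationError
from gaitreliab.lowback_events import (bandpass_ap, bandpass_filter,
                                       detect_first_contact,
                                       detect_lowback_events,
                                       lateralize_and_match)
from gaitreliab.orientation import OrientedSignal
from gaitreliab.stride_detection import StridePrior
from gaitreliab.synthetic_gait import WalkSpec, generate_walk

FS = 100.0


def _oriented(ap, ml=None):
    n = ap.size
    zeros = np.zeros(n)
    return OrientedSignal(accel_vt=zeros.copy(), accel_ml=ml if ml is not None
                          else zeros.copy(), accel_ap=ap,
                          gyro_vt=zeros.copy(), gyro_ml=zeros.copy(),
                          gyro_ap=zeros.copy(), sample_rate_hz=FS,
                          source="low_back")


class TestBandpass:
    def test_stopband_attenuation_at_0p1_hz(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        y = bandpass_filter(x, FS)
        seg = slice(int(20 * FS), int(100 * FS))
        assert np.abs(y[seg]).max() <= 0.1 * 1.0   # >= 90% attenuated

    def test_passband_flat_at_1_hz(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass_filter(x, FS)
        seg = slice(int(10 * FS), int(50 * FS))
        amp = 0.5 * (y[seg].max() - y[seg].min())
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_zero_in_zero_out(self):
        sig = _oriented(np.zeros(3000))
        np.testing.assert_allclose(bandpass_ap(sig), 0.0, atol=1e-12)

    def test_integrate_twice_mode_differs(self):
        rng = np.random.default_rng(0)
        sig = _oriented(rng.normal(size=3000))
        once = bandpass_ap(sig, RunConfig(lowback_ap_mode="integrate_once"))
        twice = bandpass_ap(sig, RunConfig(lowback_ap_mode="integrate_twice"))
        assert not np.allclose(once, twice)


def _step_bumps(contact_times, fs=FS, duration=None, amp=1.0):
    duration = duration or (max(contact_times) + 2.0)
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros(t.size)
    for c in contact_times:
        d = t - c
        x += amp * (-d / 0.05 ** 2) * np.exp(-d ** 2 / (2 * 0.05 ** 2))
    return x


class TestFirstContact:
    def test_first_contact_found_on_bump_train(self):
        contacts = np.arange(3.0, 20.0, 0.6)
        ap = _step_bumps(contacts)
        sig = _oriented(ap)
        filt = bandpass_ap(sig)
        prior = StridePrior(1.2, 1 / 1.2)
        first = detect_first_contact(filt, prior, FS)
        assert abs(first / FS - contacts[0]) <= 0.1

    def test_flat_signal_fails(self):
        prior = StridePrior(1.2, 1 / 1.2)
        with pytest.raises(LowBackDetectionError):
            detect_first_contact(np.zeros(3000), prior, FS)

    def test_halved_prior_keeps_the_first_peak(self):
        """The distance constraint is inactive for the first event."""
        contacts = np.arange(3.0, 20.0, 1.2)
        filt = bandpass_ap(_oriented(_step_bumps(contacts)))
        a = detect_first_contact(filt, StridePrior(1.2, 1 / 1.2), FS)
        b = detect_first_contact(filt, StridePrior(0.6, 1 / 0.6), FS)
        assert a == b


class TestLateralizeAndMatch:
    def _chain(self, spec):
        rec, truth = generate_walk(spec)
        pre = preprocess(rec)
        oriented, events = {}, {}
        for p in ("left_foot", "right_foot", "low_back"):
            span = pre.walk_bounds_per_sensor[p]
            oriented[p] = orient(pre.sensors[p].accel, pre.sensors[p].gyro,
                                 FS, source=p, walk_span=span)
        for p in ("left_foot", "right_foot"):
            span = pre.walk_bounds_per_sensor[p]
            prior = estimate_stride_prior(oriented[p].accel_ml[span[0]:span[1]],
                                          FS)
            events[p] = detect_gait_events(oriented[p], FS,
                                           foot=p.split("_")[0],
                                           walk_bounds=span, prior=prior)
        lb = detect_lowback_events(
            oriented["low_back"], events["left_foot"], events["right_foot"],
            StridePrior(1.2, 1 / 1.2),
            walk_bounds=pre.walk_bounds_per_sensor["low_back"])
        return truth, events, lb

    def test_clean_walk_contacts_match_feet(self):
        spec = WalkSpec(rng_seed=21, duration_s=60.0, noise_sd_accel=0.1,
                        noise_sd_gyro=0.3)
        truth, events, lb = self._chain(spec)
        for foot in ("left_foot", "right_foot"):
            det = lb.contact_samples[foot] / FS + 2.0
            tt = truth.foot_contacts[foot]
            assert len(det) == len(tt)
            err = np.abs(det[:, None] - tt[None, :]).min(axis=1)
            assert np.median(err) <= 0.05
            assert np.mean(err <= 0.1) >= 0.9
        assert lb.alternation_ok()

    def test_lateralisation_matches_anchor_foot(self):
        """The ML sign rule names the foot that made the anchor contact."""
        hits = 0
        specs = [WalkSpec(rng_seed=s, duration_s=60.0) for s in range(30, 35)]
        specs += [WalkSpec(rng_seed=s, duration_s=60.0, step_time_ratio=1.3)
                  for s in range(35, 40)]
        for spec in specs:
            truth, events, lb = self._chain(spec)
            anchor_t = lb.contact_samples[f"{lb.first_foot}_foot"][0] / FS + 2.0
            nearest = {f: np.min(np.abs(truth.foot_contacts[f] - anchor_t))
                       for f in ("left_foot", "right_foot")}
            hits += min(nearest, key=nearest.get) == f"{lb.first_foot}_foot"
        assert hits == len(specs)

    def test_ml_convention_flip_flips_the_foot(self):
        spec = WalkSpec(rng_seed=21, duration_s=60.0, noise_sd_accel=0.1,
                        noise_sd_gyro=0.3)
        truth, events, lb = self._chain(spec)
        flipped_spec = WalkSpec(rng_seed=21, duration_s=60.0,
                                noise_sd_accel=0.1, noise_sd_gyro=0.3,
                                ml_positive_foot="left")
        _, _, lb_flipped = self._chain(flipped_spec)
        assert lb_flipped.first_foot != lb.first_foot

    def test_missing_foot_template_is_an_error(self):
        filt = np.zeros(1000)
        with pytest.raises(ValidationError, match="template unavailable"):
            lateralize_and_match(filt, filt, None, None, 100,
                                 StridePrior(1.2, 1 / 1.2), FS)
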