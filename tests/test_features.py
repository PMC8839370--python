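"""Feature catalogue and the four computation domains."""

import json
from pathlib import Path

import numpy as np
import pytest

from gaitreliab.config import RunConfig
from gaitreliab.errors import CatalogueError
from gaitreliab.features import (DOMAIN_COUNTS, SOURCE_COUNTS, TOTAL_FEATURES,
                                 approximate_entropy, assemble, block_stats,
                                 build_catalogue, complexity_features,
                                 frequency_features, lagged_autocorrelation,
                                 load_manifest, reference_foot, sample_entropy,
                                 symmetry_index, time_normalise)
from gaitreliab.features.assemble import FeatureVector
from gaitreliab.io_preprocess import SubjectMeta
from gaitreliab.synthetic_gait import WalkSpec, generate_walk
from gaitreliab.pipeline import run_assessment


# ----------------------------------------------------------------------
# Catalogue
# ----------------------------------------------------------------------

class TestCatalogue:
    def test_counts_per_domain_and_source(self):
        defs = build_catalogue()
        assert len(defs) == TOTAL_FEATURES == 166
        by_domain = {d: sum(x.domain == d for x in defs)
                     for d in DOMAIN_COUNTS}
        assert by_domain == DOMAIN_COUNTS
        by_source = {s: sum(x.source == s for x in defs)
                     for s in SOURCE_COUNTS}
        assert by_source == SOURCE_COUNTS

    def test_names_unique(self):
        names = [d.name for d in build_catalogue()]
        assert len(set(names)) == len(names)

    def test_shipped_manifest_matches_code(self):
        assert load_manifest() == build_catalogue()


# ----------------------------------------------------------------------
# Spatio-temporal
# ----------------------------------------------------------------------

class TestSpatioTemporal:
    def test_block_arithmetic_drops_partial_blocks(self):
        """25 strides -> two 10-stride blocks; the last 5 are unused."""
        series = np.concatenate([np.full(10, 1.0), np.full(10, 3.0),
                                 np.full(5, 100.0)])
        mean, sd, cv = block_stats(series, 10)
        assert mean == 2.0          # (1 + 3) / 2, the 100s never enter
        assert sd == 0.0

    def test_fewer_than_one_block_is_missing(self):
        assert block_stats(np.arange(9.0), 10) is None

    def test_fixture_stride_time_and_height_norm(self, pipeline_result):
        v = pipeline_result.features.values
        assert v["left_foot_stride_time_mean"] == pytest.approx(1.2, abs=0.02)
        # 1.3 m strides, 1.80 m subject -> 0.722
        assert v["left_foot_stride_length_height_norm"] == pytest.approx(
            1.3 / 1.8, abs=0.02)

    def test_cadence_from_stride_time(self, pipeline_result):
        """1.2-s strides are two steps each: 100 steps/min."""
        v = pipeline_result.features.values
        assert v["left_foot_cadence"] == pytest.approx(100.0, abs=2.0)


# ----------------------------------------------------------------------
# Frequency
# ----------------------------------------------------------------------

def _sig_from_axes(vt, ml=None, ap=None, fs=100.0):
    from gaitreliab.orientation import OrientedSignal
    n = vt.size
    z = np.zeros(n)
    return OrientedSignal(accel_vt=vt, accel_ml=ml if ml is not None else z,
                          accel_ap=ap if ap is not None else z,
                          gyro_vt=z, gyro_ml=z, gyro_ap=z,
                          sample_rate_hz=fs, source="left_foot")


class TestFrequency:
    def test_pure_sinusoid_dominant_and_density(self):
        t = np.arange(6000) / 100.0
        sig = _sig_from_axes(np.sin(2 * np.pi * 1.0 * t))
        values, _ = frequency_features({"left_foot": sig})
        assert values["left_foot_vt_dominant_frequency"] == pytest.approx(
            1.0, abs=0.02)
        assert values["left_foot_vt_dominant_density"] >= 0.95

    def test_two_equal_sinusoids_split_density(self):
        t = np.arange(6000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 2.0 * t)
        values, _ = frequency_features({"left_foot": _sig_from_axes(x)})
        assert values["left_foot_vt_dominant_density"] == pytest.approx(
            0.5, abs=0.05)

    def test_lowback_vt_dominant_is_step_frequency(self, pipeline_result):
        v = pipeline_result.features.values
        assert v["low_back_vt_dominant_frequency"] == pytest.approx(
            2.0 / 1.2, abs=0.05)

    def test_flat_spectrum_marks_missing(self, rng):
        sig = _sig_from_axes(rng.normal(size=6000))
        values, missing = frequency_features({"left_foot": sig})
        assert "left_foot_vt_dominant_frequency" in missing
        assert missing["left_foot_vt_dominant_frequency"] == "flat_spectrum"

    def test_short_span_marks_missing(self):
        t = np.arange(1500) / 100.0   # 15 s < 30 s minimum
        sig = _sig_from_axes(np.sin(2 * np.pi * t))
        _, missing = frequency_features({"left_foot": sig})
        assert missing["left_foot_vt_dominant_frequency"] == "insufficient_span"


# ----------------------------------------------------------------------
# Complexity (with naive O(N^2) oracles)
# ----------------------------------------------------------------------

def naive_sampen(x, m=2, r=0.2):
    n = len(x)
    def count(mm):
        templ = [x[i:i + mm] for i in range(n - m)]  # equal template counts
        c = 0
        for i in range(len(templ)):
            for j in range(len(templ)):
                if i == j:
                    continue
                if max(abs(a - b) for a, b in zip(templ[i], templ[j])) <= r:
                    c += 1
        return c
    b = count(m)
    a = count(m + 1)
    return -np.log(a / b) if a > 0 and b > 0 else np.inf


def naive_apen(x, m=2, r=0.2):
    n = len(x)
    def phi(mm):
        templ = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for i in range(len(templ)):
            c = sum(1 for j in range(len(templ))
                    if max(abs(a - b) for a, b in zip(templ[i], templ[j])) <= r)
            total += np.log(c / len(templ))
        return total / len(templ)
    return phi(m) - phi(m + 1)


class TestComplexity:
    def test_entropies_match_naive_oracle(self, rng):
        x = rng.normal(size=300)
        r = 0.2 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(
            naive_sampen(x.tolist(), 2, r), abs=1e-8)
        assert approximate_entropy(x, 2, r) == pytest.approx(
            naive_apen(x.tolist(), 2, r), abs=1e-8)

    def test_periodic_signal_is_regular(self):
        # regularity limit: nearly every length-2 match extends to length 3
        x = np.sign(np.sin(2 * np.pi * np.arange(2500) / 100.0))
        assert sample_entropy(x) < 0.05

    def test_noise_less_regular_than_periodic(self, rng):
        t = np.arange(1000)
        periodic = np.sin(2 * np.pi * t / 100.0)
        noise = rng.normal(size=1000)
        assert sample_entropy(noise) > sample_entropy(periodic)

    def test_stride_periodic_autocorrelation_is_one(self):
        x = np.tile(np.sin(2 * np.pi * np.arange(100) / 100.0), 25)
        assert lagged_autocorrelation(x, 100) == pytest.approx(1.0, abs=1e-9)

    def test_time_normalise_uses_exactly_the_window(self):
        x = np.arange(5000.0)
        contacts = np.arange(0, 5000, 110)
        out = time_normalise(x, contacts, 25, 100)
        assert out.size == 25 * 100

    def test_short_walk_marks_complexity_missing(self):
        spec = WalkSpec(duration_s=34.0, rng_seed=9,
                        subject_meta=SubjectMeta(height_m=1.7))
        rec, _ = generate_walk(spec)
        result = run_assessment(rec)
        fv = result.features
        assert fv.n_features == 166
        cx_missing = [k for k, r in fv.missing.items()
                      if r == "insufficient_strides" and "entropy" in k]
        assert len(cx_missing) == 18  # 3 sensors x 3 axes x 2 entropies


# ----------------------------------------------------------------------
# Asymmetry
# ----------------------------------------------------------------------

class TestAsymmetry:
    def test_symmetry_index_formula(self):
        assert symmetry_index(0.44, 0.40) == pytest.approx(9.5238, abs=1e-3)
        assert symmetry_index(0.4, 0.4) == 0.0

    def test_left_foot_fallback_for_undefined_paretic_side(self):
        assert reference_foot(SubjectMeta(paretic_side="unknown")) == "left"
        assert reference_foot(SubjectMeta(paretic_side="both")) == "left"
        assert reference_foot(SubjectMeta(paretic_side="right")) == "right"

    def test_symmetric_fixture_has_near_unit_ratios(self, pipeline_result):
        v = pipeline_result.features.values
        for q in ("swing_time", "stance_time", "stride_time"):
            assert v[f"combined_{q}_si"] < 3.0
            assert v[f"combined_{q}_ratio"] == pytest.approx(1.0, abs=0.03)

    def test_temporal_asymmetry_is_detected(self):
        spec = WalkSpec(rng_seed=13, duration_s=60.0, step_time_ratio=1.3,
                        stance_fraction=(0.55, 0.65),
                        subject_meta=SubjectMeta(paretic_side="left",
                                                 height_m=1.7))
        rec, _ = generate_walk(spec)
        fv = run_assessment(rec).features
        assert fv.values["combined_stance_time_si"] > 5.0
        ratio = fv.values["combined_step_time_ratio"]
        assert max(ratio, 1.0 / ratio) == pytest.approx(1.3, rel=0.1)


# ----------------------------------------------------------------------
# Assembly
# ----------------------------------------------------------------------

class TestAssemble:
    def test_exact_key_coverage(self, pipeline_result):
        fv = pipeline_result.features
        assert fv.n_features == 166
        assert set(fv.values) == {d.name for d in build_catalogue()}

    def test_unknown_keys_rejected(self):
        with pytest.raises(CatalogueError):
            assemble([({"bogus_feature": 1.0}, {})])

    def test_uncomputed_features_carry_reasons(self):
        fv = assemble([({}, {})])
        assert fv.n_features == 166
        assert all(reason == "not_computed" for reason in fv.missing.values())

    def test_pipeline_is_deterministic(self, default_walk, pipeline_result):
        recording, _ = default_walk
        again = run_assessment(recording)
        a = pipeline_result.features.values
        b = again.features.values
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == b[k] or (np.isnan(a[k]) and np.isnan(b[k]))
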