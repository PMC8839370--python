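"""ICC(2,1), SEM/MDC/rMDC closed forms, classification, cohort tables."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from gaitreliab.errors import ReliabilityError
from gaitreliab.features import build_catalogue
from gaitreliab.reliability import (classify_icc, icc_2_1, reliability_table,
                                    sem_mdc_rmdc)
from gaitreliab.synthetic_gait import CohortSpec, generate_cohort


def _pingouin_icc(matrix):
    n, k = matrix.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "session": np.tile(np.arange(k), n),
        "value": matrix.ravel(),
    })
    row = pg.intraclass_corr(df, targets="subject", raters="session",
                             ratings="value").set_index("Type").loc["ICC(A,1)"]
    return float(row["ICC"])


class TestIcc:
    def test_perfect_agreement(self):
        matrix = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        icc, ci = icc_2_1(matrix)
        assert icc == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ReliabilityError):
            icc_2_1(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ReliabilityError):
            icc_2_1(np.full((5, 2), 3.0))

    def test_matches_variance_components_oracle_on_random_fixtures(self, rng):
        for _ in range(50):
            scale = rng.uniform(0.5, 2.0)
            matrix = (rng.normal(size=(10, 2))
                      + scale * rng.normal(size=(10, 1)))
            icc, ci = icc_2_1(matrix)
            assert icc == pytest.approx(_pingouin_icc(matrix), abs=1e-10)
            assert ci[0] <= icc <= ci[1]

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0),
           seed=st.integers(0, 2 ** 16))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        r = np.random.default_rng(seed)
        matrix = r.normal(size=(8, 2)) + r.normal(size=(8, 1))
        icc, _ = icc_2_1(matrix)
        icc_t, _ = icc_2_1(a * matrix + b)
        assert icc_t == pytest.approx(icc, abs=1e-8)

    def test_converges_to_analytic_icc_at_large_n(self):
        estimates = [
            icc_2_1(generate_cohort(CohortSpec(
                n_subjects=200, between_subject_sd=1.0,
                within_subject_sd=0.5, rng_seed=seed))[0])[0]
            for seed in range(40)
        ]
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.02)


class TestSemMdc:
    def test_perfect_icc_means_no_measurement_error(self):
        sem, mdc, rmdc = sem_mdc_rmdc(1.0, np.array([1.0, 2.0, 3.0, 4.0]))
        assert sem == mdc == rmdc == 0.0

    def test_closed_form_at_half_icc(self):
        """ICC 0.5, SD 2 -> SEM 1.4142, MDC 3.9199, rMDC 1.9600."""
        pooled = np.array([-math.sqrt(2.0), math.sqrt(2.0)])  # ddof=1 SD = 2
        assert np.std(pooled, ddof=1) == pytest.approx(2.0)
        sem, mdc, rmdc = sem_mdc_rmdc(0.5, pooled)
        assert sem == pytest.approx(1.4142, abs=1e-4)
        assert mdc == pytest.approx(1.96 * math.sqrt(2.0) * sem, abs=1e-12)
        assert mdc == pytest.approx(3.9200, abs=1e-4)
        assert rmdc == pytest.approx(1.9600, abs=1e-4)

    def test_rmdc_at_zero_icc_is_unit_free_constant(self):
        for sd in (0.5, 2.0, 10.0):
            pooled = np.array([-sd, sd]) / math.sqrt(2.0)
            _, _, rmdc = sem_mdc_rmdc(0.0, pooled)
            assert rmdc == pytest.approx(1.96 * math.sqrt(2.0), abs=1e-9)

    def test_out_of_range_icc_rejected(self):
        with pytest.raises(ReliabilityError):
            sem_mdc_rmdc(-0.1, np.array([1.0, 2.0]))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ReliabilityError):
            sem_mdc_rmdc(0.5, np.array([2.0, 2.0]))


class TestClassification:
    @pytest.mark.parametrize("icc, expected", [
        (0.49, "poor"), (0.5, "moderate"), (0.74, "moderate"),
        (0.75, "good"), (0.8, "good"), (0.89, "good"),
        (0.9, "excellent"), (0.95, "excellent"), (-0.3, "poor"),
    ])
    def test_bands_lower_inclusive(self, icc, expected):
        assert classify_icc(icc) == expected


class TestReliabilityTable:
    def _cohort_frames(self, n=10, within_sd=0.0, rng_seed=0):
        defs = build_catalogue()
        rng = np.random.default_rng(rng_seed)
        idx = [f"subj{i}" for i in range(n)]
        base = {d.name: rng.normal(0.0, 1.0, n) for d in defs}
        s1 = pd.DataFrame({k: v + rng.normal(0, within_sd, n)
                           for k, v in base.items()}, index=idx)
        s2 = pd.DataFrame({k: v + rng.normal(0, within_sd, n)
                           for k, v in base.items()}, index=idx)
        return s1, s2

    def test_noise_free_cohort_is_perfectly_reliable(self):
        s1, s2 = self._cohort_frames(within_sd=0.0)
        table, summary = reliability_table(s1, s2)
        assert len(table) == 166
        assert np.allclose(table["icc"], 1.0)
        assert summary["good_excellent_total"] == 166
        assert summary["good_excellent_by_domain"]["spatio_temporal"] == 56

    def test_table_has_the_reported_columns(self):
        s1, s2 = self._cohort_frames(within_sd=0.3)
        table, _ = reliability_table(s1, s2)
        for col in ("mean", "sd_pooled", "icc", "ci95_low", "ci95_high",
                    "sem", "mdc", "rmdc", "icc_class"):
            assert col in table.columns

    def test_listwise_deletion_of_incomplete_pairs(self):
        s1, s2 = self._cohort_frames(within_sd=0.2)
        feat = s1.columns[0]
        s1.loc["subj0", feat] = np.nan
        table, _ = reliability_table(s1, s2)
        assert table.loc[feat, "n_pairs"] == 9

    def test_mostly_missing_feature_flagged(self):
        s1, s2 = self._cohort_frames(within_sd=0.2)
        feat = s1.columns[0]
        s1.loc[s1.index[:6], feat] = np.nan
        table, _ = reliability_table(s1, s2)
        assert table.loc[feat, "flag"] == "insufficient data"

    def test_empty_cohort_rejected(self):
        with pytest.raises(ReliabilityError):
            reliability_table(pd.DataFrame(), pd.DataFrame())

    def test_disjoint_subjects_rejected(self):
        s1, s2 = self._cohort_frames(within_sd=0.2)
        s2.index = [f"other{i}" for i in range(len(s2))]
        with pytest.raises(ReliabilityError, match="no paired subjects"):
            reliability_table(s1, s2)

    def test_negative_icc_reported_with_sem_suppressed(self):
        # anti-correlated sessions force a negative estimate
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        s1 = pd.DataFrame({"f": x}, index=range(12))
        s2 = pd.DataFrame({"f": -x}, index=range(12))
        table, _ = reliability_table(s1, s2)
        assert table.loc["f", "icc"] < 0
        assert table.loc["f", "icc_class"] == "poor"
        assert np.isnan(table.loc["f", "sem"])
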