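"""Test-retest reliability statistics: ICC(2,1), SEM, MDC and relative MDC.

The intraclass correlation is the two-way random-effects, absolute-agreement,
single-measurement form (Shrout & Fleiss 2,1), computed from the mean
squares of the subjects x sessions table:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with the 95% confidence interval by the F-distribution method of McGraw &
Wong. Derived statistics:

    SEM  = SD_pooled * sqrt(1 - ICC)        (suppressed for negative ICC)
    MDC  = 1.96 * sqrt(2) * SEM
    rMDC = MDC / SD_pooled

where SD_pooled is the standard deviation (ddof=1) of all test and retest
observations concatenated. Classification bands: ICC < 0.5 poor,
0.5-0.75 moderate, 0.75-0.9 good, >= 0.9 excellent (lower bounds inclusive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import ReliabilityError
from .features.catalogue import FeatureDef, build_catalogue, catalogue_index

MDC_FACTOR = 1.96 * math.sqrt(2.0)

ICC_BANDS = (("poor", -np.inf, 0.5), ("moderate", 0.5, 0.75),
             ("good", 0.75, 0.9), ("excellent", 0.9, np.inf))


@dataclass
class ReliabilityRow:
    feature: str
    n_pairs: int
    mean: float
    sd_pooled: float
    icc: float
    ci95: Tuple[float, float]
    sem: float
    mdc: float
    rmdc: float
    icc_class: str
    flag: str = ""


# ----------------------------------------------------------------------
# ICC(2,1)
# ----------------------------------------------------------------------

def _mean_squares(matrix: np.ndarray) -> Tuple[float, float, float, int, int]:
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((matrix - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_2_1(matrix: np.ndarray, alpha: float = 0.05
            ) -> Tuple[float, Tuple[float, float]]:
    """ICC(2,1) with its (1 - alpha) confidence interval.

    Rows are subjects, columns sessions; incomplete rows must be removed by
    the caller (``reliability_table`` applies listwise deletion).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ReliabilityError("need a subjects x sessions matrix with >= 2 sessions")
    if np.any(~np.isfinite(matrix)):
        raise ReliabilityError("matrix contains non-finite values")
    if matrix.shape[0] < 3:
        raise ReliabilityError(
            f"need at least 3 complete subjects, got {matrix.shape[0]}")
    msr, msc, mse, n, k = _mean_squares(matrix)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.ptp(matrix) == 0:
        raise ReliabilityError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    # McGraw & Wong F-method CI with Satterthwaite degrees of freedom
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = 1.0
    lower = min(lower, icc)
    upper = max(upper, icc)
    return float(icc), (float(lower), float(upper))


def sem_mdc_rmdc(icc: float, values_pooled: np.ndarray
                 ) -> Tuple[float, float, float]:
    """SEM, MDC and relative MDC from the ICC and the pooled observations."""
    if -1e-9 <= icc < 0.0 or 1.0 < icc <= 1.0 + 1e-9:
        icc = float(np.clip(icc, 0.0, 1.0))  # tolerate rounding overshoot
    if not 0.0 <= icc <= 1.0:
        raise ReliabilityError("SEM requires an ICC in [0, 1]")
    pooled = np.asarray(values_pooled, dtype=float).ravel()
    sd = float(np.std(pooled, ddof=1))
    sem = sd * math.sqrt(1.0 - icc)
    mdc = MDC_FACTOR * sem
    if sd == 0:
        raise ReliabilityError("zero pooled SD: rMDC undefined")
    return sem, mdc, mdc / sd


def classify_icc(icc: float) -> str:
    """Qualitative reliability band; lower bounds inclusive."""
    if not np.isfinite(icc):
        raise ReliabilityError("ICC must be finite to classify")
    for label, lo, hi in ICC_BANDS:
        if lo <= icc < hi:
            return label
    return "excellent"


# ----------------------------------------------------------------------
# Cohort tables
# ----------------------------------------------------------------------

def reliability_table(session1: pd.DataFrame, session2: pd.DataFrame,
                      catalogue: Optional[List[FeatureDef]] = None,
                      min_fraction: float = 0.5
                      ) -> Tuple[pd.DataFrame, Dict]:
    """Per-feature reliability over a two-session cohort.

    Inputs are feature tables indexed by subject id (one row per subject,
    one column per feature). Subjects missing from either session are
    dropped; per feature, incomplete pairs are removed listwise and features
    observed in fewer than ``min_fraction`` of subjects are flagged.
    Returns the table plus summary counts of good-excellent features overall
    and per domain/source.
    """
    if session1.empty or session2.empty:
        raise ReliabilityError("empty cohort")
    common = session1.index.intersection(session2.index)
    if len(common) == 0:
        raise ReliabilityError("no paired subjects between sessions")
    s1 = session1.loc[common]
    s2 = session2.loc[common]
    features = [c for c in s1.columns if c in s2.columns]
    defs = catalogue_index(catalogue or build_catalogue())

    rows: List[ReliabilityRow] = []
    for feat in features:
        pair = np.column_stack([s1[feat].to_numpy(dtype=float),
                                s2[feat].to_numpy(dtype=float)])
        complete = pair[np.all(np.isfinite(pair), axis=1)]
        n_pairs = complete.shape[0]
        if n_pairs < max(3, int(np.ceil(min_fraction * len(common)))):
            rows.append(ReliabilityRow(feat, n_pairs, np.nan, np.nan, np.nan,
                                       (np.nan, np.nan), np.nan, np.nan,
                                       np.nan, "", "insufficient data"))
            continue
        pooled = complete.ravel()
        mean = float(pooled.mean())
        sd = float(np.std(pooled, ddof=1))
        try:
            icc, ci = icc_2_1(complete)
        except ReliabilityError as exc:
            rows.append(ReliabilityRow(feat, n_pairs, mean, sd, np.nan,
                                       (np.nan, np.nan), np.nan, np.nan,
                                       np.nan, "", str(exc)))
            continue
        icc_class = classify_icc(icc)
        if icc >= 0.0:
            sem, mdc, rmdc = sem_mdc_rmdc(icc, pooled)
            flag = ""
        else:
            # negative estimates are reported but SEM-derived stats suppressed
            sem = mdc = rmdc = np.nan
            flag = "negative ICC: SEM suppressed"
        rows.append(ReliabilityRow(feat, n_pairs, mean, sd, icc, ci, sem,
                                   mdc, rmdc, icc_class, flag))

    table = pd.DataFrame([{
        "feature": r.feature, "n_pairs": r.n_pairs, "mean": r.mean,
        "sd_pooled": r.sd_pooled, "icc": r.icc, "ci95_low": r.ci95[0],
        "ci95_high": r.ci95[1], "sem": r.sem, "mdc": r.mdc, "rmdc": r.rmdc,
        "icc_class": r.icc_class, "flag": r.flag,
    } for r in rows]).set_index("feature")

    good = table["icc"] >= 0.75
    summary: Dict = {
        "n_features": int(len(table)),
        "n_pairs": int(len(common)),
        "good_excellent_total": int(good.sum()),
        "good_excellent_by_domain": {},
        "good_excellent_by_source": {},
    }
    for feat, is_good in good.items():
        d = defs.get(feat)
        if d is None:
            continue
        summary["good_excellent_by_domain"].setdefault(d.domain, 0)
        summary["good_excellent_by_source"].setdefault(d.source, 0)
        if is_good:
            summary["good_excellent_by_domain"][d.domain] += 1
            summary["good_excellent_by_source"][d.source] += 1
    return table, summary


def write_reliability_outputs(table: pd.DataFrame, summary: Dict,
                              out_dir: str | Path,
                              prefix: str = "reliability") -> Tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{prefix}_table.csv"
    json_path = out_dir / f"{prefix}_summary.json"
    table.to_csv(csv_path)
    json_path.write_text(json.dumps(summary, indent=2))
    return csv_path, json_path
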