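"""Data preparation: minimum imputation, median centering, near-zero-variance
filtering, log transform and a Kolmogorov-Smirnov normality screen.

The canonical order is fixed by the analysis design: impute -> median-center
-> near-zero-variance filter, after which the rank-based tests run on the
centered (still "raw"-scale) data and the parametric moderated test runs on
the natural-log transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AbundanceMatrix

__all__ = [
    "impute_and_center",
    "filter_near_zero_variance",
    "log_transform",
    "ks_normality",
    "NormalityScreen",
]

log = logging.getLogger(__name__)


def impute_and_center(m: AbundanceMatrix, zeros_as_missing: bool = True) -> AbundanceMatrix:
    """Minimum-impute missing values per feature, then median-center each feature.

    Missing entries (NaN, and zeros when ``zeros_as_missing`` — zeros code
    below-limit-of-detection values) are replaced by the feature's minimum
    observed positive value; each feature is then divided by its median, so
    every output feature has median 1.

    Raises
    ------
    ValueError
        If a feature has no observed positive value.
    """
    if m.scale != "raw":
        raise ValueError(f"expected raw-scale input, got {m.scale!r}")
    v = m.values.astype(float).copy()
    if zeros_as_missing:
        v = v.mask(v == 0.0)
    obs_min = v.min(axis=1)
    bad = obs_min.index[obs_min.isna() | (obs_min <= 0)]
    if len(bad):
        raise ValueError(f"feature(s) with no observed positive value: {list(bad[:5])}")
    v = v.apply(lambda row: row.fillna(obs_min[row.name]), axis=1)
    v = v.div(v.median(axis=1), axis=0)
    return m.with_values(v, scale="median_centered")


def filter_near_zero_variance(
    m: AbundanceMatrix,
    freq_ratio_cut: float = 19.0,
    unique_cut_pct: float = 10.0,
) -> tuple[AbundanceMatrix, list[str]]:
    """Drop zero- and near-zero-variance features.

    A feature is removed iff its variance is exactly zero, or both
    (most-common-value frequency / second-most-common frequency)
    >= ``freq_ratio_cut`` and (distinct values / samples) * 100 <
    ``unique_cut_pct`` — the classical freqRatio/uniqueCut convention.

    Returns the filtered matrix and the sorted list of removed feature ids.
    """
    removed: list[str] = []
    n = m.n_samples
    for fid, row in m.values.iterrows():
        vals = row.to_numpy()
        if np.var(vals) == 0.0:
            removed.append(fid)
            continue
        counts = pd.Series(vals).value_counts().to_numpy()
        freq_ratio = counts[0] / counts[1] if len(counts) > 1 else np.inf
        unique_pct = 100.0 * len(counts) / n
        if freq_ratio >= freq_ratio_cut and unique_pct < unique_cut_pct:
            removed.append(fid)
    removed = sorted(removed)
    if removed:
        log.info("near-zero-variance filter removed %d of %d features", len(removed), m.n_features)
    keep = [f for f in m.feature_ids if f not in set(removed)]
    return m.subset_features(keep), removed


def log_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Natural log, elementwise; requires strictly positive entries."""
    arr = m.values.to_numpy()
    if not (arr > 0).all():
        i, j = np.argwhere(~(arr > 0))[0]
        raise ValueError(
            f"nonpositive entry at feature {m.feature_ids[i]!r}, sample {m.sample_ids[j]!r}"
        )
    return m.with_values(np.log(m.values), scale="log")


@dataclass
class NormalityScreen:
    """Per-feature Kolmogorov-Smirnov screen against a fitted normal."""

    table: pd.DataFrame  # columns: D, p, tested (bool)
    alpha: float

    @property
    def rejection_fraction(self) -> float:
        tested = self.table[self.table["tested"]]
        if tested.empty:
            return float("nan")
        return float((tested["p"] < self.alpha).mean())


def ks_normality(m: AbundanceMatrix, alpha: float = 0.05) -> NormalityScreen:
    """One-sample KS test of each feature against N(mean, sd) with estimated
    parameters (Lilliefors-style composite test; screening only, the p-values
    are anticonservative and never gate downstream analysis).

    Constant features are flagged ``tested=False`` and excluded from the
    rejection fraction.
    """
    if m.n_samples < 8:
        raise ValueError("need >= 8 samples for the normality screen")
    rows = []
    for fid, row in m.values.iterrows():
        x = row.to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0:
            rows.append({"feature_id": fid, "D": np.nan, "p": np.nan, "tested": False})
            continue
        d, p = stats.kstest(x, "norm", args=(x.mean(), sd))
        rows.append({"feature_id": fid, "D": d, "p": p, "tested": True})
    return NormalityScreen(pd.DataFrame(rows).set_index("feature_id"), alpha=alpha)
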