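"""Cohort characteristics table: group-wise descriptives and tests.

Continuous variables are compared with the Mann-Whitney U test, categorical
variables with the Pearson chi-square test (Yates-corrected when 2x2); 2x2
tables with a zero margin or tiny expected cells fall back to Fisher's
exact test. Human-readable p-values follow clinical-table style: two
decimals, "<0.001" below that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import mann_whitney_test

__all__ = [
    "chi_square_test",
    "fisher_exact",
    "cohort_table",
    "CohortComparison",
    "format_p",
]

#: Variable typing of the standard 13-variable clinical table.
CONTINUOUS_VARS = {"age", "vat", "sat"}


def chi_square_test(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a 2 x k contingency table.

    Yates continuity correction is applied iff the table is 2x2;
    df = k - 1. A zero margin raises, directing the caller to Fisher.
    """
    t = np.asarray(counts)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError(f"expected a 2 x k table, got shape {t.shape}")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: use fisher_exact")
    correction = t.shape == (2, 2)
    chi2, p, df, _ = stats.chi2_contingency(t, correction=correction)
    return float(chi2), int(df), float(p)


def fisher_exact(counts) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sum)."""
    t = np.asarray(counts)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def format_p(p: float) -> str:
    """Clinical-table p formatting: '<0.001' below 0.001, else 2 decimals."""
    if np.isnan(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.2f}"


@dataclass
class CohortComparison:
    """Per-variable group descriptives and test results."""

    table: pd.DataFrame  # variable, descriptive_0, descriptive_1, test, statistic, p

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def report(self) -> pd.DataFrame:
        out = self.table.copy()
        out["p"] = out["p"].map(format_p)
        return out


def _needs_fisher(t: np.ndarray) -> bool:
    if t.shape != (2, 2):
        return False
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return True
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return bool((expected < 1).any())


def cohort_table(
    clinical: pd.DataFrame, group_col: str = "mets"
) -> CohortComparison:
    """Compare every clinical variable between the two groups.

    Continuous variables (per ``CONTINUOUS_VARS`` or float dtype) get
    mean (sd) descriptives and Mann-Whitney U; categorical variables get
    n (%) per level and chi-square (Fisher for sparse 2x2). Constant
    variables are reported with the p-value omitted.
    """
    g = clinical[group_col]
    if g.nunique() != 2:
        raise ValueError("group column must be binary")
    g0, g1 = sorted(g.unique())
    a = clinical[g == g0]
    b = clinical[g == g1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for var in clinical.columns:
        if var == group_col:
            continue
        x = clinical[var]
        continuous = var in CONTINUOUS_VARS or (
            np.issubdtype(x.dtype, np.floating) and x.nunique() > 10
        )
        if continuous:
            stat, p = mann_whitney_test(a[var].to_numpy(float), b[var].to_numpy(float))
            rows.append(
                {
                    "variable": var,
                    "descriptive_0": f"{a[var].mean():.1f} ({a[var].std():.1f})",
                    "descriptive_1": f"{b[var].mean():.1f} ({b[var].std():.1f})",
                    "test": "mann-whitney",
                    "statistic": stat,
                    "p": p,
                }
            )
            continue
        levels = sorted(x.unique(), key=str)
        counts = np.array(
            [[int((a[var] == lv).sum()) for lv in levels],
             [int((b[var] == lv).sum()) for lv in levels]]
        )
        desc0 = "; ".join(f"{lv}: {c} ({100 * c / len(a):.1f}%)" for lv, c in zip(levels, counts[0]))
        desc1 = "; ".join(f"{lv}: {c} ({100 * c / len(b):.1f}%)" for lv, c in zip(levels, counts[1]))
        if len(levels) == 1:
            rows.append({"variable": var, "descriptive_0": desc0, "descriptive_1": desc1,
                         "test": "none (constant)", "statistic": np.nan, "p": np.nan})
            continue
        if _needs_fisher(counts):
            p = fisher_exact(counts)
            rows.append({"variable": var, "descriptive_0": desc0, "descriptive_1": desc1,
                         "test": "fisher", "statistic": np.nan, "p": p})
        else:
            chi2, _, p = chi_square_test(counts)
            rows.append({"variable": var, "descriptive_0": desc0, "descriptive_1": desc1,
                         "test": "chi-square", "statistic": chi2, "p": p})
    return CohortComparison(pd.DataFrame(rows))
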