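"""Univariate differential-abundance arms of the four-method consensus.

Two tests are run per lipid feature:

* Mann-Whitney U on the (median-centered) raw-scale data — rank-based,
  invariant to monotone transforms;
* an empirical-Bayes moderated t-statistic on the natural-log data.

The moderated test is the two-group special case of variance-moderated
linear modelling: per feature, an ordinary two-sample effect
``beta = mean(log MetS) - mean(log no-MetS)`` with pooled residual variance
``s2`` on ``d = n - 2`` degrees of freedom is shrunk toward a prior variance
``s0_sq`` with prior degrees of freedom ``d0``:

    s_tilde_sq = (d0 * s0_sq + d * s2) / (d0 + d)
    t_mod      = beta / (s_tilde * sqrt(1/n1 + 1/n2)),   df = d0 + d

``(d0, s0_sq)`` are estimated by matching the empirical mean and variance of
``log(s2)`` to their scaled-F expectations (digamma / trigamma identities),
solving the trigamma equation with a monotone Newton iteration.

Both arms are Benjamini-Hochberg adjusted; default selection is FDR < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import AbundanceMatrix

__all__ = [
    "DifferentialResult",
    "ModeratedModel",
    "mann_whitney_test",
    "mann_whitney_all",
    "fit_moderated",
    "bh_adjust",
]


@dataclass
class DifferentialResult:
    """Per-feature statistics and the selected set for one method."""

    method: str  # mann_whitney | moderated_t | plsda_vip | rf_rdcv
    table: pd.DataFrame  # index feature_id; columns effect, statistic, p, q
    selected: set
    threshold_rule: str

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["selected"] = out.index.isin(self.selected)
        out["method"] = self.method
        out.rename_axis("feature_id").to_csv(path, sep="\t")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two samples.

    Exact enumeration when the pooled size is <= 20 and the data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections. Returns ``(U, p)`` with U for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_all(
    m: AbundanceMatrix, fdr_cut: float = 0.001
) -> DifferentialResult:
    """Mann-Whitney U per feature (MetS vs no-MetS), BH-adjusted."""
    g = m.group.to_numpy()
    a_cols = g == 1
    b_cols = g == 0
    vals = m.values.to_numpy(float)
    stats_u = np.empty(m.n_features)
    pvals = np.empty(m.n_features)
    effects = np.empty(m.n_features)
    for i in range(m.n_features):
        u, p = mann_whitney_test(vals[i, a_cols], vals[i, b_cols])
        stats_u[i] = u
        pvals[i] = p
        effects[i] = np.median(vals[i, a_cols]) - np.median(vals[i, b_cols])
    q = bh_adjust(pvals)
    tbl = pd.DataFrame(
        {"effect": effects, "statistic": stats_u, "p": pvals, "q": q},
        index=m.values.index,
    )
    selected = set(tbl.index[tbl["q"] < fdr_cut])
    return DifferentialResult("mann_whitney", tbl, selected, f"q < {fdr_cut}")


def _estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0_sq) from per-feature variances.

    Matches mean/variance of ``log s2`` to the scaled-F model:
    ``e = log s2 - digamma(d/2) + log(d/2)`` has expectation
    ``log s0_sq + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond the sampling term ``trigamma(d/2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) if e.size > 1 else 0.0
    target = e_var - special.polygamma(1, d / 2)
    if target <= 0:
        # observed spread no larger than pure sampling noise: infinite prior
        # df; the prior variance is the geometric mean of the observed s2 so
        # the all-equal-variance case shrinks to exactly the common value
        return np.inf, float(np.exp(z.mean()))
    # solve trigamma(d0/2) = target by monotone Newton on x = d0/2
    x = 0.5 + 1.0 / target  # standard starting value
    for _ in range(60):
        tri = special.polygamma(1, x)
        step = tri * (1 - tri / target) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    d0 = 2 * x
    s0_sq = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    return float(d0), s0_sq


@dataclass
class ModeratedModel:
    """Fitted empirical-Bayes moderated two-group model."""

    table: pd.DataFrame  # index feature_id; beta, s2, s_tilde_sq, t, p, q
    d0: float
    s0_sq: float
    df_residual: float
    excluded: list = field(default_factory=list)  # zero-variance features

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_residual

    def result(self, fdr_cut: float = 0.001) -> DifferentialResult:
        tbl = self.table.rename(columns={"t": "statistic"})[
            ["beta", "statistic", "p", "q"]
        ].rename(columns={"beta": "effect"})
        selected = set(tbl.index[tbl["q"] < fdr_cut])
        return DifferentialResult("moderated_t", tbl, selected, f"q < {fdr_cut}")


def fit_moderated(
    m: AbundanceMatrix, d0_override: float | None = None
) -> ModeratedModel:
    """Fit the moderated two-group model on log-scale data.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary equal-variance t-test exactly); by default ``(d0, s0_sq)`` are
    estimated from the data.
    """
    if m.scale != "log":
        raise ValueError(f"expected log-scale input, got {m.scale!r}")
    g = m.group.to_numpy()
    n1 = int((g == 1).sum())
    n2 = int((g == 0).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")
    x1 = m.values.to_numpy(float)[:, g == 1]
    x2 = m.values.to_numpy(float)[:, g == 0]
    beta = x1.mean(axis=1) - x2.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    keep = s2 > 0
    excluded = list(m.values.index[~keep])
    if excluded:
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d zero-variance feature(s) from moderated fit", len(excluded)
        )

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[keep])) if np.isfinite(d0) and d0 > 0 else float("nan")
        if d0 == 0:
            s0_sq = 0.0
    else:
        d0, s0_sq = _estimate_prior(s2[keep], d)

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s_tilde_sq = s2.copy()
    else:
        s_tilde_sq = (d0 * s0_sq + d * s2) / (d0 + d)
    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / (np.sqrt(s_tilde_sq) * c)
    df_total = d0 + d if np.isfinite(d0) else np.inf
    if np.isfinite(df_total):
        p = 2 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2 * stats.norm.sf(np.abs(t))
    tbl = pd.DataFrame(
        {"beta": beta, "s2": s2, "s_tilde_sq": s_tilde_sq, "t": t, "p": p},
        index=m.values.index,
    ).loc[keep]
    tbl["q"] = bh_adjust(tbl["p"].to_numpy())
    return ModeratedModel(tbl, d0=d0, s0_sq=s0_sq, df_residual=d, excluded=excluded)
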