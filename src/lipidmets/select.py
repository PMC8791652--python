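"""Multivariate arms of the consensus and the four-way intersection.

Two multivariate selectors complement the univariate tests:

* **PLS-DA** — partial least squares discriminant analysis (NIPALS, via the
  scikit-learn backend) of the +/-1-coded group on standardized log
  abundances. Per-feature importance is the VIP score

      VIP_j = sqrt( p * sum_a w_ja^2 SSY_a / sum_a SSY_a )

  with ``p`` features, weights ``w`` and ``SSY_a`` the response variance
  explained by component ``a``; mean(VIP^2) over features is identically 1,
  and features with VIP > 1 are selected. Model quality is Q2Y =
  1 - PRESS/TSS from k-fold cross-validated predictions.

* **rdCV random forest** — repeated double cross-validation with recursive
  feature elimination. Outer folds are held out entirely; inside each outer
  training set an inner CV repeatedly drops the lowest-importance fraction
  of features, recording validation misclassification per feature count.
  The averaged validation curve yields three feature counts: ``min`` (fewest
  features within tolerance of the curve minimum), ``max`` (most features
  within tolerance) and ``mid`` (rounded geometric mean). Final Min/Mid/Max
  sets are the top features by average elimination rank; AUROC is computed
  strictly from outer-fold predictions, so selection never sees the samples
  it is judged on.

``consensus_features`` intersects the four selected sets and reports all
2^k - 1 UpSet-style intersection cardinalities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PLSModel",
    "RFSelection",
    "ConsensusSet",
    "fit_plsda",
    "q2y",
    "rdcv_rf_select",
    "consensus_features",
]


@dataclass
class PLSModel:
    """Fitted PLS-DA model with VIP scores."""

    n_components: int
    scores: np.ndarray  # samples x A
    loadings: np.ndarray  # features x A
    weights: np.ndarray  # features x A
    y_loadings: np.ndarray  # A
    r2x: np.ndarray  # per-component fraction of X variance
    vip: pd.Series  # per-feature VIP >= 0
    q2y: float | None = None

    def selected(self, vip_cut: float = 1.0) -> set:
        return set(self.vip.index[self.vip > vip_cut])


def _as_xy(X, y):
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"y must be binary, got classes {classes}")
    ypm = np.where(y == classes.max(), 1.0, -1.0)
    return X, ypm


def fit_plsda(
    X, y, n_components: int = 2, standardize: bool = True
) -> PLSModel:
    """Fit PLS-DA of binary ``y`` on ``X`` (samples x features).

    ``y`` is coded +/-1 and centered; features are standardized to unit
    variance unless ``standardize=False``.
    """
    X, ypm = _as_xy(X, y)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} too large for {n}x{p} data")
    pls = PLSRegression(n_components=n_components, scale=standardize)
    pls.fit(X.to_numpy(float), ypm)
    T = pls.x_scores_
    W = pls.x_weights_
    P = pls.x_loadings_
    q = pls.y_loadings_.ravel()
    Xc = pls._x_mean  # noqa: F841 - centering handled by sklearn
    ssx_total = (
        ((X.to_numpy(float) - pls._x_mean) / pls._x_std) ** 2
    ).sum()
    r2x = np.array(
        [np.outer(T[:, a], P[:, a]).ravel().__pow__(2).sum() / ssx_total
         for a in range(n_components)]
    )
    # response variance explained per component
    ssy = np.array([(q[a] ** 2) * (T[:, a] ** 2).sum() for a in range(n_components)])
    w2 = W**2
    denom = ssy.sum()
    vip = np.sqrt(p * (w2 * ssy[None, :]).sum(axis=1) / denom)
    return PLSModel(
        n_components=n_components,
        scores=T,
        loadings=P,
        weights=W,
        y_loadings=q,
        r2x=r2x,
        vip=pd.Series(vip, index=X.columns, name="vip"),
    )


def q2y(X, y, n_components: int = 2, k_folds: int = 7, seed: int = 0,
        standardize: bool = True) -> float:
    """Cross-validated Q2Y = 1 - PRESS/TSS for a PLS-DA model.

    Folds are stratified on class so each fold sees both classes; may be
    negative for uninformative models.
    """
    X, ypm = _as_xy(X, y)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    Xa = X.to_numpy(float)
    yc = ypm - ypm.mean()
    press = 0.0
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(Xa, ypm):
        if np.unique(ypm[tr]).size < 2:
            raise ValueError("fold with a single class; reduce k_folds")
        ncomp = min(n_components, len(tr) - 1, Xa.shape[1])
        pls = PLSRegression(n_components=ncomp, scale=standardize)
        pls.fit(Xa[tr], ypm[tr])
        pred = pls.predict(Xa[te]).ravel()
        press += ((ypm[te] - pred) ** 2).sum()
    tss = (yc**2).sum()
    return float(1.0 - press / tss)


# ---------------------------------------------------------------------------
# repeated double cross-validated random forest


@dataclass
class RFSelection:
    """Result of rdCV random-forest variable selection."""

    min_set: set
    mid_set: set
    max_set: set
    auroc: dict  # model name -> outer-fold AUROC
    ranks: pd.Series  # per-feature average elimination rank (low = kept longest)
    validation_curve: pd.DataFrame  # columns n_features, misclass
    params: dict = field(default_factory=dict)


def _elimination_path(n_features: int, var_ratio: float) -> list[int]:
    """Decreasing feature counts: each step keeps ``var_ratio`` of features."""
    path = [n_features]
    while path[-1] > 2:
        nxt = max(2, int(np.floor(path[-1] * var_ratio)))
        if nxt == path[-1]:
            nxt -= 1
        path.append(nxt)
    return path


def _rf(seed: int, n_estimators: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )


def rdcv_rf_select(
    X,
    y,
    n_rep: int = 5,
    n_outer: int = 6,
    var_ratio: float = 0.75,
    tolerance: float = 0.05,
    n_estimators: int = 50,
    seed: int = 0,
) -> RFSelection:
    """Repeated double cross-validated random-forest feature selection.

    Importance is the forest's Gini importance refit at every elimination
    step; selection fitness is inner-validation misclassification; AUROC is
    reported from outer-fold held-out predictions only.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("y must be binary")
    ybin = (y == classes.max()).astype(int)
    counts = np.bincount(ybin)
    if counts.min() < n_outer:
        raise ValueError(
            f"each class needs >= n_outer={n_outer} samples, have {counts.tolist()}"
        )
    feats = np.array(X.columns)
    Xa = X.to_numpy(float)
    p = Xa.shape[1]
    path = _elimination_path(p, var_ratio)
    rng = np.random.default_rng(seed)

    curve_sum = np.zeros(len(path))
    curve_n = 0
    rank_sum = pd.Series(0.0, index=X.columns)
    rank_n = 0
    outer_counts = {"min": [], "mid": [], "max": []}
    outer_pred: dict[str, list] = {k: [] for k in ("min", "mid", "max")}
    outer_true: list[np.ndarray] = []

    for rep in range(n_rep):
        okf = StratifiedKFold(
            n_splits=n_outer, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for otr, ote in okf.split(Xa, ybin):
            n_inner = max(2, n_outer - 1)
            ikf = StratifiedKFold(
                n_splits=n_inner, shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            step_miss = np.zeros(len(path))
            # per-inner-fold elimination; ranks averaged across folds
            fold_ranks = np.zeros(p)
            for itr, ival in ikf.split(Xa[otr], ybin[otr]):
                tr_idx, val_idx = otr[itr], otr[ival]
                active = np.arange(p)
                elim_rank = np.zeros(p)  # high rank = eliminated early
                for si, k in enumerate(path):
                    if len(active) > k:
                        active = active[np.argsort(-imp)[:k]]  # keep top-k
                    rf = _rf(int(rng.integers(2**31)), n_estimators)
                    rf.fit(Xa[np.ix_(tr_idx, active)], ybin[tr_idx])
                    pred = rf.predict(Xa[np.ix_(val_idx, active)])
                    step_miss[si] += (pred != ybin[val_idx]).mean()
                    imp = rf.feature_importances_
                    # survived to step si; ties within a step broken by the
                    # importance that decided the next elimination
                    elim_rank[active] = si + 0.5 * imp / (imp.max() + 1e-12)
                order = np.argsort(-elim_rank)  # longest survivors first
                fold_ranks += pd.Series(
                    np.arange(p), index=order
                ).sort_index().to_numpy()
            step_miss /= n_inner
            curve_sum += step_miss
            curve_n += 1
            rank_sum += fold_ranks / n_inner
            rank_n += 1

            # per-outer-fold optimal counts from the inner curve
            lo = step_miss.min()
            tol = lo + tolerance * max(lo, 1e-12) + 1e-12
            within = [path[i] for i in range(len(path)) if step_miss[i] <= tol]
            k_min, k_max = min(within), max(within)
            k_mid = int(round(np.sqrt(k_min * k_max)))
            outer_counts["min"].append(k_min)
            outer_counts["mid"].append(k_mid)
            outer_counts["max"].append(k_max)

            # outer predictions with each model size, features chosen on
            # outer-train ranks only
            otr_rank = np.argsort(fold_ranks)
            for name, k in (("min", k_min), ("mid", k_mid), ("max", k_max)):
                sel = otr_rank[:k]
                rf = _rf(int(rng.integers(2**31)), n_estimators)
                rf.fit(Xa[np.ix_(otr, sel)], ybin[otr])
                outer_pred[name].append(rf.predict_proba(Xa[np.ix_(ote, sel)])[:, 1])
            outer_true.append(ybin[ote])

    ranks = (rank_sum / rank_n).sort_values()
    k_min = int(round(np.mean(outer_counts["min"])))
    k_max = int(round(np.mean(outer_counts["max"])))
    k_mid = int(round(np.sqrt(k_min * k_max)))
    k_min, k_mid, k_max = sorted((k_min, k_mid, k_max))
    min_set = set(ranks.index[:k_min])
    mid_set = set(ranks.index[:k_mid])
    max_set = set(ranks.index[:k_max])

    ytrue = np.concatenate(outer_true)
    auroc = {
        name: float(roc_auc_score(ytrue, np.concatenate(outer_pred[name])))
        for name in ("min", "mid", "max")
    }
    curve = pd.DataFrame({"n_features": path, "misclass": curve_sum / curve_n})
    return RFSelection(
        min_set=min_set,
        mid_set=mid_set,
        max_set=max_set,
        auroc=auroc,
        ranks=ranks,
        validation_curve=curve,
        params={"n_rep": n_rep, "n_outer": n_outer, "var_ratio": var_ratio,
                "tolerance": tolerance, "n_estimators": n_estimators, "seed": seed},
    )


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusSet:
    """Four-method consensus with UpSet-style intersection cardinalities."""

    method_sets: dict  # method name -> selected set
    intersection: set
    upset: pd.DataFrame  # columns: one bool per method, 'count'

    def to_tsv(self, path) -> None:
        self.upset.to_csv(path, sep="\t", index=False)


def consensus_features(method_sets: dict, universe=None) -> ConsensusSet:
    """Intersect per-method selected sets; report exclusive UpSet counts.

    ``universe``, when given, must contain every selected feature; a
    mismatch raises with the offending difference listed.
    """
    if len(method_sets) < 2:
        raise ValueError("need >= 2 method sets")
    sets = {k: set(v) for k, v in method_sets.items()}
    if universe is not None:
        uni = set(universe)
        for name, s in sets.items():
            extra = s - uni
            if extra:
                raise ValueError(
                    f"method {name!r} selected features outside the universe: "
                    f"{sorted(extra)[:5]}"
                )
    inter = set.intersection(*sets.values())
    names = list(sets)
    all_feats = set().union(*sets.values())
    rows = []
    for mask in itertools.product([True, False], repeat=len(names)):
        if not any(mask):
            continue
        members = all_feats
        for name, inc in zip(names, mask):
            members = members & sets[name] if inc else members - sets[name]
        rows.append({**dict(zip(names, mask)), "count": len(members)})
    upset = pd.DataFrame(rows)
    return ConsensusSet(method_sets=sets, intersection=inter, upset=upset)
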