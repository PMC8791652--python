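"""Weighted lipid-metabolite network integration.

Builds an undirected biomolecular network whose nodes are lipid and
metabolite features and whose edges are positive Spearman rank correlations
passing both an FDR cut and a correlation floor (defaults FDR < 1e-07,
rho > 0.38). The observed topology is contrasted with a G(n, m)
Erdos-Renyi null; communities are detected with the Leiden algorithm;
community abundance scores and individual features are regressed against
clinical variables (logistic for binary, linear for continuous); and a
generic hypergeometric over-representation analysis tests annotation terms
against a network-wide background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import AbundanceMatrix
from .diffabund import bh_adjust
from .nomenclature import LipidParseError, parse_lipid_name

__all__ = [
    "BiomolecularNetwork",
    "CommunityPartition",
    "NullComparison",
    "spearman_network",
    "er_null_compare",
    "detect_communities",
    "centrality_rank",
    "community_clinical_assoc",
    "feature_clinical_assoc",
    "ora_enrichment",
]

log = logging.getLogger(__name__)


@dataclass
class BiomolecularNetwork:
    """Weighted undirected graph over lipid + metabolite nodes."""

    graph: nx.Graph  # node attr 'node_type'; edge attr 'weight' (rho > 0)
    fdr_cut: float
    rho_cut: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist(self, path) -> None:
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )


def spearman_network(
    combined: AbundanceMatrix,
    fdr_cut: float = 1e-07,
    rho_cut: float = 0.38,
    node_types: dict | None = None,
) -> BiomolecularNetwork:
    """All-pairs Spearman correlation network, positive edges only.

    Tie-corrected Spearman rho for every feature pair, two-sided p, BH
    adjustment across all pairs; an edge is kept iff ``q <= fdr_cut`` and
    ``rho >= rho_cut``. Constant features are excluded with a warning.
    """
    if combined.n_samples < 10:
        raise ValueError("need >= 10 samples for the correlation network")
    v = combined.values
    sd = v.std(axis=1, ddof=0)
    constant = list(v.index[sd == 0])
    if constant:
        log.warning("excluding %d constant feature(s) from the network", len(constant))
        v = v.drop(index=constant)
    ids = list(v.index)
    k = len(ids)
    n = v.shape[1]
    rho, _ = stats.spearmanr(v.to_numpy(float), axis=1)
    if k == 2:  # scipy returns a scalar for exactly two variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    iu = np.triu_indices(k, 1)
    r = np.clip(rho[iu], -1 + 1e-15, 1 - 1e-15)
    # t-approximation for the two-sided p of Spearman's rho
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    q = bh_adjust(p)
    keep = (q <= fdr_cut) & (rho[iu] >= rho_cut)

    # nodes are the features incident to at least one retained edge;
    # features with no passing correlation stay out of the network
    g = nx.Graph()
    node_types = node_types or {}
    for a, b, w in zip(iu[0][keep], iu[1][keep], rho[iu][keep]):
        for idx in (a, b):
            if ids[idx] not in g:
                g.add_node(ids[idx], node_type=node_types.get(ids[idx], "lipid"))
        g.add_edge(ids[a], ids[b], weight=float(w))
    return BiomolecularNetwork(graph=g, fdr_cut=fdr_cut, rho_cut=rho_cut)


# ---------------------------------------------------------------------------
# Erdos-Renyi null


@dataclass
class NullComparison:
    """Observed topology vs a G(n, m) Erdos-Renyi ensemble."""

    observed: dict  # metric -> value
    null_mean: dict
    null_sd: dict
    null_lo: dict  # 0.5% quantile
    null_hi: dict  # 99.5% quantile
    markedly_distinct: bool
    n_draws: int


def _topology_metrics(g: nx.Graph) -> dict:
    degs = np.array([d for _, d in g.degree()], dtype=float)
    out = {
        "degree_variance": float(degs.var()) if degs.size else 0.0,
        "clustering": nx.transitivity(g),
    }
    if g.number_of_nodes():
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        out["mean_shortest_path"] = (
            nx.average_shortest_path_length(sub) if len(comp) > 1 else 0.0
        )
    else:
        out["mean_shortest_path"] = 0.0
    return out


def _degree_divergence(g: nx.Graph, ref: nx.Graph) -> float:
    """Jensen-Shannon divergence between two degree distributions."""
    da = np.bincount([d for _, d in g.degree()])
    db = np.bincount([d for _, d in ref.degree()])
    m = max(len(da), len(db))
    pa = np.pad(da, (0, m - len(da))).astype(float)
    pb = np.pad(db, (0, m - len(db))).astype(float)
    pa /= pa.sum()
    pb /= pb.sum()
    mid = (pa + pb) / 2

    def _kl(x, y):
        mask = x > 0
        return float((x[mask] * np.log2(x[mask] / y[mask])).sum())

    return 0.5 * _kl(pa, mid) + 0.5 * _kl(pb, mid)


def er_null_compare(net: BiomolecularNetwork, n_draws: int = 100, seed: int = 0) -> NullComparison:
    """Compare the observed network against G(n, m) random graphs.

    Reports observed vs null mean/sd and a 99% null envelope for degree
    variance, global clustering, mean shortest path (largest component) and
    degree-distribution JS divergence; the network is flagged *markedly
    distinct* when any observed metric falls outside its envelope.
    """
    if net.n_edges < 1:
        raise ValueError("network has no edges")
    n, m = net.n_nodes, net.n_edges
    obs = _topology_metrics(net.graph)
    rng = np.random.default_rng(seed)
    draws: list[dict] = []
    for _ in range(n_draws):
        gnull = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        met = _topology_metrics(gnull)
        met["degree_divergence"] = _degree_divergence(net.graph, gnull)
        draws.append(met)
    tbl = pd.DataFrame(draws)
    obs["degree_divergence"] = 0.0  # divergence of observed from itself
    metrics = ["degree_variance", "clustering", "mean_shortest_path"]
    lo = tbl.quantile(0.005)
    hi = tbl.quantile(0.995)
    distinct = any(not (lo[k] <= obs[k] <= hi[k]) for k in metrics)
    return NullComparison(
        observed=obs,
        null_mean=tbl.mean().to_dict(),
        null_sd=tbl.std(ddof=1).to_dict(),
        null_lo=lo.to_dict(),
        null_hi=hi.to_dict(),
        markedly_distinct=bool(distinct),
        n_draws=n_draws,
    )


# ---------------------------------------------------------------------------
# communities


@dataclass
class CommunityPartition:
    """Leiden partition with per-community summaries."""

    membership: pd.Series  # node -> community id (0-based, by size)
    summary: pd.DataFrame  # per community: size, avg_degree, structure means
    resolution: float
    seed: int
    modularity: float

    def members(self, community: int) -> list:
        return list(self.membership.index[self.membership == community])

    @property
    def n_communities(self) -> int:
        return int(self.membership.nunique())

    def to_tsv(self, path) -> None:
        self.membership.rename("community").rename_axis("feature_id").to_csv(
            path, sep="\t"
        )


def detect_communities(
    net: BiomolecularNetwork, resolution: float = 1.0, seed: int = 1
) -> CommunityPartition:
    """Leiden communities maximizing weighted modularity at ``resolution``.

    Deterministic given ``seed``. Communities are relabelled 0..k-1 by
    decreasing size. The summary attaches full-network average degree and,
    where node names parse as glycerolipids, mean total carbons / double
    bonds of those members.
    """
    if net.n_nodes == 0:
        raise ValueError("empty graph")
    nodes = list(net.graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.graph.edges]
    weights = [d["weight"] for _, _, d in net.graph.edges(data=True)]
    g = ig.Graph(n=len(nodes), edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights or None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = pd.Series(part.membership, index=nodes)
    order = raw.value_counts().index  # by size, ties by first label
    relabel = {old: new for new, old in enumerate(order)}
    membership = raw.map(relabel)

    deg = dict(net.graph.degree())
    rows = []
    for cid in range(membership.nunique()):
        mem = membership.index[membership == cid]
        carbons, dbs = [], []
        for v in mem:
            try:
                sp = parse_lipid_name(str(v))
            except LipidParseError:
                continue
            if sp.category == "glycerolipid":
                carbons.append(sp.total_carbons)
                dbs.append(sp.total_double_bonds)
        rows.append(
            {
                "community": cid,
                "size": len(mem),
                "avg_degree": float(np.mean([deg[v] for v in mem])),
                "glycerolipid_mean_carbons": float(np.mean(carbons)) if carbons else np.nan,
                "glycerolipid_mean_double_bonds": float(np.mean(dbs)) if dbs else np.nan,
            }
        )
    groups = [set(membership.index[membership == c]) for c in range(membership.nunique())]
    modularity = nx.community.modularity(net.graph, groups, weight="weight",
                                         resolution=resolution)
    return CommunityPartition(
        membership=membership,
        summary=pd.DataFrame(rows),
        resolution=resolution,
        seed=seed,
        modularity=float(modularity),
    )


def centrality_rank(net: BiomolecularNetwork, top_fraction: float = 0.1) -> list:
    """Most interconnected nodes by degree.

    Ties broken by weighted degree, then lexicographic id; returns the top
    ``ceil(top_fraction * n)`` nodes.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    wdeg = dict(net.graph.degree(weight="weight"))
    deg = dict(net.graph.degree())
    ranked = sorted(net.graph.nodes, key=lambda v: (-deg[v], -wdeg[v], v))
    k = math.ceil(top_fraction * net.n_nodes)
    return ranked[:k]


# ---------------------------------------------------------------------------
# clinical association


def _is_binary(x: pd.Series) -> bool:
    vals = pd.unique(x.dropna())
    return len(vals) == 2


def _regress(y: pd.Series, score: np.ndarray) -> tuple[str, float, float] | None:
    """Regress clinical variable on a score; returns (model, estimate, p)."""
    X = sm.add_constant(pd.DataFrame({"score": score}, index=y.index))
    if _is_binary(y):
        yb = (y == sorted(pd.unique(y))[-1]).astype(float)
        try:
            fit = sm.Logit(yb, X).fit(disp=0)
        except Exception:  # non-convergence
            return None
        # likelihood-ratio p: robust under (quasi-)separation, where the
        # Wald statistic degenerates
        return "logistic", float(fit.params["score"]), float(fit.llr_pvalue)
    fit = sm.OLS(y.astype(float), X).fit()
    return "linear", float(fit.params["score"]), float(fit.pvalues["score"])


def community_scores(
    partition: CommunityPartition, combined: AbundanceMatrix, method: str = "mean_z"
) -> pd.DataFrame:
    """Per-sample community abundance scores (samples x communities).

    ``mean_z``: mean of member z-scores; ``pc1``: first principal component
    of the member z-score matrix (sign aligned with the mean-z score).
    """
    z = combined.zscores()
    out = {}
    for cid in range(partition.n_communities):
        mem = [v for v in partition.members(cid) if v in z.index]
        zm = z.loc[mem]
        mean_z = zm.mean(axis=0)
        if method == "mean_z" or len(mem) == 1:
            out[cid] = mean_z
        elif method == "pc1":
            u, s, vt = np.linalg.svd(zm.to_numpy() - zm.to_numpy().mean(axis=1, keepdims=True),
                                     full_matrices=False)
            pc1 = pd.Series(vt[0] * s[0], index=zm.columns)
            if np.corrcoef(pc1, mean_z)[0, 1] < 0:
                pc1 = -pc1
            out[cid] = pc1
        else:
            raise ValueError(f"unknown community score method {method!r}")
    return pd.DataFrame(out)


def community_clinical_assoc(
    partition: CommunityPartition,
    combined: AbundanceMatrix,
    clinical: pd.DataFrame,
    score_method: str = "mean_z",
) -> pd.DataFrame:
    """Regress every clinical variable on every community score.

    Logistic regression for binary variables, linear for continuous;
    BH-adjusted across all community x variable tests. Constant variables
    are skipped with a warning.
    """
    scores = community_scores(partition, combined, score_method)
    clinical = clinical.loc[combined.sample_ids]
    rows = []
    for var in clinical.columns:
        y = clinical[var]
        if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
            if y.nunique() != 2:
                log.warning("skipping non-binary categorical variable %r", var)
                continue
        if y.nunique() <= 1:
            log.warning("skipping constant clinical variable %r", var)
            continue
        for cid in scores.columns:
            res = _regress(y, scores[cid].to_numpy())
            if res is None:
                log.warning("regression failed for %r ~ community %d", var, cid)
                continue
            model, est, p = res
            rows.append(
                {"unit": f"c{cid + 1}", "variable": var, "model": model,
                 "estimate": est, "p": p}
            )
    tbl = pd.DataFrame(rows)
    if not tbl.empty:
        tbl["q"] = bh_adjust(tbl["p"].to_numpy())
    return tbl


def feature_clinical_assoc(
    combined: AbundanceMatrix, clinical_var: pd.Series, q_cut: float = 0.01
) -> pd.DataFrame:
    """Univariate regression of one clinical variable on each feature.

    Model chosen by variable type (logistic if binary); BH across features;
    ``selected`` flags q <= q_cut.
    """
    clinical_var = clinical_var.loc[combined.sample_ids]
    if clinical_var.nunique() <= 1:
        raise ValueError("clinical variable is constant")
    rows = []
    for fid, row in combined.values.iterrows():
        res = _regress(clinical_var, row.to_numpy(float))
        if res is None:
            log.warning("regression failed for %r ~ %s", clinical_var.name, fid)
            continue
        model, est, p = res
        rows.append({"feature_id": fid, "model": model, "estimate": est, "p": p})
    tbl = pd.DataFrame(rows).set_index("feature_id")
    tbl["q"] = bh_adjust(tbl["p"].to_numpy())
    tbl["selected"] = tbl["q"] <= q_cut
    return tbl


# ---------------------------------------------------------------------------
# over-representation analysis


def ora_enrichment(member_set, annotation: dict, background) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a set.

    ``annotation`` maps term -> feature collection; terms are intersected
    with ``background`` first. Upper-tail hypergeometric p per term
    (P[overlap >= observed]), BH across terms.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    members = set(member_set)
    if not members <= background:
        raise ValueError(
            f"member set not contained in background: {sorted(members - background)[:5]}"
        )
    n_bg = len(background)
    n_mem = len(members)
    rows = []
    for term, feats in annotation.items():
        term_set = set(feats) & background
        k = len(term_set & members)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(term_set), n_mem))
        rows.append(
            {"term": term, "overlap": k, "term_size": len(term_set), "p": p}
        )
    tbl = pd.DataFrame(rows)
    if not tbl.empty:
        tbl["q"] = bh_adjust(tbl["p"].to_numpy())
    return tbl
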