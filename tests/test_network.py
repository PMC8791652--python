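"""Spearman network, ER null, Leiden communities, clinical association, ORA."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidmets.data import AbundanceMatrix
from lipidmets.network import (
    BiomolecularNetwork,
    centrality_rank,
    community_clinical_assoc,
    detect_communities,
    er_null_compare,
    feature_clinical_assoc,
    ora_enrichment,
    spearman_network,
)
from conftest import make_matrix


def _net_from_graph(g):
    return BiomolecularNetwork(graph=g, fdr_cut=1.0, rho_cut=0.0)


class TestSpearmanNetwork:
    def test_monotone_transforms_form_complete_triangle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        m = make_matrix(np.vstack([x, np.exp(x), x**3]))
        net = spearman_network(m, fdr_cut=0.05, rho_cut=0.3)
        assert net.n_nodes == 3 and net.n_edges == 3
        assert all(d["weight"] == pytest.approx(1.0)
                   for _, _, d in net.graph.edges(data=True))

    def test_negative_correlation_excluded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        m = make_matrix(np.vstack([x, -x + rng.normal(0, 0.01, 50)]))
        net = spearman_network(m, fdr_cut=0.05, rho_cut=0.3)
        assert net.n_edges == 0

    def test_tie_heavy_rho_matches_midrank_oracle(self):
        """Spearman rho on tie-heavy vectors equals Pearson on mid-ranks
        computed independently."""
        a = np.array([1, 1, 2, 2, 2, 3, 4, 4, 5, 5, 5, 5] * 3, dtype=float)
        rng = np.random.default_rng(2)
        b = np.floor(a + rng.integers(-1, 2, a.size)).astype(float)
        m = make_matrix(np.vstack([a, b]))
        net = spearman_network(m, fdr_cut=1.0, rho_cut=0.0)
        rho_oracle = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
        w = net.graph["f0"]["f1"]["weight"]
        assert w == pytest.approx(rho_oracle, abs=1e-12)

    def test_constant_feature_excluded(self):
        rng = np.random.default_rng(3)
        vals = np.vstack([np.ones(30), rng.normal(size=(2, 30))])
        net = spearman_network(make_matrix(vals), fdr_cut=1.0, rho_cut=0.0)
        assert "f0" not in net.graph

    def test_edge_set_invariant_to_monotone_feature_transform(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(6, 60))
        vals[1] = vals[0] * 0.9 + rng.normal(0, 0.3, 60)
        m1 = make_matrix(vals)
        vals2 = vals.copy()
        vals2[0] = np.exp(vals2[0])
        m2 = make_matrix(vals2)
        n1 = spearman_network(m1, fdr_cut=0.05, rho_cut=0.3)
        n2 = spearman_network(m2, fdr_cut=0.05, rho_cut=0.3)
        assert set(n1.graph.edges) == set(n2.graph.edges)


class TestERNull:
    def test_null_draws_have_exact_node_and_edge_counts(self):
        g = nx.gnm_random_graph(30, 60, seed=0)
        net = _net_from_graph(g)
        rng = np.random.default_rng(1)
        for _ in range(20):
            draw = nx.gnm_random_graph(net.n_nodes, net.n_edges,
                                       seed=int(rng.integers(2**31)))
            assert draw.number_of_nodes() == 30
            assert draw.number_of_edges() == 60

    def test_null_clustering_matches_er_density(self):
        """Mean null clustering over 200 G(100,500) draws approximates the
        ER edge density 2m/(n(n-1))."""
        net = _net_from_graph(nx.gnm_random_graph(100, 500, seed=2))
        cmp = er_null_compare(net, n_draws=200, seed=3)
        expected = 2 * 500 / (100 * 99)
        se = cmp.null_sd["clustering"] / np.sqrt(200)
        assert abs(cmp.null_mean["clustering"] - expected) < 3 * max(se, 1e-4)

    def test_planted_blocks_fall_outside_envelope(self):
        blocks = [nx.complete_graph(range(10 * i, 10 * i + 10)) for i in range(3)]
        g = nx.union_all(blocks)
        g.add_edge(0, 10)
        g.add_edge(10, 20)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        cmp = er_null_compare(_net_from_graph(g), n_draws=100, seed=4)
        assert cmp.markedly_distinct


def _exhaustive_best_modularity(g, resolution=1.0):
    """Max modularity over all partitions of the node set (<= 8 nodes)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i in range(len(smaller)):
                yield smaller[:i] + [smaller[i] | {head}] + smaller[i + 1:]
            yield smaller + [{head}]

    best = -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(g, part, weight="weight", resolution=resolution)
        best = max(best, q)
    return best


class TestCommunities:
    def test_two_cliques_recovered(self):
        g = nx.union(nx.complete_graph(5),
                     nx.relabel_nodes(nx.complete_graph(5), {i: i + 5 for i in range(5)}))
        g.add_edge(0, 5)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        part = detect_communities(_net_from_graph(g), seed=1)
        assert part.n_communities == 2
        comm = {frozenset(part.members(c)) for c in range(2)}
        assert comm == {frozenset(range(5)), frozenset(range(5, 10))}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_leiden_matches_exhaustive_modularity_on_8_nodes(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(8, 14, seed=seed + 10)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.4, 1.0))
        part = detect_communities(_net_from_graph(g), seed=1)
        best = _exhaustive_best_modularity(g)
        assert part.modularity == pytest.approx(best, abs=1e-10)

    def test_huge_resolution_gives_singletons(self):
        g = nx.complete_graph(6)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        part = detect_communities(_net_from_graph(g), resolution=1000.0, seed=1)
        assert part.n_communities == 6

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            detect_communities(_net_from_graph(nx.Graph()))

    def test_planted_block_network_recovered_at_high_ari(self):
        """Three correlated feature blocks (within-rho 0.7, between ~0.1)
        are recovered by spearman_network + Leiden at mean ARI >= 0.9."""
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, per = 120, 12
            rho = 0.7
            rows, truth = [], []
            for b in range(3):
                f = rng.standard_normal(n)
                for _ in range(per):
                    rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n))
                    truth.append(b)
            m = make_matrix(np.array(rows))
            net = spearman_network(m, fdr_cut=1e-4, rho_cut=0.3)
            part = detect_communities(net, seed=1)
            labels = [part.membership[f"f{i}"] for i in range(len(rows))
                      if f"f{i}" in part.membership.index]
            kept_truth = [truth[i] for i in range(len(rows))
                          if f"f{i}" in part.membership.index]
            aris.append(adjusted_rand_score(kept_truth, labels))
        assert np.mean(aris) >= 0.9


class TestCentrality:
    def test_star_hub(self):
        g = nx.star_graph(9)  # node 0 plus 9 leaves
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        assert centrality_rank(_net_from_graph(g), 0.1) == [0]

    def test_equal_degrees_lexicographic(self):
        g = nx.cycle_graph(["b", "a", "d", "c"])
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        assert centrality_rank(_net_from_graph(g), 0.5) == ["a", "b"]

    def test_hub_set_stable_under_weight_rescaling(self):
        g = nx.gnm_random_graph(20, 50, seed=5)
        for u, v in g.edges:
            g[u][v]["weight"] = np.random.default_rng(6).uniform(0.4, 1)
        net = _net_from_graph(g)
        top = centrality_rank(net, 0.2)
        for u, v in g.edges:
            g[u][v]["weight"] *= 7.5
        assert centrality_rank(_net_from_graph(g), 0.2) == top


class TestClinicalAssociation:
    def test_known_effect_detected(self, small_cohort):
        from lipidmets.preprocess import impute_and_center, log_transform

        logged = log_transform(impute_and_center(small_cohort.lipids))
        met = log_transform(impute_and_center(small_cohort.metabolites))
        combined = logged.concat(met)
        net = spearman_network(combined, fdr_cut=1e-4, rho_cut=0.3)
        part = detect_communities(net, seed=1)
        assoc = community_clinical_assoc(part, combined, small_cohort.clinical)
        mets_rows = assoc[assoc["variable"] == "mets"]
        # the planted community associates positively with MetS at the
        # community-association threshold of the analysis
        hit = mets_rows[(mets_rows["q"] < 0.12) & (mets_rows["estimate"] > 0)]
        assert not hit.empty

    def test_constructed_score_strongly_associated(self):
        """A community whose members track the group label (score ~ group
        + N(0, 0.1)) yields a positive MetS association at q < 0.01."""
        from lipidmets.network import CommunityPartition

        rng = np.random.default_rng(42)
        g = np.repeat([0, 1], 50)
        vals = np.vstack([g + rng.normal(0, 0.1, 100) for _ in range(3)]
                         + [rng.normal(size=100) for _ in range(3)])
        m = make_matrix(vals, group=list(g), scale="log")
        membership = pd.Series([0, 0, 0, 1, 1, 1],
                               index=[f"f{i}" for i in range(6)])
        part = CommunityPartition(membership=membership, summary=pd.DataFrame(),
                                  resolution=1.0, seed=1, modularity=0.0)
        clinical = pd.DataFrame({"mets": g}, index=m.sample_ids)
        assoc = community_clinical_assoc(part, m, clinical)
        row = assoc[(assoc["unit"] == "c1") & (assoc["variable"] == "mets")].iloc[0]
        assert row["model"] == "logistic"
        assert row["estimate"] > 0 and row["q"] < 0.01

    def test_null_scores_give_uniform_pvalues(self):
        """Clinical variable independent of community scores: p-values over
        repeated draws are uniform (KS p > 0.01)."""
        from lipidmets.network import CommunityPartition

        rng = np.random.default_rng(77)
        pvals = []
        membership = pd.Series([0, 0, 0], index=["f0", "f1", "f2"])
        part = CommunityPartition(membership=membership, summary=pd.DataFrame(),
                                  resolution=1.0, seed=1, modularity=0.0)
        for _ in range(100):
            m = make_matrix(rng.normal(size=(3, 40)), scale="log")
            clinical = pd.DataFrame({"v": rng.normal(size=40)}, index=m.sample_ids)
            assoc = community_clinical_assoc(part, m, clinical)
            pvals.append(assoc["p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_member_community_score_is_feature_zscore(self):
        from lipidmets.network import CommunityPartition, community_scores

        rng = np.random.default_rng(13)
        m = make_matrix(rng.normal(size=(1, 30)), scale="log")
        part = CommunityPartition(membership=pd.Series([0], index=["f0"]),
                                  summary=pd.DataFrame(), resolution=1.0,
                                  seed=1, modularity=0.0)
        scores = community_scores(part, m)
        assert np.allclose(scores[0].to_numpy(), m.zscores().iloc[0].to_numpy())

    def test_feature_assoc_simulated_vat(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(10, 80))
        m = make_matrix(vals, scale="log")
        vat = pd.Series(2 * vals[0] + rng.normal(0, 0.5, 80),
                        index=m.sample_ids, name="vat")
        tbl = feature_clinical_assoc(m, vat, q_cut=0.01)
        assert bool(tbl.loc["f0", "selected"])
        assert tbl.loc["f0", "estimate"] > 0
        assert tbl.loc["f0", "model"] == "linear"

    def test_feature_assoc_permuted_var_mostly_empty(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            m = make_matrix(rng.normal(size=(15, 60)), scale="log")
            var = pd.Series(rng.normal(size=60), index=m.sample_ids, name="v")
            tbl = feature_clinical_assoc(m, var, q_cut=0.01)
            hits += int(tbl["selected"].any())
        assert hits <= 1  # >= 95% of seeds select nothing

    def test_single_feature_q_equals_p(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(size=(1, 40)), scale="log")
        var = pd.Series(rng.normal(size=40), index=m.sample_ids, name="v")
        tbl = feature_clinical_assoc(m, var)
        assert tbl["q"].iloc[0] == pytest.approx(tbl["p"].iloc[0])

    def test_constant_variable_errors(self):
        m = make_matrix(np.random.default_rng(9).normal(size=(2, 30)), scale="log")
        with pytest.raises(ValueError):
            feature_clinical_assoc(m, pd.Series(1.0, index=m.sample_ids))


class TestORA:
    @staticmethod
    def _direct_p(N, K, n, k):
        """Exact upper-tail hypergeometric by direct summation."""
        total = math.comb(N, n)
        return sum(math.comb(K, j) * math.comb(N - K, n - j)
                   for j in range(k, min(K, n) + 1)) / total

    def test_fully_contained_term(self):
        background = [f"x{i}" for i in range(100)]
        term = background[:10]
        members = set(background[:10])
        tbl = ora_enrichment(members, {"T": term}, background).set_index("term")
        assert tbl.loc["T", "p"] == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            N = int(rng.integers(20, 120))
            background = [f"x{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            term = set(rng.choice(background, K, replace=False))
            members = set(rng.choice(background, n, replace=False))
            tbl = ora_enrichment(members, {"T": term}, background)
            k = len(term & members)
            assert tbl["p"].iloc[0] == pytest.approx(
                self._direct_p(N, K, n, k), abs=1e-12)

    def test_no_enrichment_when_proportions_match(self):
        background = [f"x{i}" for i in range(40)]
        term = background[:20]  # half of background
        members = set(background[:5] + background[20:25])  # half of members
        tbl = ora_enrichment(members, {"T": term}, background)
        assert tbl["p"].iloc[0] >= 0.5

    def test_empty_background_and_containment(self):
        with pytest.raises(ValueError):
            ora_enrichment({"a"}, {}, [])
        with pytest.raises(ValueError):
            ora_enrichment({"a"}, {}, ["b"])
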