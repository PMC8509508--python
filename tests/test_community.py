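"""Modularity, Louvain, leading-eigenvector and cluster summaries."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from agepnet import (
    LeadingEigenvectorCommunities,
    LouvainCommunities,
    cluster_summary,
    exhaustive_modularity_maximum,
    leading_eigenvector,
    louvain,
    modularity,
    stratified_analysis,
)
from agepnet.community import _adjacency
from agepnet.types import Partition, Report, ReportSet

from conftest import clique_bridge_graph, two_four_cliques


def _random_weighted_graph(rng, n, p=0.55):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 10**6)))
    for u, v in g.edges:
        g.edges[u, v]["weight"] = int(rng.integers(1, 6))
    return g


# ---------------------------------------------------------------- modularity

def test_two_disjoint_edges_component_partition_has_q_half():
    g = nx.Graph()
    g.add_edge("a", "b", weight=1)
    g.add_edge("c", "d", weight=1)
    assert modularity(g, {"a": 0, "b": 0, "c": 1, "d": 1}) == pytest.approx(0.5)


def test_singleton_partition_closed_form():
    """Every node alone: Q = -sum (k_i/2m)^2, always negative."""
    rng = np.random.default_rng(5)
    g = _random_weighted_graph(rng, 12)
    k = dict(g.degree(weight="weight"))
    m2 = sum(k.values())
    expected = -sum((kv / m2) ** 2 for kv in k.values())
    labels = {n: i for i, n in enumerate(g.nodes)}
    assert modularity(g, labels) == pytest.approx(expected, abs=1e-12)
    assert modularity(g, labels) < 0


def test_clique_bridge_partition_is_exactly_5_14():
    g = clique_bridge_graph()
    labels = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
    assert modularity(g, labels) == pytest.approx(5 / 14, abs=1e-12)


def test_modularity_matches_networkx_on_random_graphs():
    """Independent cross-check against the networkx implementation."""
    import networkx.algorithms.community as nxc

    rng = np.random.default_rng(17)
    for _ in range(5):
        g = _random_weighted_graph(rng, 10)
        if g.number_of_edges() == 0:
            continue
        part = louvain(g, seed=1)
        assert part.modularity == pytest.approx(
            nxc.modularity(g, part.communities()), abs=1e-10)


def test_modularity_requires_full_cover_and_edges():
    g = nx.Graph()
    g.add_edge("a", "b", weight=1)
    with pytest.raises(ValueError):
        modularity(g, {"a": 0})
    g2 = nx.Graph()
    g2.add_node("lonely")
    with pytest.raises(ValueError):
        modularity(g2, {"lonely": 0})


# ------------------------------------------------------------------- louvain

def test_louvain_recovers_disjoint_cliques():
    part = louvain(two_four_cliques(), seed=0)
    assert part.n_communities == 2
    assert part.modularity == pytest.approx(0.5)
    comms = part.communities()
    assert {frozenset(c) for c in comms} == {
        frozenset(range(4)), frozenset(range(4, 8))}


def test_louvain_finds_global_optimum_on_clique_bridge():
    part = louvain(clique_bridge_graph(), seed=0)
    assert part.modularity == pytest.approx(5 / 14, abs=1e-12)
    assert part.labels[0] == part.labels[1] == part.labels[2]
    assert part.labels[3] == part.labels[4] == part.labels[5]


def test_louvain_q_never_below_singleton_partition():
    rng = np.random.default_rng(31)
    for _ in range(5):
        g = _random_weighted_graph(rng, 9)
        if g.number_of_edges() == 0:
            continue
        singleton = modularity(g, {n: i for i, n in enumerate(g.nodes)})
        assert louvain(g, seed=2).modularity >= singleton


def test_louvain_deterministic_given_seed_and_estimator_api():
    g = nx.karate_club_graph()
    for u, v in g.edges:
        g.edges[u, v]["weight"] = 1
    est1 = LouvainCommunities(seed=7).fit(g)
    est2 = LouvainCommunities(seed=7).fit(g)
    assert est1.labels_ == est2.labels_
    assert est1.get_params() == {"resolution": 1.0, "seed": 7}
    est3 = LouvainCommunities().set_params(seed=7)
    assert (est3.fit_predict(g) == est1.fit_predict(g)).all()
    with pytest.raises(ValueError):
        est3.set_params(bogus=1)


def test_louvain_accepts_adjacency_matrix():
    A = np.array([[0, 3, 0, 0], [3, 0, 0, 0], [0, 0, 0, 2], [0, 0, 2, 0]],
                 dtype=float)
    labels = LouvainCommunities(seed=0).fit_predict(A)
    assert labels[0] == labels[1] and labels[2] == labels[3]
    assert labels[0] != labels[2]


def test_louvain_aggregation_preserves_modularity():
    """Q of the super-graph under identity = Q of the original partition."""
    rng = np.random.default_rng(8)
    g = _random_weighted_graph(rng, 10, p=0.6)
    nodes, A = _adjacency(g)
    labels = np.array([i % 3 for i in range(len(nodes))])
    agg = LouvainCommunities._aggregate(A, labels, 3)

    def q_from_matrix(M):
        m2 = M.sum()
        k = M.sum(axis=1)
        return float(np.trace(M) / m2 - ((k / m2) ** 2).sum())

    q_original = modularity(g, {n: int(c) for n, c in zip(nodes, labels)})
    assert q_from_matrix(agg) == pytest.approx(q_original, abs=1e-12)


def test_louvain_empty_graph_errors():
    with pytest.raises(ValueError):
        louvain(nx.Graph(), seed=0)


# ------------------------------------------------------- leading eigenvector

def test_leading_eigenvector_recovers_disjoint_cliques():
    part = leading_eigenvector(two_four_cliques())
    assert part.n_communities == 2
    assert part.modularity == pytest.approx(0.5)


def test_leading_eigenvector_agrees_with_louvain_on_clique_bridge():
    g = clique_bridge_graph()
    pe = leading_eigenvector(g)
    pl = louvain(g, seed=0)
    assert pe.labels == pl.labels
    assert pe.modularity == pytest.approx(5 / 14, abs=1e-12)


def test_single_edge_has_no_positive_eigenvalue_one_community():
    g = nx.Graph()
    g.add_edge("x", "y", weight=1)
    part = leading_eigenvector(g)
    assert part.n_communities == 1


def test_leading_eigenvector_split_is_sign_flip_invariant(monkeypatch):
    """Negating the leading eigenvector yields the same bipartition."""
    import agepnet.community as community_mod

    g = clique_bridge_graph()
    reference = leading_eigenvector(g).labels

    true_eig = community_mod._leading_eig

    def negated(Bg):
        val, vec = true_eig(Bg)
        return val, -vec

    monkeypatch.setattr(community_mod, "_leading_eig", negated)
    assert leading_eigenvector(g).labels == reference


def test_max_communities_caps_recursion():
    g = nx.disjoint_union_all(
        [nx.complete_graph(3) for _ in range(4)]
    )
    for u, v in g.edges:
        g.edges[u, v]["weight"] = 1
    est = LeadingEigenvectorCommunities(max_communities=2).fit(g)
    assert est.n_communities_ <= 2


# --------------------------------------------------- oracle-backed optimality

def test_both_methods_near_exhaustive_optimum_on_small_graphs():
    rng = np.random.default_rng(7)
    checked = 0
    for _ in range(8):
        n = int(rng.integers(4, 9))
        g = _random_weighted_graph(rng, n)
        if g.number_of_edges() == 0:
            continue
        q_max, _ = exhaustive_modularity_maximum(g)
        assert louvain(g, seed=0).modularity >= 0.95 * q_max - 1e-12
        assert leading_eigenvector(g).modularity >= 0.95 * q_max - 1e-12
        checked += 1
    assert checked >= 5


def test_partition_modularity_recomputes_exactly():
    g = clique_bridge_graph()
    part = louvain(g, seed=0)
    assert abs(modularity(g, part.labels) - part.modularity) < 1e-12


def test_igraph_cross_check_on_clique_bridge():
    """python-igraph reaches the same optimum (independent implementation)."""
    igraph = pytest.importorskip("igraph")
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    ig = igraph.Graph(edges)
    ours_l = louvain(clique_bridge_graph(), seed=0).modularity
    ours_e = leading_eigenvector(clique_bridge_graph()).modularity
    theirs = ig.community_leading_eigenvector().modularity
    assert ours_e == pytest.approx(theirs, abs=1e-9)
    assert ours_l == pytest.approx(
        ig.community_multilevel().modularity, abs=1e-9)


# --------------------------------------------------------- summaries, strata

def test_cluster_summary_dominant_share_matches_hand_ratio():
    """283-drug cluster with 77 cardiovascular drugs: share 27.2% (1 dp)."""
    n_total, n_cardio = 283, 77
    drugs = [f"d{i}" for i in range(n_total)]
    atc = {d: ("C01AA01" if i < n_cardio else f"{'JNABM'[i % 5]}01AA01")
           for i, d in enumerate(drugs)}
    reports = [
        Report(report_id=f"r{i}", drugs=frozenset({drugs[i], drugs[(i + 1) % n_total]}))
        for i in range(n_total)
    ]
    rs = ReportSet(reports=reports, atc=atc)
    from agepnet import build_graph

    g = build_graph(rs)
    part = Partition(labels={d: 0 for d in drugs}, modularity=0.0)
    summary = cluster_summary(g, part, rs, top_n=20)
    row = summary.overview.iloc[0]
    assert row["size"] == n_total
    assert row["dominant_atc1"] == "C"
    assert round(100 * row["dominant_share"], 1) == 27.2
    assert summary.overview["size"].sum() == g.number_of_nodes()


def test_cluster_summary_degree_matches_adjacency_recount(reference_cohort):
    from agepnet import build_graph, louvain as run_louvain

    g = build_graph(reference_cohort)
    part = run_louvain(g, seed=0)
    summary = cluster_summary(g, part, reference_cohort, top_n=5)
    for _, row in summary.top_drugs.iterrows():
        recount = sum(1 for _ in g.neighbors(row["drug"]))
        assert row["degree"] == recount


def test_stratified_pair_counts_are_additive(reference_cohort):
    """Pooling per-sex pair counts = unstratified counts minus unknown-sex."""
    from agepnet import count_ksets

    known = reference_cohort.subset(lambda r: r.sex in ("female", "male"))
    total = count_ksets(known, 2)
    by_sex = {
        s: count_ksets(reference_cohort.subset(lambda r, s=s: r.sex == s), 2)
        for s in ("female", "male")
    }
    pooled = by_sex["female"] + by_sex["male"]
    assert pooled == total


def test_age65_boundary_assigns_65_to_older_stratum():
    reports = [
        Report(report_id="r1", drugs=frozenset({"a", "b"}), age_years=65),
        Report(report_id="r2", drugs=frozenset({"a", "b"}), age_years=64),
        Report(report_id="r3", drugs=frozenset({"a", "c"}), age_years=70),
        Report(report_id="r4", drugs=frozenset({"b", "c"}), age_years=30),
    ]
    rs = ReportSet(reports=reports, atc={"a": "A01AA01", "b": "B01AA01",
                                         "c": "C01AA01"})
    results = stratified_analysis(rs, "age65", seed=0)
    assert results["65+"].n_reports == 2
    assert results["<65"].n_reports == 2


def test_tiny_stratum_skipped_with_warning():
    reports = [
        Report(report_id=f"r{i}", drugs=frozenset({"a", "b"}), sex="female")
        for i in range(3)
    ] + [Report(report_id="rm", drugs=frozenset({"a", "b"}), sex="male")]
    rs = ReportSet(reports=reports, atc={"a": "A01AA01", "b": "B01AA01"})
    with pytest.warns(UserWarning, match="skipped"):
        results = stratified_analysis(rs, "sex", seed=0)
    assert "male" not in results and "female" in results


def test_identically_structured_strata_agree(planted_cohort):
    """Both sexes carry the same planted structure: partitions agree."""
    from sklearn.metrics import adjusted_rand_score

    report_set, truth, _ = planted_cohort
    results = stratified_analysis(report_set, "sex", seed=11)
    profile_drugs = sorted(truth.drug_labels)
    parts = []
    for res in results.values():
        labels = res.louvain.labels
        parts.append([labels[d] for d in profile_drugs])
    assert len(parts) == 2
    assert adjusted_rand_score(parts[0], parts[1]) >= 0.9
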