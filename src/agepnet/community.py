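"""Community detection on the weighted co-reporting network.

Two complementary algorithms, both maximizing Newman-Girvan modularity

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j)

with weighted adjacency A, weighted degrees k and total edge weight m:

* :class:`LouvainCommunities` — greedy multi-level optimization, alternating
  local node moves (each node to the neighboring community with the largest
  positive modularity gain) with aggregation of communities into a weighted
  super-graph with self-loops, until no move improves Q.  Node visit order
  is shuffled once per sweep from a seeded generator; among equal-gain moves
  the smallest community label wins, so a (graph, seed) pair is fully
  deterministic.
* :class:`LeadingEigenvectorCommunities` — recursive spectral bisection by
  the sign pattern of the leading eigenvector of the (generalized)
  modularity matrix, used here as a robustness check.  A split is accepted
  only when the leading eigenvalue is positive (beyond tolerance) and the
  bipartition strictly increases Q.

Both classes follow the scikit-learn estimator idiom (``fit`` /
``fit_predict``, fitted ``labels_`` and ``modularity_`` attributes,
``get_params``/``set_params``) and accept either a ``networkx`` graph or a
symmetric weighted adjacency matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .cooccurrence import marginal_counts
from .network import build_graph
from .types import Partition, ReportSet, relabel_contiguous

logger = logging.getLogger(__name__)

#: eigenvalue below this is treated as non-positive (bisection stopping rule)
EIG_TOL = 1e-9


def _as_graph(X) -> nx.Graph:
    """Accept a networkx graph or a square symmetric adjacency array."""
    if isinstance(X, nx.Graph):
        return X
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric (undirected network)")
    return nx.from_numpy_array(A)


def _adjacency(graph: nx.Graph):
    """Node list and dense adjacency with self-loop weights doubled.

    Doubling the diagonal makes ``A.sum()`` equal 2m and row sums the
    weighted degrees, the convention every formula here relies on.
    """
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    A[np.diag_indices_from(A)] *= 2.0
    return nodes, A


def modularity(
    graph: nx.Graph, labels: Mapping, resolution: float = 1.0
) -> float:
    """Newman-Girvan modularity Q of a partition on a weighted graph."""
    nodes, A = _adjacency(graph)
    missing = [n for n in nodes if n not in labels]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    m2 = A.sum()
    if m2 <= 0:
        raise ValueError("graph has no edge weight; modularity undefined")
    k = A.sum(axis=1)
    lab = np.array([labels[n] for n in nodes])
    q = 0.0
    for c in np.unique(lab):
        idx = np.flatnonzero(lab == c)
        sigma_in = A[np.ix_(idx, idx)].sum()
        sigma_tot = k[idx].sum()
        q += sigma_in / m2 - resolution * (sigma_tot / m2) ** 2
    return float(q)


class LouvainCommunities:
    """Greedy multi-level modularity optimization (clustering estimator).

    Parameters
    ----------
    resolution:
        Resolution parameter gamma of generalized modularity; 1.0 is the
        classic definition used throughout this package.
    seed:
        Seeds the node-visit shuffling; fixed seed => fixed partition.

    Attributes (after ``fit``)
    --------------------------
    nodes_, labels_ : node order and node -> community mapping
    modularity_ : Q of the returned partition
    n_communities_ : number of communities
    """

    def __init__(self, resolution: float = 1.0, seed: int = 0):
        self.resolution = resolution
        self.seed = seed

    # minimal scikit-learn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"resolution": self.resolution, "seed": self.seed}

    def set_params(self, **params) -> "LouvainCommunities":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "LouvainCommunities":
        graph = _as_graph(X)
        if graph.number_of_nodes() == 0:
            raise ValueError("empty graph")
        nodes, A = _adjacency(graph)
        if A.sum() <= 0:
            raise ValueError("graph has no edge weight")
        rng = np.random.default_rng(self.seed)

        n = len(nodes)
        labels = np.arange(n)  # flat labels on original nodes
        agg = A.copy()
        q_prev = -np.inf
        while True:
            level_labels = self._one_level(agg, rng)
            # map original nodes through this level's assignment
            labels = level_labels[labels]
            q_now = modularity(
                graph,
                {node: int(c) for node, c in zip(nodes, labels)},
                resolution=self.resolution,
            )
            n_comms = len(np.unique(level_labels))
            if q_now - q_prev <= 1e-12 or n_comms == agg.shape[0]:
                break
            q_prev = q_now
            # level_labels are compact, so they double as aggregated node ids
            agg = self._aggregate(agg, level_labels, n_comms)

        mapping = {node: int(c) for node, c in zip(nodes, labels)}
        mapping = relabel_contiguous(mapping, nodes)
        self.nodes_ = nodes
        self.labels_ = mapping
        self.modularity_ = modularity(graph, mapping, self.resolution)
        self.n_communities_ = len(set(mapping.values()))
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return np.array([self.labels_[n] for n in self.nodes_])

    def _one_level(self, A: np.ndarray, rng) -> np.ndarray:
        """Local-moving phase; returns a compacted community id per node."""
        n = A.shape[0]
        m2 = A.sum()
        k = A.sum(axis=1)
        self_w = A.diagonal().copy()
        comm = np.arange(n)
        sigma_tot = k.copy()
        gamma = self.resolution

        neighbors = [np.flatnonzero(A[i]) for i in range(n)]
        improved = True
        while improved:
            improved = False
            order = rng.permutation(n)  # visit order shuffled once per sweep
            for i in order:
                ci = comm[i]
                # links from i to each neighboring community (self-loop apart)
                w_comm: dict[int, float] = {}
                for j in neighbors[i]:
                    if j == i:
                        continue
                    w_comm[comm[j]] = w_comm.get(comm[j], 0.0) + A[i, j]
                # remove i from its community
                sigma_tot[ci] -= k[i]
                w_own = w_comm.get(ci, 0.0)
                # gain (x m) of joining community c; staying is the baseline
                best_c, best_gain = ci, w_own - gamma * k[i] * sigma_tot[ci] / m2
                for c, w in sorted(w_comm.items()):
                    if c == ci:
                        continue
                    gain = w - gamma * k[i] * sigma_tot[c] / m2
                    if gain > best_gain + 1e-12 or (
                        abs(gain - best_gain) <= 1e-12 and c < best_c
                    ):
                        best_c, best_gain = c, gain
                comm[i] = best_c
                sigma_tot[best_c] += k[i]
                if best_c != ci:
                    improved = True
        # compact labels to 0..n_comms-1 preserving first-appearance order
        uniq: dict[int, int] = {}
        out = np.empty(n, dtype=int)
        for i in range(n):
            out[i] = uniq.setdefault(comm[i], len(uniq))
        return out

    @staticmethod
    def _aggregate(A: np.ndarray, labels: np.ndarray, n_comms: int) -> np.ndarray:
        """Community super-graph; diagonal keeps doubled internal weight."""
        M = np.zeros((n_comms, A.shape[0]))
        M[labels, np.arange(A.shape[0])] = 1.0
        return M @ A @ M.T


class LeadingEigenvectorCommunities:
    """Recursive modularity-matrix bisection (Newman's spectral method).

    Each candidate group g is split by the sign of the leading eigenvector
    of the generalized modularity matrix
    ``B(g)_ij = B_ij - delta_ij * sum_{l in g} B_il`` restricted to g; the
    sign convention fixes the largest-magnitude component positive, so
    negating the eigenvector cannot change the bipartition.  Splitting stops
    when the leading eigenvalue is <= ``tol`` or the split does not increase
    Q, or when ``max_communities`` is reached.
    """

    def __init__(self, max_communities: Optional[int] = None,
                 tol: float = EIG_TOL):
        self.max_communities = max_communities
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"max_communities": self.max_communities, "tol": self.tol}

    def set_params(self, **params) -> "LeadingEigenvectorCommunities":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "LeadingEigenvectorCommunities":
        graph = _as_graph(X)
        if graph.number_of_nodes() == 0:
            raise ValueError("empty graph")
        nodes, A = _adjacency(graph)
        m2 = A.sum()
        if m2 <= 0:
            raise ValueError("graph has no edge weight")
        k = A.sum(axis=1)
        B = A - np.outer(k, k) / m2

        groups: list[np.ndarray] = [np.arange(len(nodes))]
        final: list[np.ndarray] = []
        while groups:
            if (
                self.max_communities is not None
                and len(groups) + len(final) >= self.max_communities
            ):
                final.extend(groups)
                break
            g = groups.pop(0)
            split = self._try_split(B, g, m2)
            if split is None:
                final.append(g)
            else:
                groups.extend(split)

        labels: dict = {}
        for c, g in enumerate(final):
            for idx in g:
                labels[nodes[idx]] = c
        labels = relabel_contiguous(labels, nodes)
        self.nodes_ = nodes
        self.labels_ = labels
        self.modularity_ = modularity(graph, labels)
        self.n_communities_ = len(set(labels.values()))
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return np.array([self.labels_[n] for n in self.nodes_])

    def _try_split(self, B: np.ndarray, g: np.ndarray, m2: float):
        if g.size < 2:
            return None
        Bg = B[np.ix_(g, g)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        lead_val, vec = _leading_eig(Bg)
        if lead_val <= self.tol:
            return None
        # fixed sign convention: largest-magnitude component positive
        pivot = int(np.argmax(np.abs(vec)))
        if vec[pivot] < 0:
            vec = -vec
        s = np.where(vec >= 0.0, 1.0, -1.0)
        delta_q = float(s @ Bg @ s) / (2.0 * m2)
        left, right = g[s > 0], g[s < 0]
        if delta_q <= 1e-12 or left.size == 0 or right.size == 0:
            return None
        return [left, right]


def _leading_eig(Bg: np.ndarray):
    """Leading (largest) eigenpair of a symmetric matrix, deterministically."""
    n = Bg.shape[0]
    if n > 500:
        from scipy.sparse.linalg import eigsh

        v0 = np.arange(1.0, n + 1.0)
        v0 /= np.linalg.norm(v0)
        vals, vecs = eigsh(Bg, k=1, which="LA", v0=v0)
        return float(vals[0]), vecs[:, 0]
    vals, vecs = np.linalg.eigh(Bg)
    return float(vals[-1]), vecs[:, -1]


def louvain(graph: nx.Graph, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Louvain partition of a weighted graph (functional wrapper)."""
    est = LouvainCommunities(resolution=resolution, seed=seed).fit(graph)
    return Partition(labels=est.labels_, modularity=est.modularity_)


def leading_eigenvector(
    graph: nx.Graph, max_communities: Optional[int] = None
) -> Partition:
    """Leading-eigenvector partition of a weighted graph (functional wrapper)."""
    est = LeadingEigenvectorCommunities(max_communities=max_communities).fit(graph)
    return Partition(labels=est.labels_, modularity=est.modularity_)


def _set_partitions(items: Sequence):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    n = len(items)
    if n == 0:
        yield []
        return
    codes = [0] * n

    def rec(i: int, max_code: int):
        if i == n:
            groups: dict[int, list] = {}
            for item, c in zip(items, codes):
                groups.setdefault(c, []).append(item)
            yield [groups[c] for c in sorted(groups)]
            return
        for c in range(max_code + 2):
            codes[i] = c
            yield from rec(i + 1, max(max_code, c))

    yield from rec(1, 0)


def exhaustive_modularity_maximum(graph: nx.Graph) -> tuple[float, dict]:
    """Brute-force maximum-modularity partition (oracle for small graphs).

    Enumerates every set partition of the nodes — Bell(n) of them — so this
    is only usable for roughly n <= 10.  Independent of both optimization
    algorithms; used to validate them.
    """
    nodes, A = _adjacency(graph)
    if len(nodes) > 10:
        raise ValueError("exhaustive search limited to graphs with <= 10 nodes")
    m2 = A.sum()
    if m2 <= 0:
        raise ValueError("graph has no edge weight; modularity undefined")
    k = A.sum(axis=1)
    B = (A - np.outer(k, k) / m2) / m2
    index = {n: i for i, n in enumerate(nodes)}
    best_q, best_labels = -np.inf, None
    for parts in _set_partitions(nodes):
        q = sum(
            B[np.ix_([index[n] for n in group], [index[n] for n in group])].sum()
            for group in parts
        )
        if q > best_q:
            best_q = q
            best_labels = {n: c for c, group in enumerate(parts) for n in group}
    return float(best_q), best_labels


@dataclass
class ClusterSummary:
    """Per-cluster overview plus the top drugs of each cluster."""

    overview: "pd.DataFrame"
    top_drugs: "pd.DataFrame"


def cluster_summary(
    graph: nx.Graph,
    partition: Partition,
    report_set: ReportSet,
    top_n: int = 20,
) -> ClusterSummary:
    """Summarize each community: size, dominant ATC-1 share, leading drugs.

    The dominant ATC-1 share is (drugs in the modal anatomical main group) /
    (cluster size).  Top drugs are ranked by prevalence with their node
    degree (connections in the graph), report count and prevalence.
    """
    import pandas as pd

    n_reports = report_set.n_reports
    marg = marginal_counts(report_set)
    overview_rows = []
    drug_rows = []
    for c, members in enumerate(partition.communities()):
        atc1 = [graph.nodes[d].get("atc1", "unknown") for d in members]
        counts = pd.Series(atc1).value_counts()
        dominant = counts.index[0]
        overview_rows.append(
            {
                "community": c,
                "size": len(members),
                "dominant_atc1": dominant,
                "dominant_share": counts.iloc[0] / len(members),
            }
        )
        ranked = sorted(
            members, key=lambda d: (-marg.get(d, 0), d)
        )[:top_n]
        for d in ranked:
            drug_rows.append(
                {
                    "community": c,
                    "drug": d,
                    "degree": graph.degree(d),
                    "n_reports": marg.get(d, 0),
                    "prevalence": marg.get(d, 0) / n_reports,
                    "atc1": graph.nodes[d].get("atc1", "unknown"),
                }
            )
    overview = pd.DataFrame(overview_rows).sort_values(
        "size", ascending=False, ignore_index=True
    )
    top = pd.DataFrame(drug_rows)
    return ClusterSummary(overview=overview, top_drugs=top)


@dataclass
class StratumResult:
    graph: nx.Graph
    louvain: Partition
    leading_eigenvector: Partition
    summary: ClusterSummary
    n_reports: int


def _stratum_assign(report, strata: str) -> Optional[str]:
    if strata == "sex":
        return report.sex if report.sex in ("female", "male") else None
    if strata == "age65":
        if report.age_years is None:
            return None
        # boundary rule: exactly 65 goes to the older stratum (<65 vs >=65)
        return "65+" if report.age_years >= 65 else "<65"
    raise ValueError(f"strata must be 'sex' or 'age65', got {strata!r}")


def stratified_analysis(
    report_set: ReportSet,
    strata: str,
    seed: int = 0,
    top_n: int = 20,
    min_reports: int = 2,
) -> dict[str, StratumResult]:
    """Re-run network construction + both clusterings within each stratum.

    Reports with unknown sex (or unknown age) are excluded from their
    stratification only.  Strata with fewer than ``min_reports`` reports are
    skipped with a warning.
    """
    buckets: dict[str, list] = {}
    for report in report_set.reports:
        key = _stratum_assign(report, strata)
        if key is not None:
            buckets.setdefault(key, []).append(report)

    results: dict[str, StratumResult] = {}
    for key in sorted(buckets):
        reports = buckets[key]
        if len(reports) < min_reports:
            warnings.warn(
                f"stratum {key!r} has {len(reports)} report(s); skipped",
                stacklevel=2,
            )
            continue
        subset = ReportSet(reports=reports, flow=None, atc=dict(report_set.atc))
        graph = build_graph(subset)
        part_l = louvain(graph, seed=seed)
        part_e = leading_eigenvector(graph)
        results[key] = StratumResult(
            graph=graph,
            louvain=part_l,
            leading_eigenvector=part_e,
            summary=cluster_summary(graph, part_l, subset, top_n=top_n),
            n_reports=len(reports),
        )
    return results
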