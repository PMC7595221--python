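"""Permutation significance of node-set statistics in an interaction network.

Four statistics of a protein set are measured against the whole analysis
network: mean degree, mean unweighted shortest-path length over ordered pairs
within the set (paths run through the full network), the size of the largest
connected component of the subgraph induced on the set alone, and mean
normalised betweenness centrality.  Null distributions are built by uniformly
resampling node sets of the same size from the network; one-sided empirical P
values use the add-one (bias-corrected) estimator by default.  Hubs and
bottlenecks are nodes strictly above the 90th percentile of degree and/or
betweenness.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

STAT_NAMES = ("mean_degree", "mean_shortest_path", "lcc_size", "mean_betweenness")
# tails fixed a priori: altered sets are expected to be better connected
# (higher degree/betweenness/LCC) and closer together (lower shortest path)
TAILS = {
    "mean_degree": "upper",
    "mean_shortest_path": "lower",
    "lcc_size": "upper",
    "mean_betweenness": "upper",
}


def read_string_links(path: str | Path, score_threshold: float = 0.5) -> nx.Graph:
    """Parse a STRING protein-links file into an undirected scored graph.

    Accepts 0-999 integer or 0-1 decimal combined scores (auto-detected);
    integer scores are divided by 1000.  Edges below the threshold, duplicate
    rows and self-loops are dropped.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    rows: list[tuple[str, str, float]] = []
    with opener(path, "rt") as fh:
        header = fh.readline().split()
        if len(header) < 3:
            raise ValueError(f"{path}: malformed header {header!r}")
        start = 2
        if header[:3] != ["protein1", "protein2", "combined_score"]:
            # headerless file: first line is data
            try:
                rows.append((header[0], header[1], float(header[2])))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line 1") from exc
            start = 1
        for lineno, line in enumerate(fh, start=start):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed score at line {lineno}") from exc
            rows.append((parts[0], parts[1], score))
    if not rows:
        raise ValueError(f"{path}: no edges")
    max_score = max(r[2] for r in rows)
    if max_score > 1.0:
        if max_score > 1000:
            raise ValueError(f"{path}: unknown score scale (max {max_score})")
        scale = 1000.0
    else:
        scale = 1.0
    g = nx.Graph()
    n_self = 0
    for u, v, s in rows:
        score = s / scale
        if u == v:
            n_self += 1
            continue
        if score >= score_threshold:
            g.add_edge(u, v, combined_score=score)
    g.graph["score_scale"] = scale
    g.graph["self_loops_dropped"] = n_self
    return g


def induce_lcc_subgraph(net: nx.Graph, ids: Iterable[str]) -> nx.Graph:
    """Subgraph induced on ids, then its largest connected component.

    Component-size ties break toward the component containing the
    lexicographically smallest node.
    """
    ids = set(ids)
    present = ids & set(net.nodes)
    if not present:
        raise ValueError("none of the requested ids are in the network")
    sub = net.subgraph(present)
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    lcc = net.subgraph(comps[0]).copy()
    lcc.graph["n_query"] = len(ids)
    lcc.graph["n_absent"] = len(ids - set(net.nodes))
    lcc.graph["n_outside_lcc"] = len(present) - lcc.number_of_nodes()
    return lcc


@dataclasses.dataclass
class NodeSetStats:
    nodes: tuple[str, ...]
    mean_degree: float
    mean_shortest_path: float
    lcc_size: int
    mean_betweenness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_degree": self.mean_degree,
            "mean_shortest_path": self.mean_shortest_path,
            "lcc_size": float(self.lcc_size),
            "mean_betweenness": self.mean_betweenness,
        }


class NetworkStatsEngine:
    """Precomputes whole-network degree, betweenness and distances once.

    Degree and betweenness of a node set are means over per-node values on the
    full network, so nulls at many samples reduce to indexed means; the
    shortest-path statistic uses the dense all-pairs unweighted distance
    matrix, and the induced-LCC size a sparse adjacency submatrix.
    """

    def __init__(self, net: nx.Graph):
        if net.number_of_nodes() < 2:
            raise ValueError("network must have at least 2 nodes")
        if not nx.is_connected(net):
            raise ValueError("analysis network must be connected (take the LCC first)")
        self.net = net
        self.nodes = sorted(net.nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.degree = np.array([net.degree(v) for v in self.nodes], dtype=float)
        bc = nx.betweenness_centrality(net, normalized=True)
        self.betweenness = np.array([bc[v] for v in self.nodes])
        adj = nx.to_scipy_sparse_array(net, nodelist=self.nodes, weight=None, format="csr")
        self.adjacency = csr_matrix(adj)
        self.distances = shortest_path(self.adjacency, method="D", unweighted=True)

    def _indices(self, s: Sequence[str]) -> np.ndarray:
        missing = [v for v in s if v not in self.index]
        if missing:
            raise ValueError(f"nodes not in network: {sorted(missing)[:10]}")
        return np.array([self.index[v] for v in s], dtype=int)

    def stats_for_indices(self, idx: np.ndarray) -> tuple[float, float, int, float]:
        k = idx.size
        sub = self.distances[np.ix_(idx, idx)]
        msp = float((sub.sum() - np.trace(sub)) / (k * (k - 1))) if k > 1 else 0.0
        a = self.adjacency[idx][:, idx]
        _, labels = connected_components(a, directed=False)
        lcc = int(np.bincount(labels).max())
        return float(self.degree[idx].mean()), msp, lcc, float(self.betweenness[idx].mean())

    def set_statistics(self, s: Sequence[str]) -> NodeSetStats:
        s = list(s)
        if len(s) < 2:
            raise ValueError("node set must contain at least 2 nodes")
        idx = self._indices(s)
        d, msp, lcc, b = self.stats_for_indices(idx)
        return NodeSetStats(tuple(sorted(s)), d, msp, lcc, b)


def set_statistics(net: nx.Graph, s: Sequence[str]) -> NodeSetStats:
    """Observed four statistics of a node set against the whole network."""
    return NetworkStatsEngine(net).set_statistics(s)


@dataclasses.dataclass
class NullDistribution:
    statistic: str
    samples: np.ndarray
    tail: str

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


def permutation_null(
    net: nx.Graph,
    set_size: int,
    n_samples: int = 10_000,
    seed: int = 0,
    engine: NetworkStatsEngine | None = None,
) -> dict[str, NullDistribution]:
    """Null distributions of the four statistics under uniform node resampling.

    The same sampled sets are reused across all four statistics.
    """
    engine = engine or NetworkStatsEngine(net)
    n = len(engine.nodes)
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds network size {n}")
    rng = np.random.default_rng(int(seed) % (2**31))
    out = {name: np.empty(n_samples) for name in STAT_NAMES}
    for i in range(n_samples):
        idx = rng.choice(n, size=set_size, replace=False)
        d, msp, lcc, b = engine.stats_for_indices(idx)
        out["mean_degree"][i] = d
        out["mean_shortest_path"][i] = msp
        out["lcc_size"][i] = lcc
        out["mean_betweenness"][i] = b
    return {name: NullDistribution(name, out[name], TAILS[name]) for name in STAT_NAMES}


def empirical_pvalue(
    null: NullDistribution, observed: float, tail: str | None = None, add_one: bool = True
) -> float:
    """One-sided empirical P: share of null values as or more extreme.

    The default add-one estimator counts the observation itself, so P is never
    exactly 0; ``add_one=False`` gives the raw proportion.
    """
    if null.samples.size == 0:
        raise ValueError("empty null distribution")
    tail = tail or null.tail
    if tail == "upper":
        extreme = int((null.samples >= observed).sum())
    elif tail == "lower":
        extreme = int((null.samples <= observed).sum())
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    if add_one:
        return (1 + extreme) / (1 + null.samples.size)
    return extreme / null.samples.size


def node_set_significance(
    net: nx.Graph,
    s: Sequence[str],
    n_samples: int = 10_000,
    seed: int = 0,
) -> tuple[NodeSetStats, dict[str, float]]:
    """Observed statistics of a set plus empirical P values against the null."""
    engine = NetworkStatsEngine(net)
    observed = engine.set_statistics(s)
    nulls = permutation_null(net, len(set(s)), n_samples=n_samples, seed=seed, engine=engine)
    obs = observed.as_dict()
    pvals = {name: empirical_pvalue(nulls[name], obs[name]) for name in STAT_NAMES}
    return observed, pvals


def classify_hub_bottleneck(net: nx.Graph, percentile: float = 90.0):
    """Classify every node by strict exceedance of the degree/betweenness percentiles.

    hub-bottleneck: above both; nonhub-bottleneck: betweenness only;
    hub-nonbottleneck: degree only; otherwise neither.  Percentiles use
    linear interpolation over all nodes of the analysis network.
    """
    import pandas as pd

    nodes = sorted(net.nodes)
    degree = np.array([net.degree(v) for v in nodes], dtype=float)
    bc_map = nx.betweenness_centrality(net, normalized=True)
    betweenness = np.array([bc_map[v] for v in nodes])
    deg_cut = np.percentile(degree, percentile)
    bet_cut = np.percentile(betweenness, percentile)
    is_hub = degree > deg_cut
    is_bottleneck = betweenness > bet_cut
    classes = np.where(
        is_hub & is_bottleneck,
        "hub-bottleneck",
        np.where(is_bottleneck, "nonhub-bottleneck", np.where(is_hub, "hub-nonbottleneck", "neither")),
    )
    n = len(nodes)
    deg_pct = 100.0 * (np.argsort(np.argsort(degree)) + 0.5) / n
    bet_pct = 100.0 * (np.argsort(np.argsort(betweenness)) + 0.5) / n
    return pd.DataFrame(
        {
            "degree": degree,
            "betweenness": betweenness,
            "degree_percentile": deg_pct,
            "betweenness_percentile": bet_pct,
            "class": classes,
        },
        index=pd.Index(nodes, name="protein_id"),
    )
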