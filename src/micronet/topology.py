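"""Network topology metrics, module detection and degree-preserving nulls.

Produces one consolidated summary per network: node/link/sign counts,
power-law degree fit, average degree, clustering, path distances,
centralization, density, transitivity, Krackhardt connectedness, module
count and modularity — plus means and standard deviations of selected
metrics over a Maslov-Sneppen (double-edge-swap) random ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import linregress

from .errors import ValidationError

NULL_METRICS = ("avgCC", "GD", "HD", "transitivity", "modularity")


def _g(net) -> nx.Graph:
    # accept either a CoNetwork wrapper or a bare networkx graph
    g = getattr(net, "graph", None)
    return g if isinstance(g, nx.Graph) else net


def _require_nonempty(g: nx.Graph):
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")


@dataclass
class ModulePartition:
    membership: dict          # node -> module id
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class NullSummary:
    means: dict
    sds: dict
    n_nets: int


@dataclass
class TopologySummary:
    name: str
    cutoff: float
    total_nodes: int
    total_links: int
    n_negative: int
    n_positive: int
    pct_negative: float
    pct_positive: float
    powerlaw_r2: float
    avgK: float
    avgCC: float
    GD: float
    HD: float
    CD: float
    CB: float
    density: float
    transitivity: float
    connectedness: float
    n_modules: int
    modularity: float
    random_null: NullSummary | None = None

    def to_series(self) -> pd.Series:
        d = {k: v for k, v in vars(self).items() if k not in ("random_null", "name")}
        if self.random_null is not None:
            for m in NULL_METRICS:
                d[f"random_{m}_mean"] = self.random_null.means[m]
                d[f"random_{m}_sd"] = self.random_null.sds[m]
        return pd.Series(d, name=self.name)


# -- elementary count identities (also reused on printed node/link counts) --

def avg_degree_from_counts(n_nodes: int, n_links: int) -> float:
    """avgK = 2L/N."""
    if n_nodes <= 0:
        raise ValidationError("empty network")
    return 2.0 * n_links / n_nodes


def density_from_counts(n_nodes: int, n_links: int) -> float:
    """D = 2L / (N(N-1))."""
    if n_nodes < 2:
        raise ValidationError("density needs at least two nodes")
    return 2.0 * n_links / (n_nodes * (n_nodes - 1))


def sign_percentages(n_negative: int, n_positive: int) -> tuple[float, float]:
    """Percentages of negative/positive links, rounded to 2 decimals."""
    total = n_negative + n_positive
    if total == 0:
        raise ValidationError("no links")
    return (round(100.0 * n_negative / total, 2),
            round(100.0 * n_positive / total, 2))


def avg_degree(net) -> float:
    g = _g(net)
    _require_nonempty(g)
    return avg_degree_from_counts(g.number_of_nodes(), g.number_of_edges())


def density(net) -> float:
    g = _g(net)
    return density_from_counts(g.number_of_nodes(), g.number_of_edges())


def sign_counts(net) -> tuple[int, int, float, float]:
    """(n_negative, n_positive, pct_negative, pct_positive) by edge sign."""
    g = _g(net)
    _require_nonempty(g)
    n_neg = sum(1 for *_, d in g.edges(data=True) if d.get("sign") == "-"
                or d.get("correlation", 1.0) < 0)
    n_pos = g.number_of_edges() - n_neg
    pct_neg, pct_pos = sign_percentages(n_neg, n_pos)
    return n_neg, n_pos, pct_neg, pct_pos


def clustering(net) -> tuple[float, float]:
    """(avgCC, transitivity); degree-<2 nodes count as 0 in the average."""
    g = _g(net)
    _require_nonempty(g)
    return float(nx.average_clustering(g)), float(nx.transitivity(g))


def geodesics(net) -> tuple[float, float]:
    """(GD, HD): mean shortest path over connected pairs, and the harmonic
    geodesic distance P / sum(1/d) with P = N(N-1)/2 (disconnected pairs
    contribute zero reciprocal distance)."""
    g = _g(net)
    _require_nonempty(g)
    n = g.number_of_nodes()
    total = 0.0
    inv_total = 0.0
    n_connected_pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for src, lengths in nx.all_pairs_shortest_path_length(sub):
            for dst, d in lengths.items():
                if d > 0:
                    total += d
                    inv_total += 1.0 / d
                    n_connected_pairs += 1
    total /= 2.0
    inv_total /= 2.0
    n_connected_pairs //= 2
    p = n * (n - 1) / 2.0
    gd = total / n_connected_pairs if n_connected_pairs else np.nan
    hd = p / inv_total if inv_total else np.inf
    return float(gd), float(hd)


def centralization(net) -> tuple[float, float]:
    """(CD, CB): degree and betweenness centralization, both normalized so
    a star graph scores 1."""
    g = _g(net)
    n = g.number_of_nodes()
    if n < 3:
        raise ValidationError("centralization needs at least three nodes")
    degs = np.array([d for _, d in g.degree()], dtype=float)
    cd = float((degs.max() - degs).sum() / ((n - 1) * (n - 2)))
    btw = np.array(list(nx.betweenness_centrality(g, normalized=True).values()))
    cb = float((btw.max() - btw).sum() / (n - 1))
    return cd, cb


def connectedness(net) -> float:
    """Krackhardt connectedness: fraction of node pairs joined by a path."""
    g = _g(net)
    _require_nonempty(g)
    n = g.number_of_nodes()
    if n < 2:
        return 1.0
    reachable = sum(len(c) * (len(c) - 1) for c in nx.connected_components(g))
    return float(reachable / (n * (n - 1)))


def degree_powerlaw_r2(degrees) -> float:
    """OLS R^2 of log(count of nodes with degree k) on log(k), k >= 1."""
    degs = np.asarray([d for d in degrees if d > 0])
    ks, counts = np.unique(degs, return_counts=True)
    if len(ks) < 3:
        raise ValidationError("power-law fit needs >= 3 distinct degrees")
    fit = linregress(np.log(ks), np.log(counts))
    return float(fit.rvalue ** 2)


def powerlaw_r2(net) -> float:
    g = _g(net)
    _require_nonempty(g)
    return degree_powerlaw_r2([d for _, d in g.degree()])


def detect_modules(net, method: str = "fast-greedy",
                   seed: int | None = None) -> ModulePartition:
    """Greedy agglomerative modularity maximization on the unsigned graph."""
    if method != "fast-greedy":
        raise ValidationError(f"unknown module detection method {method!r}")
    g = _g(net)
    _require_nonempty(g)
    if g.number_of_edges() == 0:
        membership = {node: i for i, node in enumerate(g.nodes)}
        return ModulePartition(membership, 0.0)
    communities = nx.community.greedy_modularity_communities(g)
    membership = {}
    for mid, comm in enumerate(communities):
        for node in comm:
            membership[node] = mid
    q = float(nx.community.modularity(g, communities))
    return ModulePartition(membership, q)


def random_null(net, n_nets: int = 100, n_swaps: int | None = None,
                seed: int | None = None) -> NullSummary:
    """Degree-preserving (Maslov-Sneppen double-edge-swap) null ensemble.

    Each replicate attempts 10*L swaps (rejecting self-loops/multi-edges)
    and contributes avgCC, GD, HD, transitivity and fast-greedy
    modularity; graphs admitting no swap yield identical copies with a
    warning.
    """
    g = _g(net)
    if g.number_of_edges() < 2:
        raise ValidationError("null model needs at least two links")
    if n_swaps is None:
        n_swaps = 10 * g.number_of_edges()
    rng = np.random.default_rng(seed)
    degrees = sorted(d for _, d in g.degree())
    samples = {m: [] for m in NULL_METRICS}
    warned = False
    for _ in range(n_nets):
        rep = g.copy()
        try:
            nx.double_edge_swap(rep, nswap=n_swaps,
                                max_tries=100 * n_swaps + 100,
                                seed=int(rng.integers(2 ** 31 - 1)))
        except nx.NetworkXError:
            if not warned:
                warnings.warn("no degree-preserving swap possible; null "
                              "ensemble is identical copies")
                warned = True
        assert sorted(d for _, d in rep.degree()) == degrees
        gd, hd = geodesics(rep)
        samples["avgCC"].append(nx.average_clustering(rep))
        samples["GD"].append(gd)
        samples["HD"].append(hd)
        samples["transitivity"].append(nx.transitivity(rep))
        samples["modularity"].append(detect_modules(rep).modularity)
    means = {m: float(np.mean(v)) for m, v in samples.items()}
    sds = {m: float(np.std(v)) for m, v in samples.items()}
    return NullSummary(means, sds, n_nets)


def summarize(net, nulls: NullSummary | None = None,
              name: str = "network") -> TopologySummary:
    """One consolidated record per network (Table-style column)."""
    g = _g(net)
    _require_nonempty(g)
    n_neg, n_pos, pct_neg, pct_pos = sign_counts(net)
    try:
        r2 = powerlaw_r2(net)
    except ValidationError:
        warnings.warn("power-law fit not evaluable (<3 distinct degrees); "
                      "reporting NaN")
        r2 = np.nan
    avgcc, trans = clustering(net)
    gd, hd = geodesics(net)
    cd, cb = centralization(net)
    mods = detect_modules(net)
    summary = TopologySummary(
        name=name,
        cutoff=float(getattr(net, "cutoff", np.nan)),
        total_nodes=g.number_of_nodes(),
        total_links=g.number_of_edges(),
        n_negative=n_neg, n_positive=n_pos,
        pct_negative=pct_neg, pct_positive=pct_pos,
        powerlaw_r2=r2,
        avgK=avg_degree(net),
        avgCC=avgcc, GD=gd, HD=hd, CD=cd, CB=cb,
        density=density(net),
        transitivity=trans,
        connectedness=connectedness(net),
        n_modules=mods.n_modules,
        modularity=mods.modularity,
        random_null=nulls,
    )
    # cross-check identity D = avgK/(N-1)
    assert abs(summary.density
               - summary.avgK / (summary.total_nodes - 1)) < 1e-9
    return summary


def topology_report(summaries: list[TopologySummary]) -> pd.DataFrame:
    """Table-style report: one column per network, metrics as rows."""
    return pd.DataFrame({s.name: s.to_series() for s in summaries})
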