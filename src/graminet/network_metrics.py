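"""Bipartite network topology, nestedness, attack-tolerance robustness,
vulnerability, and degree-preserving null baselines."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms import bipartite as nx_bipartite

from .core import ValidationError
from .iden import BipartiteNetwork, Edge


@dataclass
class TopologySummary:
    n_plants: int
    n_microbes: int
    n_edges: int
    connectance: float
    mean_degree: float
    avg_clustering: float
    nestedness_nodf: float
    modularity: float | None = None


def topology_summary(net: BipartiteNetwork, with_modularity: bool = False) -> TopologySummary:
    """Connectance L/(m*n), mean degree, Latapy bipartite clustering (dot
    mode), and NODF nestedness."""
    if not net.edges:
        raise ValidationError("empty network")
    m, n = len(net.plant_nodes), len(net.microbe_nodes)
    g = net.to_graph()
    clustering = nx_bipartite.clustering(g, mode="dot")
    modularity = None
    if with_modularity:
        comms = nx.algorithms.community.greedy_modularity_communities(g)
        modularity = nx.algorithms.community.modularity(g, comms)
    return TopologySummary(
        n_plants=m,
        n_microbes=n,
        n_edges=net.n_edges,
        connectance=net.n_edges / (m * n),
        mean_degree=2.0 * net.n_edges / (m + n),
        avg_clustering=float(np.mean(list(clustering.values()))),
        nestedness_nodf=nodf(net),
        modularity=modularity,
    )


def _nodf_axis(mat: np.ndarray) -> list[float]:
    """Paired overlap terms over row pairs of ``mat``."""
    deg = mat.sum(axis=1)
    terms = []
    for i in range(mat.shape[0]):
        for j in range(i + 1, mat.shape[0]):
            hi, lo = (i, j) if deg[i] > deg[j] else (j, i)
            if deg[i] == deg[j] or deg[lo] == 0:
                terms.append(0.0)
            else:
                overlap = np.sum(mat[hi] * mat[lo]) / deg[lo]
                terms.append(100.0 * overlap)
    return terms


def nodf(net: BipartiteNetwork) -> float:
    """NODF nestedness in [0, 100] on the binary incidence matrix.

    Each row pair / column pair contributes 0 when degrees are equal, else
    the percentage of the smaller-degree node's partners shared with the
    larger-degree node; NODF is the mean over all pairs.
    """
    _, _, mat = net.incidence()
    terms = _nodf_axis(mat) + _nodf_axis(mat.T)
    if not terms:
        return 0.0
    return float(np.mean(terms))


@dataclass
class StabilityResult:
    fractions_removed: np.ndarray
    attack_curve: np.ndarray
    robustness: float
    survival_at_half: float
    scheme: str
    vulnerability: float | None = None
    null_distribution: np.ndarray | None = None
    empirical_vs_null_p: float | None = None
    null_degenerate: bool = False


def _surviving_fraction(adj: dict[str, set[str]], removed: set[str], nodes: list[str]) -> float:
    remaining = [v for v in nodes if v not in removed]
    if not remaining:
        return 0.0
    alive = sum(1 for v in remaining if any(u not in removed for u in adj[v]))
    return alive / len(remaining)


def attack_tolerance(
    net: BipartiteNetwork,
    removal: str = "random",
    step: float = 0.05,
    n_rep: int = 100,
    seed: int = 0,
) -> StabilityResult:
    """Attack-tolerance curve and its area-under-curve robustness.

    At each removed fraction the curve records the fraction of remaining
    nodes that still retain at least one edge.  Random removal is averaged
    over ``n_rep`` node orders; degree-descending removal uses the initial
    degree order (deterministic, ties broken by node id).
    """
    nodes = list(net.plant_nodes) + list(net.microbe_nodes)
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for e in net.edges:
        adj[e.plant].add(e.microbe)
        adj[e.microbe].add(e.plant)
    n = len(nodes)
    fractions = np.arange(0.0, 1.0 + step / 2, step)
    rng = np.random.default_rng(seed)
    if removal == "degree_descending":
        orders = [sorted(nodes, key=lambda v: (-len(adj[v]), v))]
    elif removal == "random":
        orders = [list(rng.permutation(nodes)) for _ in range(n_rep)]
    else:
        raise ValueError(f"unknown removal scheme {removal!r}")
    curves = np.zeros((len(orders), len(fractions)))
    for k, order in enumerate(orders):
        for fi, f in enumerate(fractions):
            removed = set(order[: int(round(f * n))])
            curves[k, fi] = _surviving_fraction(adj, removed, nodes)
    curve = curves.mean(axis=0)
    robustness = float(np.trapezoid(curve, fractions))
    at_half = float(curve[np.argmin(np.abs(fractions - 0.5))])
    return StabilityResult(fractions, curve, robustness, at_half, removal)


def vulnerability(net: BipartiteNetwork) -> float:
    """Max relative drop in global efficiency over single-node deletions.

    Efficiency is the mean over unordered node pairs of 1 / shortest path
    length (0 for disconnected pairs), edges unweighted.
    """
    g = net.to_graph()
    if g.number_of_nodes() <= 1:
        return 0.0
    e_full = nx.global_efficiency(g)
    if e_full == 0:
        return 0.0
    worst = 0.0
    for v in list(g.nodes):
        h = g.copy()
        h.remove_node(v)
        if h.number_of_nodes() <= 1:
            e_i = 0.0
        else:
            e_i = nx.global_efficiency(h)
        worst = max(worst, (e_full - e_i) / e_full)
    return float(worst)


def degree_preserving_nulls(net: BipartiteNetwork, n_null: int, seed: int = 0,
                            swap_factor: int = 10) -> tuple[list[BipartiteNetwork], bool]:
    """Checkerboard-swap rewired networks preserving every node degree.

    Returns the ensemble and a flag set when no swap was ever possible (all
    nulls identical to the empirical network).
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    if net.n_edges < 2:
        raise ValidationError("need >= 2 edges to rewire")
    rng = np.random.default_rng(seed)
    nulls = []
    any_swap = False
    for _ in range(n_null):
        pairs = {(e.plant, e.microbe) for e in net.edges}
        edge_list = list(pairs)
        attempts = swap_factor * len(edge_list)
        for _ in range(attempts):
            i, j = rng.integers(0, len(edge_list), size=2)
            (a, b), (c, d) = edge_list[i], edge_list[j]
            if a == c or b == d:
                continue
            if (a, d) in pairs or (c, b) in pairs:
                continue
            pairs.remove((a, b))
            pairs.remove((c, d))
            pairs.add((a, d))
            pairs.add((c, b))
            edge_list[i] = (a, d)
            edge_list[j] = (c, b)
            any_swap = True
        edges = [Edge(p, m, 1.0, 1, {"null"}) for p, m in sorted(pairs)]
        nulls.append(BipartiteNetwork(list(net.plant_nodes), dict(net.microbe_nodes), edges))
    return nulls, not any_swap


def null_model_ensemble(
    net: BipartiteNetwork,
    n_null: int = 100,
    seed: int = 0,
    removal: str = "random",
    step: float = 0.05,
    n_rep: int = 20,
) -> StabilityResult:
    """Empirical robustness against a degree-preserving null ensemble.

    Two-sided permutation p with the +1 convention, capped at 1.
    """
    emp = attack_tolerance(net, removal=removal, step=step, n_rep=n_rep, seed=seed)
    nulls, degenerate = degree_preserving_nulls(net, n_null, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    null_rob = np.array([
        attack_tolerance(nn, removal=removal, step=step, n_rep=n_rep,
                         seed=int(rng.integers(2**31))).robustness
        for nn in nulls
    ])
    ge = (np.sum(null_rob >= emp.robustness) + 1) / (n_null + 1)
    le = (np.sum(null_rob <= emp.robustness) + 1) / (n_null + 1)
    p = min(1.0, 2.0 * min(ge, le))
    return StabilityResult(
        emp.fractions_removed, emp.attack_curve, emp.robustness,
        emp.survival_at_half, removal,
        vulnerability=None,
        null_distribution=null_rob,
        empirical_vs_null_p=float(p),
        null_degenerate=degenerate,
    )
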