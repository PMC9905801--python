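"""Inter-domain network inference.

Pipeline order: compositionality-aware correlation (SparCC) on the stacked
plant + microbe count table -> bootstrap p-values -> |r|/p threshold filter
-> direct-dependency deconvolution on the retained-node submatrix ->
environment / geographic-distance link pruning.

SparCC estimates basis correlations from log-ratio variances under a
sparsity assumption: with t_ij = Var[log(x_i/x_j)] and basis variances w_i^2,
t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j; assuming most rho are ~0, summing
t over partners gives a linear system for the w_i^2, after which
rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j).  Strongly correlated pairs
are excluded from the system and it is re-solved, for a fixed number of
exclusion rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import CountTable, DistanceMatrix, SampleTable, ValidationError
from .network_association import mantel, partial_mantel


# ---------------------------------------------------------------------------
# SparCC core
# ---------------------------------------------------------------------------

def _fractions(counts: np.ndarray, rng: np.random.Generator | None,
               pseudocount: float) -> np.ndarray:
    x = counts.astype(float) + pseudocount
    if rng is None:
        return x / x.sum(axis=1, keepdims=True)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = rng.dirichlet(x[i])
    return out


def _logratio_variance_matrix(frac: np.ndarray) -> np.ndarray:
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return t


def _solve_basis_variances(t: np.ndarray, include: np.ndarray,
                           fallback: np.ndarray | None = None) -> np.ndarray:
    """Solve the sparsity-approximated linear system for basis variances.

    ``include`` is the boolean symmetric matrix of pairs still in the system
    (diagonal False).  With k_i included partners of i:
        sum_j t_ij ~= k_i w_i^2 + sum_{j incl i} w_j^2.

    A non-positive solution means the sparsity assumption failed badly for
    that component; its basis variance falls back to its observed
    log-fraction variance (``fallback``) rather than an arbitrary clip,
    which would send every correlation in its row to +-1.
    """
    k = include.sum(axis=1).astype(float)
    m = include.astype(float)
    m[np.diag_indices_from(m)] = k
    rhs = (t * include).sum(axis=1)
    omega2 = np.linalg.solve(m, rhs)
    bad = omega2 <= 0
    if np.any(bad):
        warnings.warn("negative basis variance; falling back to observed variance")
        if fallback is not None:
            omega2[bad] = fallback[bad]
        else:
            omega2[bad] = np.median(omega2[~bad]) if (~bad).any() else 1.0
    return omega2


def _rho_from_basis(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    om = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(om, om))
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc_single(t: np.ndarray, exclusion_threshold: float = 0.1,
                  exclusion_rounds: int = 10,
                  logfrac_variance: np.ndarray | None = None) -> np.ndarray:
    """One SparCC solve from a log-ratio variance matrix ``t``."""
    d = t.shape[0]
    if d < 3:
        raise ValidationError("SparCC needs >= 3 components")
    include = ~np.eye(d, dtype=bool)
    omega2 = _solve_basis_variances(t, include, logfrac_variance)
    rho = _rho_from_basis(t, omega2)
    for _ in range(exclusion_rounds):
        cand = np.abs(np.triu(rho, k=1)) * np.triu(include, k=1)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        if include.sum(axis=1).min() < 2:
            break  # system would become under-determined for some component
        omega2 = _solve_basis_variances(t, include, logfrac_variance)
        rho = _rho_from_basis(t, omega2)
    return rho


def sparcc(
    counts: np.ndarray,
    n_inner: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    seed: int = 0,
    resample: bool = True,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Full SparCC correlation matrix for a sample x component count matrix.

    Each inner iteration resamples fractions from a Dirichlet posterior
    (``resample=False`` uses point-estimate fractions, which makes the
    estimate exactly invariant to per-sample count rescaling when
    ``pseudocount=0``); the returned matrix is the elementwise median over
    iterations.
    """
    counts = np.asarray(counts)
    if counts.shape[0] < 4:
        raise ValidationError("SparCC needs >= 4 samples")
    if counts.shape[1] < 3:
        raise ValidationError("SparCC needs >= 3 components")
    rng = np.random.default_rng(seed) if resample else None
    rhos = []
    for _ in range(max(1, n_inner) if resample else 1):
        frac = _fractions(counts, rng, pseudocount)
        t = _logratio_variance_matrix(frac)
        v = np.log(frac).var(axis=0, ddof=1)
        rhos.append(sparcc_single(t, exclusion_threshold, exclusion_rounds, v))
    return np.median(rhos, axis=0)


# ---------------------------------------------------------------------------
# Association matrix over plant x microbe blocks
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    """Cross-domain correlation block plus the full square matrix it came
    from (needed for path-transitive deconvolution)."""

    row_taxa: list[str]             # plant species
    col_taxa: list[str]             # microbial taxa
    r: np.ndarray                   # (rows x cols) cross-domain correlations
    components: list[str]           # all stacked component labels
    full_r: np.ndarray              # (D x D) correlation over all components
    domains: dict[str, str]         # taxon -> domain
    samples: list[str]
    counts: np.ndarray              # stacked counts (samples x D)
    p: np.ndarray | None = None
    direct: np.ndarray | None = None  # cross-block direct strengths
    full_direct: np.ndarray | None = None
    n_iterations: int = 0
    n_bootstraps: int = 0
    seed: int = 0

    def validate(self) -> None:
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValidationError("|r| must be <= 1")
        if self.p is not None and (np.any(self.p < 0) or np.any(self.p > 1)):
            raise ValidationError("p must be in [0, 1]")


def _equalise_rows(counts: np.ndarray) -> np.ndarray:
    """Rescale every row to the block's median row total.

    Stacking blocks whose library sizes vary independently would make the
    block-to-block total ratio fluctuate across samples, which shows up as a
    spurious negative correlation between every cross-block pair.  Fixing
    each block's per-sample total (as rarefying to a common depth would)
    removes that artifact while leaving within-block composition untouched.
    """
    totals = counts.sum(axis=1, keepdims=True)
    target = float(np.median(totals))
    return np.rint(counts / totals * target).astype(np.int64)


def stack_tables(plant: CountTable, microbes: list[CountTable]) -> tuple[
        np.ndarray, list[str], list[str], list[str], dict[str, str]]:
    """Align plant and microbe tables to their common samples and stack
    columns; returns (counts, samples, plant_taxa, microbe_taxa, domains).

    Each block is row-normalised to a constant per-sample total first (see
    ``_equalise_rows``).
    """
    common: set[str] = set(plant.samples)
    for t in microbes:
        common &= set(t.samples)
    if len(common) < 4:
        raise ValidationError("fewer than 4 shared samples")
    order = sorted(common)
    blocks = [_equalise_rows(plant.select_samples(order).counts)]
    domains = {t: "grass" for t in plant.taxa}
    microbe_taxa: list[str] = []
    for t in microbes:
        blocks.append(_equalise_rows(t.select_samples(order).counts))
        for tax in t.taxa:
            if tax in domains:
                raise ValidationError(f"duplicate taxon id across tables: {tax}")
            domains[tax] = t.domain
        microbe_taxa.extend(t.taxa)
    counts = np.hstack(blocks)
    return counts, order, list(plant.taxa), microbe_taxa, domains


def sparcc_correlation(
    plant: CountTable,
    microbes: list[CountTable],
    n_inner: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    seed: int = 0,
    resample: bool = True,
    pseudocount: float = 1.0,
) -> AssociationMatrix:
    """SparCC over the stacked plant + microbe table; cross-domain block
    extracted into ``r``."""
    counts, order, row_taxa, col_taxa, domains = stack_tables(plant, microbes)
    full = sparcc(counts, n_inner, exclusion_threshold, exclusion_rounds,
                  seed, resample, pseudocount)
    components = row_taxa + col_taxa
    nr = len(row_taxa)
    r = full[:nr, nr:]
    am = AssociationMatrix(
        row_taxa=row_taxa, col_taxa=col_taxa, r=r, components=components,
        full_r=full, domains=domains, samples=order, counts=counts,
        n_iterations=n_inner, seed=seed,
    )
    am.validate()
    return am


def bootstrap_pvalues(
    am: AssociationMatrix,
    n_boot: int = 100,
    seed: int = 0,
    n_inner: int | None = None,
) -> AssociationMatrix:
    """Permutation-bootstrap two-sided p-values for every association.

    Each bootstrap independently permutes every component's counts across
    samples (destroying all dependence while keeping marginals), recomputes
    SparCC, and compares |r_boot| with |r_observed|.
    """
    if n_boot < 20:
        warnings.warn("n_boot < 20 gives poor p-value resolution")
    inner = am.n_iterations if n_inner is None else n_inner
    rng = np.random.default_rng(seed)
    nr = len(am.row_taxa)
    exceed = np.zeros_like(am.r)
    abs_obs = np.abs(am.full_r[:nr, nr:])
    for _ in range(n_boot):
        perm_counts = np.empty_like(am.counts)
        for j in range(am.counts.shape[1]):
            perm_counts[:, j] = rng.permutation(am.counts[:, j])
        rb = sparcc(perm_counts, inner, seed=int(rng.integers(2**31)))
        exceed += np.abs(rb[:nr, nr:]) >= abs_obs
    p = (exceed + 1.0) / (n_boot + 1.0)
    out = replace(am, p=p, n_bootstraps=n_boot)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Bipartite network
# ---------------------------------------------------------------------------

@dataclass
class Edge:
    plant: str
    microbe: str
    weight: float
    sign: int
    flags: set[str] = field(default_factory=set)


@dataclass
class BipartiteNetwork:
    plant_nodes: list[str]
    microbe_nodes: dict[str, str]   # node -> domain
    edges: list[Edge]

    def validate(self) -> None:
        pset, mset = set(self.plant_nodes), set(self.microbe_nodes)
        if pset & mset:
            raise ValidationError("node appears in both partitions")
        for e in self.edges:
            if e.plant not in pset or e.microbe not in mset:
                raise ValidationError(f"edge endpoints outside node sets: {e}")
            if e.weight == 0:
                raise ValidationError("retained edges must have nonzero weight")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {n: 0 for n in list(self.plant_nodes) + list(self.microbe_nodes)}
        for e in self.edges:
            deg[e.plant] += 1
            deg[e.microbe] += 1
        return deg

    def prune_isolated(self) -> "BipartiteNetwork":
        deg = self.degrees()
        plants = [n for n in self.plant_nodes if deg[n] > 0]
        microbes = {n: d for n, d in self.microbe_nodes.items() if deg[n] > 0}
        return BipartiteNetwork(plants, microbes, list(self.edges))

    def incidence(self) -> tuple[list[str], list[str], np.ndarray]:
        plants = list(self.plant_nodes)
        microbes = list(self.microbe_nodes)
        mat = np.zeros((len(plants), len(microbes)), dtype=int)
        pi = {p: i for i, p in enumerate(plants)}
        mi = {m: i for i, m in enumerate(microbes)}
        for e in self.edges:
            mat[pi[e.plant], mi[e.microbe]] = 1
        return plants, microbes, mat

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for p in self.plant_nodes:
            g.add_node(p, bipartite=0, domain="grass")
        for m, dom in self.microbe_nodes.items():
            g.add_node(m, bipartite=1, domain=dom)
        for e in self.edges:
            g.add_edge(e.plant, e.microbe, weight=e.weight, sign=e.sign,
                       flags=",".join(sorted(e.flags)))
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plant": e.plant,
                "microbe": e.microbe,
                "domain": self.microbe_nodes[e.microbe],
                "weight": e.weight,
                "sign": e.sign,
                "flags": ",".join(sorted(e.flags)),
            }
            for e in self.edges
        ]
        return pd.DataFrame(rows, columns=["plant", "microbe", "domain", "weight", "sign", "flags"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)

    def write_edges(self, path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)


def filter_associations(
    am: AssociationMatrix,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
) -> BipartiteNetwork:
    """Keep associations with |r| >= r_threshold AND p < p_threshold; nodes
    with no retained edge are excluded."""
    if am.p is None:
        raise ValidationError("p-values required; run bootstrap_pvalues first")
    edges = []
    for i, plant in enumerate(am.row_taxa):
        for j, microbe in enumerate(am.col_taxa):
            r = am.r[i, j]
            if abs(r) >= r_threshold and am.p[i, j] < p_threshold:
                edges.append(Edge(plant, microbe, float(r), int(np.sign(r)), {"filtered_in"}))
    net = BipartiteNetwork(
        list(am.row_taxa),
        {t: am.domains[t] for t in am.col_taxa},
        edges,
    ).prune_isolated()
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Direct-dependency deconvolution
# ---------------------------------------------------------------------------

def _bounded_matmul(s: np.ndarray, g: np.ndarray, cap: float) -> np.ndarray:
    """Two-step path influence S.G with the bounded parallel combination.

    Series influence along i-k-j is the product s_ik * g_kj; contributions
    over intermediates k combine with u (+) v = (u + v) / (1 + u v), which
    is addition in artanh space, so the combined influence stays in (-1, 1):
        (S.G)_ij = tanh( sum_k artanh(s_ik * g_kj) ).
    """
    d = s.shape[0]
    out = np.zeros((d, d))
    # chunk over intermediates to bound the D^3 temporary
    chunk = max(1, int(4e6 // (d * d)) or 1)
    for k0 in range(0, d, chunk):
        prod = s[:, k0:k0 + chunk, None] * g[None, k0:k0 + chunk, :]
        out += np.arctanh(np.clip(prod, -cap, cap)).sum(axis=1)
    # associations are undirected: average the i->k->j and j->k->i sums
    out = (out + out.T) / 2.0
    return np.tanh(out)


def idirect(total: np.ndarray, tol: float = 1e-6, max_iter: int = 100,
            damping: float = 0.5) -> tuple[np.ndarray, bool]:
    """Solve G = S (+) (S.G) for the direct-strength matrix S.

    Series influence along a path multiplies edge strengths; parallel
    contributions combine with the bounded operator
    u (+) v = (u + v) / (1 + u v) (artanh-additive, see ``_bounded_matmul``).
    Damped fixed-point iteration from S0 = G; output clipped to (-1, 1).
    """
    cap = 1.0 - 1e-9
    input_cap = 0.98  # keep artanh finite for near-unit correlations
    g = np.clip(np.asarray(total, dtype=float), -input_cap, input_cap)
    np.fill_diagonal(g, 0.0)
    s = g.copy()
    converged = False
    for _ in range(max_iter):
        sg = _bounded_matmul(s, g, input_cap)
        np.fill_diagonal(sg, 0.0)
        s_new = (g - sg) / (1.0 - g * sg)
        np.fill_diagonal(s_new, 0.0)
        s_new = np.clip(s_new, -cap, cap)
        s_next = damping * s_new + (1.0 - damping) * s
        delta = np.max(np.abs(s_next - s))
        s = s_next
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("iDIRECT fixed point did not converge; returning last iterate")
    return s, converged


def idirect_deconvolve(am: AssociationMatrix, retained_nodes: list[str] | None = None,
                       **kwargs) -> AssociationMatrix:
    """Deconvolve the association matrix (restricted to retained nodes) into
    direct strengths; cross-domain direct block stored in ``direct``."""
    nodes = list(am.components) if retained_nodes is None else list(retained_nodes)
    idx = [am.components.index(n) for n in nodes]
    sub = am.full_r[np.ix_(idx, idx)]
    s, _ = idirect(sub, **kwargs)
    full_direct = np.zeros_like(am.full_r)
    full_direct[np.ix_(idx, idx)] = s
    nr = len(am.row_taxa)
    out = replace(am, direct=full_direct[:nr, nr:], full_direct=full_direct)
    return out


def apply_deconvolution(net: BipartiteNetwork, am: AssociationMatrix,
                        r_threshold: float = 0.3) -> BipartiteNetwork:
    """Replace edge weights with direct strengths; edges whose direct
    strength drops below the filter threshold are removed."""
    if am.direct is None:
        raise ValidationError("run idirect_deconvolve first")
    ri = {t: i for i, t in enumerate(am.row_taxa)}
    ci = {t: j for j, t in enumerate(am.col_taxa)}
    edges = []
    for e in net.edges:
        d = float(am.direct[ri[e.plant], ci[e.microbe]])
        if abs(d) >= r_threshold:
            edges.append(Edge(e.plant, e.microbe, d, int(np.sign(d)),
                              e.flags | {"deconvolved"}))
    out = BipartiteNetwork(list(net.plant_nodes), dict(net.microbe_nodes), edges).prune_isolated()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Environmental / geographic link pruning
# ---------------------------------------------------------------------------

def _partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial rank correlation of x and y controlling z."""
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    design = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.std(res_x) == 0 or np.std(res_y) == 0:
        return 0.0
    return float(np.corrcoef(res_x, res_y)[0, 1])


def lted_prune(
    net: BipartiteNetwork,
    tables: dict[str, CountTable],
    frame: SampleTable,
    geo_dm: DistanceMatrix,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    env_variables: list[str] | None = None,
    position_screen: bool = True,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[BipartiteNetwork, pd.DataFrame]:
    """Remove edges attributable to shared environmental filtering or to
    dispersal limitation (geographic position / distance).

    An edge is pruned on a screening variable when both endpoints correlate
    with it significantly, the product of those correlation signs matches
    the sign of the edge (i.e. the shared driver would produce an
    association of the observed sign), AND the endpoints' partial
    correlation controlling that variable falls below the filter threshold.
    With ``position_screen`` the geographic coordinates are screened the
    same way (dispersal limitation on a transect); a partial Mantel of the
    endpoints' abundance-difference matrices controlling geographic
    distance backs this up for structure the coordinates miss.  Every
    pruned edge is logged with the triggering variable.
    """
    if not net.edges:
        return net, pd.DataFrame(columns=["plant", "microbe", "trigger"])
    if env_variables is None:
        env_variables = [c for c in ("pH", "CEC", "OM", "TN", "TP", "TC", "SMC", "MAT", "altitude")
                         if c in frame.data.columns]
    if position_screen:
        env_variables = list(env_variables) + [
            c for c in ("latitude", "longitude") if c in frame.data.columns]
    grass = tables["grass"]
    log_rows = []
    kept: list[Edge] = []
    rng = np.random.default_rng(seed)
    rel_cache: dict[str, tuple[list[str], dict[str, np.ndarray]]] = {}

    def rel_vector(domain: str, taxon: str) -> tuple[list[str], np.ndarray]:
        table = grass if domain == "grass" else tables[domain]
        if domain not in rel_cache:
            rel = table.relative_abundance()
            rel_cache[domain] = (table.samples, {t: rel[:, j] for j, t in enumerate(table.taxa)})
        samples, cols = rel_cache[domain]
        return samples, cols[taxon]

    for e in net.edges:
        p_samples, p_ab = rel_vector("grass", e.plant)
        m_dom = net.microbe_nodes[e.microbe]
        m_samples, m_ab = rel_vector(m_dom, e.microbe)
        common = sorted(set(p_samples) & set(m_samples) & set(frame.samples) & set(geo_dm.labels))
        pi = [p_samples.index(s) for s in common]
        mi = [m_samples.index(s) for s in common]
        a = p_ab[pi]
        b = m_ab[mi]
        trigger = None
        for var in env_variables:
            if var not in frame.data.columns:
                warnings.warn(f"environmental variable {var!r} missing; skipped")
                continue
            v = frame.data.loc[common, var].to_numpy(dtype=float)
            if np.std(v) == 0 or np.std(a) == 0 or np.std(b) == 0:
                continue
            ra, pa = stats.spearmanr(a, v)
            rb, pb = stats.spearmanr(b, v)
            if (pa < p_threshold and pb < p_threshold
                    and np.sign(ra) * np.sign(rb) == np.sign(e.weight)):
                if abs(_partial_spearman(a, b, v)) < r_threshold:
                    trigger = var
                    break
        if trigger is None:
            # geographic test: partial Mantel of abundance differences | distance
            da = DistanceMatrix(common, np.abs(a[:, None] - a[None, :]), "abundance_diff")
            db = DistanceMatrix(common, np.abs(b[:, None] - b[None, :]), "abundance_diff")
            geo = geo_dm.select(common)
            sa = int(rng.integers(2**31))
            sb = int(rng.integers(2**31))
            sc = int(rng.integers(2**31))
            ma = mantel(da, geo, n_perm=n_perm, seed=sa)
            mb = mantel(db, geo, n_perm=n_perm, seed=sb)
            if (
                not ma.degenerate and not mb.degenerate
                and ma.p < p_threshold and mb.p < p_threshold
                and ma.r > 0 and mb.r > 0
            ):
                pm = partial_mantel(da, db, geo, n_perm=1, seed=sc)
                if not np.isnan(pm.r) and abs(pm.r) < r_threshold:
                    trigger = "geographic_distance"
        if trigger is None:
            kept.append(e)
        else:
            log_rows.append({"plant": e.plant, "microbe": e.microbe, "trigger": trigger})
            pruned = Edge(e.plant, e.microbe, e.weight, e.sign, e.flags | {"lted_pruned"})
            # pruned edges are removed from the network but logged
    out = BipartiteNetwork(list(net.plant_nodes), dict(net.microbe_nodes), kept).prune_isolated()
    out.validate()
    return out, pd.DataFrame(log_rows, columns=["plant", "microbe", "trigger"])


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class IdenArtifacts:
    association: AssociationMatrix
    filtered: BipartiteNetwork
    deconvolved: BipartiteNetwork
    pruned: BipartiteNetwork
    prune_log: pd.DataFrame


def build_iden(
    plant: CountTable,
    microbes: list[CountTable],
    frame: SampleTable,
    geo_dm: DistanceMatrix,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    deconv_threshold: float = 0.3,
    lted_r_threshold: float = 0.3,
    n_inner: int = 20,
    n_boot: int = 100,
    n_inner_boot: int = 5,
    seed: int = 0,
    lted: bool = True,
    env_variables: list[str] | None = None,
) -> IdenArtifacts:
    """Run the full inference chain and return every intermediate.

    ``r_threshold`` applies to the initial correlation filter;
    ``deconv_threshold`` and ``lted_r_threshold`` are the cutoffs used for
    the deconvolved direct strengths and the partial-correlation screen.
    """
    am = sparcc_correlation(plant, microbes, n_inner=n_inner, seed=seed)
    am = bootstrap_pvalues(am, n_boot=n_boot, seed=seed + 1, n_inner=n_inner_boot)
    filtered = filter_associations(am, r_threshold, p_threshold)
    retained = list(filtered.plant_nodes) + list(filtered.microbe_nodes)
    if retained:
        am = idirect_deconvolve(am, retained)
        deconvolved = apply_deconvolution(filtered, am, deconv_threshold)
    else:
        deconvolved = filtered
    if lted and deconvolved.edges:
        tables = {"grass": plant, **{t.domain: t for t in microbes}}
        pruned, log = lted_prune(
            deconvolved, tables, frame, geo_dm, lted_r_threshold, p_threshold,
            env_variables=env_variables, seed=seed + 2,
        )
    else:
        pruned, log = deconvolved, pd.DataFrame(columns=["plant", "microbe", "trigger"])
    return IdenArtifacts(am, filtered, deconvolved, pruned, log)
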