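"""Benchmark harness: planted-truth recovery, statistical calibration, and
qualitative-structure checks on the synthetic generator.

These are the routines behind the acceptance checks; they run the public
pipeline pieces end to end on seeded generator output and summarise how well
the planted structure is recovered.  Everything is deterministic given the
seed arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import CountTable, DistanceMatrix
from .distance_decay import (
    fit_ddr, geographic_distance_matrix, variable_divergence_matrix,
)
from .diversity import alpha_diversity, bray_curtis_matrix
from .group_stats import permanova
from .iden import build_iden, sparcc
from .network_association import partial_mantel, sample_connectivity_profile, mantel
from .network_metrics import null_model_ensemble
from .simulate import GeneratorConfig, simulate_bundle, truth_network
from .variance_partition import vpa_three_way

TEST_TAXA = {"archaea": 40, "bacteria": 60, "fungi": 50}

# inference settings for the link-recovery benchmark; the correlation filter
# threshold is raised above the pipeline default because with n=48 samples
# the sampling noise floor of the correlation estimate makes |r|>=0.3 too
# permissive to measure precision against a handful of planted links
RECOVERY_KW = dict(n_inner=10, n_boot=80, n_inner_boot=3, r_threshold=0.5)


@dataclass
class RecoveryResult:
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    all_positive: list[bool] = field(default_factory=list)

    @property
    def mean_precision(self) -> float:
        return float(np.nanmean(self.precision)) if self.precision else float("nan")

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall)) if self.recall else float("nan")


def iden_link_recovery(seeds=range(10)) -> RecoveryResult:
    """Full inference chain on the link-recovery preset; precision/recall of
    planted direct links and the sign of every retained edge."""
    out = RecoveryResult()
    for seed in seeds:
        cfg = GeneratorConfig.link_recovery(seed)
        bundle = simulate_bundle(cfg)
        geo = geographic_distance_matrix(bundle.frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            art = build_iden(bundle.grass, [bundle.microbes["archaea"]],
                             bundle.frame, geo, seed=seed, **RECOVERY_KW)
        truth = {(g, m) for g, m, _, _ in bundle.truth.direct_links}
        pred = {(e.plant, e.microbe) for e in art.pruned.edges}
        tp = len(truth & pred)
        out.precision.append(tp / len(pred) if pred else float("nan"))
        out.recall.append(tp / len(truth))
        out.all_positive.append(bool(pred) and all(e.sign > 0 for e in art.pruned.edges))
    return out


def ddr_slope_recovery(seeds=range(10)) -> dict[str, float]:
    """Mean fitted/planted slope ratio per organism group on the
    turnover-only reference generator."""
    ratios: dict[str, list[float]] = {}
    for seed in seeds:
        cfg = GeneratorConfig.turnover_reference(
            seed, n_grass_species=24, n_taxa=dict(TEST_TAXA))
        bundle = simulate_bundle(cfg)
        geo = geographic_distance_matrix(bundle.frame)
        for dom, table in bundle.all_tables().items():
            fit = fit_ddr(bray_curtis_matrix(table), geo, organism_group=dom, n_perm=0)
            ratios.setdefault(dom, []).append(
                fit.slope / bundle.truth.ddr_slopes_per_km[dom])
    return {dom: float(np.mean(v)) for dom, v in ratios.items()}


def ddr_ordering(seeds=range(10)) -> float:
    """Fraction of seeds on default-shaped data with the planted slope
    ordering (grass steepest, fungi shallowest)."""
    ok = 0
    for seed in seeds:
        cfg = GeneratorConfig(seed=seed, n_taxa=dict(TEST_TAXA), n_grass_species=24)
        bundle = simulate_bundle(cfg)
        geo = geographic_distance_matrix(bundle.frame)
        slopes = {dom: fit_ddr(bray_curtis_matrix(t), geo, n_perm=0).slope
                  for dom, t in bundle.all_tables().items()}
        micro = [slopes["archaea"], slopes["bacteria"], slopes["fungi"]]
        if slopes["grass"] > max(micro) and slopes["fungi"] < min(
                slopes["grass"], slopes["archaea"], slopes["bacteria"]):
            ok += 1
    return ok / len(list(seeds))


def vpa_ordering(seeds=range(10), domain: str = "bacteria") -> float:
    """Fraction of seeds recovering unique-fraction ordering
    productivity > soil > diversity."""
    ok = 0
    for seed in seeds:
        cfg = GeneratorConfig(seed=seed, n_taxa=dict(TEST_TAXA), n_grass_species=24)
        bundle = simulate_bundle(cfg)
        frame = bundle.frame
        galpha = alpha_diversity(bundle.grass)
        prod = frame.data[["CD", "DB", "S"]].astype(float)
        soil = frame.data[["pH", "TN", "TP", "SMC"]].astype(float)
        div = galpha[["margalef", "shannon", "pielou"]].fillna(0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = vpa_three_way(bundle.microbes[domain], prod, div, soil,
                                names=("productivity", "diversity", "soil"))
        if res.unique["a"] > res.unique["c"] > res.unique["b"]:
            ok += 1
    return ok / len(list(seeds))


def vpa_total_explained(seed: int = 0) -> dict[str, float]:
    """Jointly explained inertia fraction per microbial domain (percent)."""
    cfg = GeneratorConfig(seed=seed, n_taxa=dict(TEST_TAXA), n_grass_species=24)
    bundle = simulate_bundle(cfg)
    frame = bundle.frame
    galpha = alpha_diversity(bundle.grass)
    prod = frame.data[["CD", "DB", "S"]].astype(float)
    soil = frame.data[["pH", "TN", "TP", "SMC"]].astype(float)
    div = galpha[["margalef", "shannon", "pielou"]].fillna(0.0)
    out = {}
    for dom, table in bundle.microbes.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = vpa_three_way(table, prod, div, soil)
        out[dom] = 100.0 * res.total_explained
    return out


def robustness_vs_null(seeds=range(10), n_null: int = 30) -> float:
    """Fraction of seeds where the planted (hub + redundant-satellite)
    network is more robust under degree-targeted attack than its
    degree-preserving nulls."""
    ok = 0
    for seed in seeds:
        cfg = GeneratorConfig.link_recovery(
            seed, link_pattern="hub_satellite", n_per_domain=40, link_density=0.4)
        bundle = simulate_bundle(cfg)
        net = truth_network(bundle)
        res = null_model_ensemble(net, n_null=n_null, seed=seed,
                                  removal="degree_descending", n_rep=1)
        if res.robustness > float(np.mean(res.null_distribution)):
            ok += 1
    return ok / len(list(seeds))


def connectivity_productivity_mantel(seeds=range(10), n_perm: int = 199) -> float:
    """Fraction of seeds with a significantly positive partial Mantel r
    between network connectivity and productivity divergence (geographic and
    soil divergence partialled out), on a generator where productivity
    genuinely drives network-member abundance."""
    ok = 0
    for seed in seeds:
        cfg = GeneratorConfig(seed=seed, n_grass_species=16, n_taxa={"archaea": 30},
                              link_density=0.3, link_mass=0.15,
                              connectivity_productivity_coef=1.2)
        bundle = simulate_bundle(cfg)
        net = truth_network(bundle)
        _, conn_dm = sample_connectivity_profile(
            net, [bundle.grass, bundle.microbes["archaea"]])
        frame = bundle.frame.select_samples(conn_dm.labels)
        geo = geographic_distance_matrix(frame)
        prod_dm = variable_divergence_matrix(frame, ["CD", "DB"])
        soil_dm = variable_divergence_matrix(frame, ["pH", "TN", "TP", "SMC"])
        res = partial_mantel(conn_dm, prod_dm, [geo, soil_dm],
                             n_perm=n_perm, seed=seed)
        if res.r > 0 and res.p < 0.05:
            ok += 1
    return ok / len(list(seeds))


# ---------------------------------------------------------------------------
# type-I error calibration
# ---------------------------------------------------------------------------

def _random_euclidean_dm(rng, n, dims=2):
    pts = rng.normal(size=(n, dims))
    return DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(pts)), "euclidean")


def permanova_type1(n_seeds: int = 200, n: int = 12, n_perm: int = 99) -> float:
    rej = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        dm = _random_euclidean_dm(rng, n, 3)
        groups = np.repeat(["a", "b", "c"], n // 3)
        if permanova(dm, groups, n_perm=n_perm, seed=seed + 10_000).p_value < 0.05:
            rej += 1
    return rej / n_seeds


def mantel_type1(n_seeds: int = 200, n: int = 12, n_perm: int = 99) -> float:
    rej = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        da = _random_euclidean_dm(rng, n)
        db = _random_euclidean_dm(rng, n)
        if mantel(da, db, n_perm=n_perm, seed=seed + 20_000).p < 0.05:
            rej += 1
    return rej / n_seeds


def partial_mantel_type1(n_seeds: int = 200, n: int = 12, n_perm: int = 99) -> float:
    rej = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        da = _random_euclidean_dm(rng, n)
        db = _random_euclidean_dm(rng, n)
        dc = _random_euclidean_dm(rng, n)
        if partial_mantel(da, db, dc, n_perm=n_perm, seed=seed + 30_000).p < 0.05:
            rej += 1
    return rej / n_seeds


def sparcc_filter_type1(n_seeds: int = 200, n: int = 30, d: int = 8,
                        n_boot: int = 60) -> float:
    """False-edge rate of the |r| >= 0.3 & p < 0.05 filter on independent
    compositional data."""
    edges = total = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        base = np.exp(rng.normal(0, 1, (n, d)) + rng.normal(2, 0.5, d))
        frac = base / base.sum(axis=1, keepdims=True)
        counts = np.array([rng.multinomial(5000, f) for f in frac])
        r = sparcc(counts, n_inner=2, seed=seed)
        exceed = np.zeros((d, d))
        for b in range(n_boot):
            perm = np.empty_like(counts)
            for j in range(d):
                perm[:, j] = rng.permutation(counts[:, j])
            rb = sparcc(perm, n_inner=1, seed=seed * 1009 + b)
            exceed += np.abs(rb) >= np.abs(r)
        p = (exceed + 1.0) / (n_boot + 1.0)
        iu = np.triu_indices(d, 1)
        edges += int(np.sum((np.abs(r[iu]) >= 0.3) & (p[iu] < 0.05)))
        total += len(iu[0])
    return edges / total
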