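"""Study-shaped synthetic data with planted ground truth.

Design
------
Samples sit on a linear transect.  Community turnover is generated by a
"moving window" composition: each domain's core taxa are laid out on an
abundance axis and every sample puts uniform mass on a window whose centre
drifts linearly with transect position.  Two boxcar compositions of equal
width ``w`` whose centres differ by ``delta`` have Bray-Curtis dissimilarity
``delta / w`` (until saturation), so the planted distance-decay slope is
exact: slope = drift_rate / width, configured per domain.

On top of the window core:
  * a small pool of rare grass species whose per-sample presence count
    follows the metadata species-richness variable S (plants a diversity
    signal without disturbing the turnover slope);
  * "linked" microbes whose latent abundance tracks one grass species'
    relative abundance (the planted direct associations);
  * "environment-driven" microbes responding to metadata variables, with
    block weights (productivity > soil > diversity by default) planting the
    variance-partitioning ordering.

Counts are drawn multinomially from noisy expected compositions with
lognormal library sizes, so the data are genuinely compositional.  A single
master seed drives every stochastic sub-step through spawned child
generators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountTable, SampleTable, ValidationError

# Per-grassland-type environmental means and SDs (soil chemistry, grass
# biophysics, temperature, altitude) used to draw the landscape.
TYPE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "ASM": {
        "pH": (7.21, 0.57), "CEC": (25.51, 14.59), "OM": (86.05, 22.55),
        "TN": (3.40, 1.26), "TP": (0.57, 0.22), "TC": (5.30, 1.55),
        "SMC": (50.75, 18.72), "H": (11.49, 4.16), "CD": (93.00, 11.91),
        "S": (9.67, 2.25), "FB": (388.13, 223.69), "DB": (187.20, 111.52),
        "MAT": (-0.47, 0.93), "altitude": (4445.67, 234.42),
    },
    "AM": {
        "pH": (7.02, 0.58), "CEC": (27.09, 15.94), "OM": (131.30, 75.35),
        "TN": (4.35, 1.58), "TP": (0.73, 0.12), "TC": (8.55, 4.62),
        "SMC": (30.31, 11.39), "H": (4.18, 2.73), "CD": (76.75, 11.74),
        "S": (11.92, 5.08), "FB": (361.10, 263.06), "DB": (124.70, 76.41),
        "MAT": (-0.19, 0.75), "altitude": (4187.58, 122.47),
    },
    "AS": {
        "pH": (8.07, 0.11), "CEC": (6.60, 3.99), "OM": (44.43, 25.66),
        "TN": (1.84, 1.06), "TP": (0.43, 0.09), "TC": (3.55, 1.59),
        "SMC": (14.45, 7.52), "H": (8.14, 8.40), "CD": (55.44, 15.56),
        "S": (6.56, 1.54), "FB": (216.49, 227.82), "DB": (107.80, 85.87),
        "MAT": (0.34, 1.69), "altitude": (4014.89, 390.24),
    },
    "TS": {
        "pH": (8.12, 0.17), "CEC": (11.94, 2.32), "OM": (46.25, 15.50),
        "TN": (2.55, 1.50), "TP": (0.71, 0.04), "TC": (3.31, 0.85),
        "SMC": (15.26, 11.83), "H": (20.49, 5.09), "CD": (49.25, 20.76),
        "S": (5.42, 2.67), "FB": (266.03, 151.47), "DB": (136.73, 58.73),
        "MAT": (3.66, 0.20), "altitude": (3232.25, 67.45),
    },
}

# sites per type along the transect, highest to lowest altitude
TYPE_SITE_SHARE = (("ASM", 2), ("AM", 4), ("AS", 6), ("TS", 4))

_CLIP = {
    "pH": (4.0, 10.0), "CEC": (0.1, None), "OM": (1.0, None),
    "TN": (0.05, None), "TP": (0.01, None), "TC": (0.1, None),
    "SMC": (1.0, 100.0), "H": (0.5, None), "CD": (1.0, 100.0),
    "S": (1.0, None), "FB": (5.0, None), "DB": (2.0, None),
    "MAT": (None, None), "altitude": (100.0, None),
}

_TRANSECT_ORIGIN_LAT = 33.202
_TRANSECT_LON = 98.0
_KM_PER_DEG_LAT = 6371.0 * np.pi / 180.0


@dataclass
class GeneratorConfig:
    seed: int
    n_sites: int = 16
    replicates_per_site: int = 3
    n_grass_species: int = 30
    n_taxa: dict[str, int] = field(
        default_factory=lambda: {"archaea": 150, "bacteria": 600, "fungi": 300}
    )
    transect_length_km: float = 2121.0
    library_size_median: dict[str, int] = field(
        default_factory=lambda: {"grass": 20000, "archaea": 20828,
                                 "bacteria": 20828, "fungi": 10140}
    )
    library_size_sigma: float = 0.15
    noise_scale: float = 0.5
    link_density: float = 0.10
    link_strength: float = 1.5
    positive_links_only: bool = True
    env_fraction: float = 0.15
    env_strength: float = 1.6
    niche_breadth_scale: float = 1.0
    link_mass: float = 0.04           # community mass share of linked taxa
    env_mass: float = 0.12            # community mass share of env-driven taxa
    rare_mass_per_species: float = 0.002
    # km shift of the effective community position per SD of productivity:
    # lets grass stand structure (CD/DB) leave a unique imprint on microbial
    # composition beyond the shared transect gradient
    productivity_coupling_km: float = 0.0
    # same idea applied to the grass community itself: a nonzero value makes
    # grass composition (and hence any planted grass-microbe network) respond
    # to stand productivity beyond the shared transect gradient
    grass_productivity_coupling_km: float = 0.0
    # 'distinct': one host per linked microbe; 'hub_satellite': a shared
    # hub host plus a distinct satellite host per microbe
    link_pattern: str = "distinct"
    # nonzero: linked microbes' latent abundance is additionally multiplied
    # by exp(coef * z(CD)), planting a direct productivity -> network-member
    # abundance (connectivity) response
    connectivity_productivity_coef: float = 0.0
    # planted Bray-Curtis turnover per 1000 km
    ddr_slopes_per_1000km: dict[str, float] = field(
        default_factory=lambda: {"grass": 0.108, "archaea": 0.054,
                                 "bacteria": 0.036, "fungi": 0.017}
    )
    vpa_weights: dict[str, float] = field(
        default_factory=lambda: {"productivity": 0.5, "soil": 0.3, "diversity": 0.2}
    )

    @classmethod
    def turnover_reference(cls, seed: int, **overrides) -> "GeneratorConfig":
        """Turnover-only preset: no planted links or environmental taxa and
        low compositional noise, so fitted distance-decay slopes can be
        compared against the planted rates without shrinkage from the
        noise-induced dissimilarity baseline."""
        params = {"link_density": 0.0, "env_fraction": 0.0, "noise_scale": 0.05}
        params.update(overrides)
        return cls(seed=seed, **params)

    @classmethod
    def link_recovery(cls, seed: int, domains: tuple[str, ...] = ("archaea",),
                      n_per_domain: int = 30, **overrides) -> "GeneratorConfig":
        """Preset for direct-link recovery benchmarks: default landscape,
        a compact taxon set with a high planted-link density, and spatial
        turnover damped enough that direct associations are identifiable
        against the shared transect gradient."""
        params: dict = {
            "n_grass_species": 16,
            "n_taxa": {d: n_per_domain for d in domains},
            "ddr_slopes_per_1000km": {"grass": 0.03, "archaea": 0.015,
                                      "bacteria": 0.01, "fungi": 0.005},
            "link_density": 0.25,
            "link_mass": 0.10,
        }
        params.update(overrides)
        return cls(seed=seed, **params)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("n_sites", "replicates_per_site", "n_grass_species"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for dom, k in self.n_taxa.items():
            if k < 1:
                raise ValidationError(f"n_taxa[{dom}] must be >= 1")
        shares = list(self.vpa_weights.values())
        if any(s < 0 or s > 1 for s in shares) or sum(shares) > 1.0 + 1e-9:
            raise ValidationError("vpa weights must be in [0,1] and sum <= 1")


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    direct_links: list[tuple[str, str, int, float]] = field(default_factory=list)
    env_driven_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    ddr_slopes_per_km: dict[str, float] = field(default_factory=dict)
    vpa_weights: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for _, _, sign, strength in self.direct_links:
            if sign not in (-1, 1):
                raise ValidationError("link sign must be +-1")
            if strength <= 0:
                raise ValidationError("link strength must be > 0")

    def to_json(self, path) -> None:
        payload = {
            "direct_links": [list(t) for t in self.direct_links],
            "env_driven_pairs": [list(t) for t in self.env_driven_pairs],
            "ddr_slopes_per_km": self.ddr_slopes_per_km,
            "vpa_weights": self.vpa_weights,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _site_types(n_sites: int) -> list[str]:
    total = sum(k for _, k in TYPE_SITE_SHARE)
    counts = {t: max(0, round(k * n_sites / total)) for t, k in TYPE_SITE_SHARE}
    # fix rounding drift
    order = [t for t, _ in TYPE_SITE_SHARE]
    while sum(counts.values()) < n_sites:
        counts[order[np.argmax([TYPE_SITE_SHARE[i][1] for i in range(4)])]] += 1
    while sum(counts.values()) > n_sites:
        for t in reversed(order):
            if counts[t] > 0 and sum(counts.values()) > n_sites:
                counts[t] -= 1
    types: list[str] = []
    for t in order:
        types.extend([t] * counts[t])
    if len(types) < n_sites:
        types.extend([order[-1]] * (n_sites - len(types)))
    return types[:n_sites]


def generate_landscape(cfg: GeneratorConfig) -> SampleTable:
    """Sites on a transect with type-specific environmental draws.

    Coordinates run along a meridian so that haversine distance equals
    transect-position difference (in km) essentially exactly.
    """
    rng_env, rng_geo = _child_rngs(cfg.seed, 2)
    types = _site_types(cfg.n_sites)
    if cfg.n_sites == 1:
        positions = np.array([cfg.transect_length_km / 2.0])
    else:
        positions = np.linspace(0.0, cfg.transect_length_km, cfg.n_sites)
    rows = []
    for s, (pos, gtype) in enumerate(zip(positions, types)):
        for r in range(cfg.replicates_per_site):
            jitter = rng_geo.normal(0.0, 0.2)  # ~200 m replicate scatter
            p = pos + jitter
            row = {
                "sample_id": f"S{s + 1:02d}R{r + 1}",
                "site_id": f"site{s + 1:02d}",
                "grassland_type": gtype,
                "position_km": p,
                "latitude": _TRANSECT_ORIGIN_LAT + p / _KM_PER_DEG_LAT,
                "longitude": _TRANSECT_LON,
            }
            for var, (mu, sd) in TYPE_STATS[gtype].items():
                val = rng_env.normal(mu, sd)
                lo, hi = _CLIP[var]
                if lo is not None:
                    val = max(lo, val)
                if hi is not None:
                    val = min(hi, val)
                row[var] = val
            row["S"] = int(round(row["S"]))
            rows.append(row)
    data = pd.DataFrame(rows).set_index("sample_id")
    return SampleTable(data)


def _window_profile(n_core: int, center: float, width: float) -> np.ndarray:
    """Uniform mass over the index interval [center - w/2, center + w/2)."""
    lo = center - width / 2.0
    hi = center + width / 2.0
    edges = np.arange(n_core + 1, dtype=float)
    overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)
    total = overlap.sum()
    if total <= 0:
        out = np.zeros(n_core)
        out[min(n_core - 1, max(0, int(center)))] = 1.0
        return out
    return overlap / total


def _window_params(n_core: int, slope_per_km: float, length_km: float,
                   breadth_scale: float) -> tuple[float, float]:
    """Width and drift rate realising the requested turnover slope."""
    if n_core < 2 or slope_per_km <= 0:
        return float(n_core), 0.0
    base_width = n_core / (1.0 + slope_per_km * length_km)
    drift = slope_per_km * base_width      # index units per km
    width = base_width * breadth_scale
    return width, drift


def _noisy_counts(expected: np.ndarray, rng: np.random.Generator,
                  noise_scale: float, median_lib: int, lib_sigma: float) -> np.ndarray:
    """Multinomial counts from lognormal-perturbed expected compositions."""
    n, d = expected.shape
    counts = np.zeros((n, d), dtype=np.int64)
    for i in range(n):
        p = expected[i] * np.exp(rng.normal(0.0, noise_scale, size=d))
        p = p / p.sum()
        lib = int(np.round(np.exp(rng.normal(np.log(median_lib), lib_sigma))))
        lib = max(1, lib)
        counts[i] = rng.multinomial(lib, p)
    return counts


def _positions(frame: SampleTable) -> np.ndarray:
    if "position_km" in frame.data.columns:
        return frame.data["position_km"].to_numpy(dtype=float)
    # fall back to latitude-derived transect position
    lat = frame.data["latitude"].to_numpy(dtype=float)
    return (lat - lat.min()) * _KM_PER_DEG_LAT


def generate_grass_community(frame: SampleTable, cfg: GeneratorConfig) -> CountTable:
    """Grass species table: moving-window turnover plus S-driven rare species."""
    rng, = _child_rngs(cfg.seed + 1_000_003, 1)
    pos = _positions(frame)
    d = cfg.n_grass_species
    pool = 0 if d < 6 else max(4, d // 3)
    n_core = d - pool
    slope = cfg.ddr_slopes_per_1000km.get("grass", 0.0) / 1000.0
    width, drift = _window_params(n_core, slope, cfg.transect_length_km, cfg.niche_breadth_scale)
    expected = np.zeros((len(pos), d))
    s_col = frame.data["S"].to_numpy(dtype=float) if "S" in frame.data.columns else np.full(len(pos), pool)
    shift = np.zeros(len(pos))
    if cfg.grass_productivity_coupling_km and "CD" in frame.data.columns:
        cd = frame.data["CD"].to_numpy(dtype=float)
        db = frame.data["DB"].to_numpy(dtype=float) if "DB" in frame.data.columns else cd
        z = ((cd - cd.mean()) / (cd.std() or 1.0) + (db - db.mean()) / (db.std() or 1.0)) / 2.0
        shift = cfg.grass_productivity_coupling_km * z
    for i, x in enumerate(pos + shift):
        center = width / 2.0 + drift * x
        core = _window_profile(n_core, center, width) if n_core >= 1 else np.array([])
        prof = np.zeros(d)
        prof[:n_core] = core
        if pool:
            # independent Bernoulli presence keeps expected richness
            # proportional to S without creating a co-presence clique
            p_present = min(0.8, 0.05 * s_col[i])
            present = rng.random(pool) < p_present
            prof[n_core + np.flatnonzero(present)] = cfg.rare_mass_per_species
        expected[i] = prof / prof.sum()
    taxa = [f"grass_sp{j + 1:02d}" for j in range(d)]
    counts = _noisy_counts(expected, rng, cfg.noise_scale,
                           cfg.library_size_median["grass"], cfg.library_size_sigma)
    # guard: multinomial can zero a sample only if lib=0, which we prevent
    return CountTable(frame.samples, taxa, counts, "grass")


_ENV_BLOCKS = {
    "productivity": ("CD", "DB"),
    "soil": ("pH", "TN", "TP", "SMC"),
    "diversity": ("S",),
}


def generate_microbial_communities(
    frame: SampleTable,
    grass: CountTable,
    cfg: GeneratorConfig,
) -> tuple[dict[str, CountTable], GroundTruth]:
    """Microbial tables per domain plus the realised planted truth."""
    rngs = _child_rngs(cfg.seed + 2_000_003, len(cfg.n_taxa) + 1)
    rng_links = rngs[-1]
    pos = _positions(frame)
    grass_rel = grass.relative_abundance()
    cv = grass_rel.std(axis=0) / np.maximum(grass_rel.mean(axis=0), 1e-12)
    eligible = [j for j in range(grass.n_taxa) if cv[j] > 0.4]
    if cfg.grass_productivity_coupling_km and "CD" in frame.data.columns:
        # when grass composition responds to productivity, plant the links on
        # productivity-favoured species so the planted network's aggregate
        # connectivity rises with stand productivity
        cd = frame.data["CD"].to_numpy(dtype=float)
        z = (cd - cd.mean()) / (cd.std() or 1.0)
        corr = np.array([
            np.corrcoef(grass_rel[:, j], z)[0, 1] if grass_rel[:, j].std() > 0 else 0.0
            for j in range(grass.n_taxa)
        ])
        favoured = [j for j in eligible if corr[j] > 0.2]
        if favoured:
            eligible = favoured
    if not eligible:
        eligible = list(np.argsort(cv)[::-1][: max(1, grass.n_taxa // 4)])

    truth = GroundTruth(
        ddr_slopes_per_km={
            dom: cfg.ddr_slopes_per_1000km.get(dom, 0.0) / 1000.0 / cfg.niche_breadth_scale
            for dom in list(cfg.n_taxa) + ["grass"]
        },
        vpa_weights=dict(cfg.vpa_weights),
    )
    truth.ddr_slopes_per_km["grass"] = (
        cfg.ddr_slopes_per_1000km.get("grass", 0.0) / 1000.0 / cfg.niche_breadth_scale
    )

    # z-scored environmental drivers
    env_z: dict[str, np.ndarray] = {}
    for block, vars_ in _ENV_BLOCKS.items():
        for v in vars_:
            if v in frame.data.columns:
                col = frame.data[v].to_numpy(dtype=float)
                sd = col.std(ddof=1)
                env_z[v] = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)

    tables: dict[str, CountTable] = {}
    for rng, (dom, d) in zip(rngs, cfg.n_taxa.items()):
        n_linked = int(round(cfg.link_density * d))
        n_env_total = int(round(cfg.env_fraction * d))
        weights = cfg.vpa_weights
        wsum = sum(weights.values()) or 1.0
        env_alloc: list[tuple[str, str]] = []  # (block, variable)
        for block in ("productivity", "soil", "diversity"):
            k = int(round(n_env_total * weights.get(block, 0.0) / wsum))
            vars_ = [v for v in _ENV_BLOCKS[block] if v in env_z]
            for t in range(k):
                if vars_:
                    env_alloc.append((block, vars_[t % len(vars_)]))
        n_env = len(env_alloc)
        n_core = d - n_linked - n_env
        if n_core < 2:
            raise ValidationError(f"n_taxa[{dom}] too small for requested link/env fractions")
        slope = cfg.ddr_slopes_per_1000km.get(dom, 0.0) / 1000.0
        width, drift = _window_params(n_core, slope, cfg.transect_length_km,
                                      cfg.niche_breadth_scale)
        core_mass = 1.0 - (cfg.link_mass if n_linked else 0.0) - (cfg.env_mass if n_env else 0.0)

        taxa = [f"{dom[:4]}_otu{j + 1:03d}" for j in range(d)]
        intensity = np.zeros((len(pos), d))
        prod_shift = np.zeros(len(pos))
        if cfg.productivity_coupling_km:
            zs = [env_z[v] for v in ("CD", "DB") if v in env_z]
            if zs:
                prod_shift = cfg.productivity_coupling_km * np.mean(zs, axis=0)
        for i, x in enumerate(pos + prod_shift):
            center = width / 2.0 + drift * x
            intensity[i, :n_core] = core_mass * _window_profile(n_core, center, width)

        # planted direct links: microbe tracks one grass host; hosts are
        # spread over distinct species where possible so that deconvolution
        # does not see redundant host-sharing paths
        if n_linked <= len(eligible):
            hosts = rng_links.choice(eligible, size=n_linked, replace=False)
        else:
            reps = int(np.ceil(n_linked / len(eligible)))
            hosts = rng_links.permutation(np.tile(eligible, reps))[:n_linked]
        spread = sorted(eligible)
        for k, host_j in enumerate(hosts):
            col = n_core + k
            sign = 1 if cfg.positive_links_only else int(rng_links.choice([-1, 1]))
            strength = cfg.link_strength
            if cfg.link_pattern == "hub_satellite" and len(spread) >= 2:
                # one shared hub plant plus a distinct satellite per microbe:
                # redundant generalist microbes whose second host persists
                # long under degree-targeted attack
                host_pair = (spread[0], spread[1 + k % (len(spread) - 1)])
                host_ab = grass_rel[:, list(set(host_pair))].mean(axis=1)
                for hj in set(host_pair):
                    truth.direct_links.append((grass.taxa[hj], taxa[col], sign, strength))
            else:
                host_ab = grass_rel[:, host_j]
                truth.direct_links.append((grass.taxa[host_j], taxa[col], sign, strength))
            latent = (host_ab + 1e-4) ** (sign * strength)
            if cfg.connectivity_productivity_coef and "CD" in env_z:
                latent = latent * np.exp(
                    cfg.connectivity_productivity_coef * np.clip(env_z["CD"], -2.0, 2.0))
            latent = latent / latent.mean()
            intensity[:, col] = (cfg.link_mass / max(1, n_linked)) * latent

        # environment-driven taxa
        for k, (block, var) in enumerate(env_alloc):
            col = n_core + n_linked + k
            coef = cfg.env_strength * (weights[block] / max(weights.values())) ** 2
            latent = np.exp(coef * np.clip(env_z[var], -2.0, 2.0))
            latent = latent / latent.mean()
            intensity[:, col] = (cfg.env_mass / max(1, n_env)) * latent
            truth.env_driven_pairs.append((taxa[col], var, coef))

        expected = intensity / intensity.sum(axis=1, keepdims=True)
        counts = _noisy_counts(expected, rng, cfg.noise_scale,
                               cfg.library_size_median.get(dom, 20000),
                               cfg.library_size_sigma)
        tables[dom] = CountTable(frame.samples, taxa, counts, dom)

    truth.validate()
    return tables, truth


@dataclass
class SyntheticBundle:
    frame: SampleTable
    grass: CountTable
    microbes: dict[str, CountTable]
    truth: GroundTruth
    config: GeneratorConfig

    def all_tables(self) -> dict[str, CountTable]:
        return {"grass": self.grass, **self.microbes}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame.write(outdir / "samples.tsv")
        self.grass.write(outdir / "grass.tsv")
        for dom, t in self.microbes.items():
            t.write(outdir / f"{dom}.tsv")
        self.truth.to_json(outdir / "ground_truth.json")
        cfg = asdict(self.config)
        (outdir / "generator_config.json").write_text(json.dumps(cfg, indent=2))


def simulate_bundle(cfg: GeneratorConfig) -> SyntheticBundle:
    """Landscape + grass + microbial tables + ground truth, one call."""
    frame = generate_landscape(cfg)
    grass = generate_grass_community(frame, cfg)
    microbes, truth = generate_microbial_communities(frame, grass, cfg)
    return SyntheticBundle(frame, grass, microbes, truth, cfg)


def truth_network(bundle: "SyntheticBundle"):
    """Bipartite network of the planted direct links (ground-truth graph)."""
    from .iden import BipartiteNetwork, Edge

    domains = {}
    for dom, t in bundle.microbes.items():
        for tax in t.taxa:
            domains[tax] = dom
    edges = [Edge(g, m, float(sign * strength), int(sign), {"planted"})
             for g, m, sign, strength in bundle.truth.direct_links]
    microbe_nodes = {m: domains[m] for _, m, _, _ in bundle.truth.direct_links}
    plant_nodes = sorted({g for g, _, _, _ in bundle.truth.direct_links})
    return BipartiteNetwork(plant_nodes, microbe_nodes, edges)
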