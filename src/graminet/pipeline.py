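"""End-to-end orchestration: load or simulate -> rarefy -> diversity ->
group statistics -> distance decay -> variance partitioning -> inter-domain
networks -> topology/stability -> connectivity Mantel tests.

Every stochastic step derives its seed from the run seed, so two runs with
the same config produce byte-identical outputs.  A stage failure aborts the
run with the stage name while preserving artifacts already written.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    CountTable, SampleTable, align_pair, read_count_table, read_sample_frame,
    GraminetError,
)
from .diversity import alpha_diversity, bray_curtis_matrix, rarefy_table
from .distance_decay import (
    compare_slopes, fit_ddr, geographic_distance_matrix, variable_divergence_matrix,
)
from .group_stats import kruskal_letters, permanova, spearman_matrix, significance_stars
from .iden import build_iden
from .network_association import partial_mantel, sample_connectivity_profile
from .network_metrics import null_model_ensemble, topology_summary, vulnerability
from .simulate import GeneratorConfig, simulate_bundle
from .variance_partition import vpa_three_way

log = logging.getLogger("graminet")

MICROBIAL_DOMAINS = ("archaea", "bacteria", "fungi")

DDR_PRODUCTIVITY_VARS = ["H", "CD", "S", "FB", "DB"]
VPA_PRODUCTIVITY_VARS = ["CD", "DB", "S"]
SOIL_VARS = ["pH", "TN", "TP", "SMC"]
DIVERSITY_INDICES = ["margalef", "shannon", "pielou"]


class StageError(GraminetError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "graminet_out"
    simulate: dict | None = None
    inputs: dict | None = None          # paths: samples, grass, archaea, ...
    orientation: str = "samples_rows"
    rarefaction_depths: dict = field(default_factory=dict)
    r_threshold: float = 0.3
    p_threshold: float = 0.05
    n_perm: int = 999
    n_boot: int = 100
    sparcc_inner: int = 20
    sparcc_inner_boot: int = 5
    n_null: int = 100
    lted: bool = True
    networks: bool = True
    build_combined_network: bool = True
    site_means: bool = False            # collapse within-site replicates

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _load_tables(cfg: RunConfig) -> tuple[SampleTable, dict[str, CountTable]]:
    if cfg.simulate is not None:
        gen = GeneratorConfig(**{"seed": cfg.seed, **cfg.simulate})
        bundle = simulate_bundle(gen)
        return bundle.frame, bundle.all_tables(), bundle
    if cfg.inputs is None:
        raise GraminetError("config needs either a simulate block or input paths")
    frame = read_sample_frame(cfg.inputs["samples"])
    tables: dict[str, CountTable] = {}
    for dom in ("grass",) + MICROBIAL_DOMAINS:
        if dom in cfg.inputs:
            tables[dom] = read_count_table(cfg.inputs[dom], dom, cfg.orientation)
        else:
            log.warning("no %s table configured; %s stages will be skipped", dom, dom)
    return frame, tables, None


def _collapse_to_site_means(frame: SampleTable, tables: dict[str, CountTable]):
    """Optional: pool replicate counts and average metadata per site."""
    site = frame.data["site_id"]
    num = frame.data.select_dtypes("number").groupby(site).mean()
    meta = frame.data.groupby(site).first()
    meta[num.columns] = num
    meta.index.name = "sample_id"
    new_frame = SampleTable(meta)
    out = {}
    for dom, t in tables.items():
        df = t.to_frame()
        pooled = df.groupby(site.loc[df.index]).sum()
        out[dom] = CountTable(list(pooled.index), list(pooled.columns),
                              pooled.to_numpy(), t.domain)
    return new_frame, out


def run_pipeline(cfg: RunConfig) -> dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "run_config.yaml")
    results: dict = {"stages": [], "versions": {"graminet": __version__,
                                                "python": platform.python_version()}}
    runlog: dict = {"seed": cfg.seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - stage name is the contract
                (outdir / "run_log.json").write_text(json.dumps(runlog, indent=2, default=str))
                raise StageError(name, exc) from exc
            results["stages"].append(name)
            return out
        return wrap

    # ---- load / simulate ----------------------------------------------
    frame, tables, bundle = stage("load")(lambda: _load_tables(cfg))
    if bundle is not None:
        bundle.write(outdir / "simulated")
    if cfg.site_means:
        frame, tables = _collapse_to_site_means(frame, tables)
    runlog["stages"]["load"] = {dom: t.n_samples for dom, t in tables.items()}

    # ---- rarefaction --------------------------------------------------
    def do_rarefy():
        out = {}
        for dom, t in tables.items():
            depth = cfg.rarefaction_depths.get(dom)
            if depth:
                rt, report = rarefy_table(t, int(depth), seed=cfg.seed + 11)
                out[dom] = rt.drop_empty_taxa()
                runlog["stages"].setdefault("rarefy", {})[dom] = {
                    "depth": depth, "dropped": report.dropped}
            else:
                out[dom] = t
        return out

    tables = stage("rarefy")(do_rarefy)

    # per-domain alignment with the metadata (domains may differ in samples)
    aligned: dict[str, tuple[CountTable, SampleTable]] = {}
    for dom, t in tables.items():
        aligned[dom] = align_pair(t, frame)

    # ---- diversity ----------------------------------------------------
    def do_diversity():
        alphas, bcs = {}, {}
        for dom, (t, fr) in aligned.items():
            alphas[dom] = alpha_diversity(t)
            alphas[dom].to_csv(outdir / f"alpha_{dom}.tsv", sep="\t")
            bcs[dom] = bray_curtis_matrix(t)
            bcs[dom].write(outdir / f"braycurtis_{dom}.tsv")
        return alphas, bcs

    alphas, bcs = stage("diversity")(do_diversity)

    # ---- group statistics ---------------------------------------------
    def do_group_stats():
        out = {"letters": {}, "permanova": {}, "spearman": {}}
        if "grassland_type" in frame.data.columns:
            groups_all = frame.data["grassland_type"]
            env_vars = [c for c in ("pH", "CEC", "OM", "TN", "TP", "TC", "SMC",
                                    "H", "CD", "S", "FB", "DB", "MAT", "altitude")
                        if c in frame.data.columns]
            rows = []
            for var in env_vars:
                ld = kruskal_letters(frame.data[var].to_numpy(dtype=float),
                                     groups_all.to_numpy(), variable=var)
                out["letters"][var] = ld
                for g in ld.groups:
                    rows.append({"variable": var, "group": g, "mean": ld.means[g],
                                 "sd": ld.sds[g], "letters": ld.letters[g]})
            pd.DataFrame(rows).to_csv(outdir / "group_letters.tsv", sep="\t", index=False)
            for dom, dm in bcs.items():
                fr = aligned[dom][1]
                res = permanova(dm, fr.data["grassland_type"].to_numpy(),
                                n_perm=cfg.n_perm, seed=cfg.seed + 23)
                out["permanova"][dom] = res
            pd.DataFrame(
                [{"domain": d, "pseudo_F": r.pseudo_f, "R2": r.r_squared, "p": r.p_value}
                 for d, r in out["permanova"].items()]
            ).to_csv(outdir / "permanova.tsv", sep="\t", index=False)
        grass_vars = [c for c in DDR_PRODUCTIVITY_VARS if c in frame.data.columns]
        for dom in MICROBIAL_DOMAINS:
            if dom not in aligned:
                continue
            t, fr = aligned[dom]
            x = alphas[dom]
            y = fr.data[grass_vars].astype(float)
            if "grass" in aligned:
                ga = alpha_diversity(aligned["grass"][0].select_samples(
                    [s for s in t.samples if s in aligned["grass"][0].samples]))
                common = [s for s in t.samples if s in ga.index]
                rho, p = spearman_matrix(x.loc[common], pd.concat(
                    [y.loc[common], ga.loc[common, DIVERSITY_INDICES]], axis=1))
            else:
                rho, p = spearman_matrix(x, y)
            stars = p.map(significance_stars)
            out["spearman"][dom] = (rho, p)
            rho.to_csv(outdir / f"spearman_rho_{dom}.tsv", sep="\t")
            stars.to_csv(outdir / f"spearman_stars_{dom}.tsv", sep="\t")
        return out

    gstats = stage("group_stats")(do_group_stats)

    # ---- distance decay -----------------------------------------------
    def do_ddr():
        fits = {}
        contrasts = {}
        predictor_dms = {}
        for dom, (t, fr) in aligned.items():
            geo = geographic_distance_matrix(fr)
            predictor_dms[dom] = {"geographic": geo}
            pvars = [c for c in DDR_PRODUCTIVITY_VARS if c in fr.data.columns]
            if pvars:
                predictor_dms[dom]["productivity"] = variable_divergence_matrix(fr, pvars)
            soils = [c for c in SOIL_VARS if c in fr.data.columns]
            if soils:
                predictor_dms[dom]["soil"] = variable_divergence_matrix(fr, soils)
            if "grass" in aligned:
                gt = aligned["grass"][0]
                shared = [s for s in fr.samples if s in gt.samples]
                if len(shared) == len(fr.samples):
                    ga = alpha_diversity(gt.select_samples(shared))
                    div_frame = SampleTable(pd.concat(
                        [fr.data[["latitude", "longitude"]], ga], axis=1))
                    predictor_dms[dom]["diversity"] = variable_divergence_matrix(
                        div_frame, DIVERSITY_INDICES)
        rows = []
        for predictor in ("geographic", "productivity", "diversity", "soil"):
            group_fits = []
            for dom, (t, fr) in aligned.items():
                if predictor not in predictor_dms.get(dom, {}):
                    continue
                fit = fit_ddr(bcs[dom], predictor_dms[dom][predictor],
                              organism_group=dom, predictor=predictor,
                              n_perm=cfg.n_perm, seed=cfg.seed + 31)
                fits[(dom, predictor)] = fit
                group_fits.append(fit)
                rows.append({"organism_group": dom, "predictor": predictor,
                             "slope": fit.slope, "intercept": fit.intercept,
                             "r2": fit.r_squared, "p_perm": fit.p_permutation,
                             "p_ols": fit.p_ols, "n_pairs": fit.n_pairs})
            if len(group_fits) >= 2:
                contrasts[predictor] = compare_slopes(group_fits)
                contrasts[predictor].to_csv(
                    outdir / f"ddr_contrasts_{predictor}.tsv", sep="\t", index=False)
        pd.DataFrame(rows).to_csv(outdir / "ddr_fits.tsv", sep="\t", index=False)
        return fits, contrasts

    ddr_fits, ddr_contrasts = stage("distance_decay")(do_ddr)

    # ---- variance partitioning ----------------------------------------
    def do_vpa():
        out = {}
        rows = []
        for dom in MICROBIAL_DOMAINS:
            if dom not in aligned or "grass" not in aligned:
                continue
            t, fr = aligned[dom]
            shared = [s for s in fr.samples if s in aligned["grass"][0].samples]
            if len(shared) < 8:
                continue
            tt = t.select_samples(shared).drop_empty_taxa()
            fsub = fr.select_samples(shared)
            ga = alpha_diversity(aligned["grass"][0].select_samples(shared))
            prod = fsub.data[[c for c in VPA_PRODUCTIVITY_VARS if c in fsub.data.columns]].astype(float)
            soil = fsub.data[[c for c in SOIL_VARS if c in fsub.data.columns]].astype(float)
            div = ga[DIVERSITY_INDICES].fillna(ga[DIVERSITY_INDICES].mean())
            res = vpa_three_way(tt, prod, div, soil,
                                names=("productivity", "diversity", "soil"))
            out[dom] = res
            rows.append({"domain": dom, "total_explained": res.total_explained,
                         "unique_productivity": res.unique["a"],
                         "unique_diversity": res.unique["b"],
                         "unique_soil": res.unique["c"],
                         "shared_prod_div": res.shared_pair["ab"],
                         "shared_prod_soil": res.shared_pair["ac"],
                         "shared_div_soil": res.shared_pair["bc"],
                         "shared_all": res.shared_triple,
                         "residual": res.residual})
        pd.DataFrame(rows).to_csv(outdir / "vpa.tsv", sep="\t", index=False)
        return out

    vpa = stage("variance_partition")(do_vpa)

    # ---- inter-domain networks ----------------------------------------
    def do_iden():
        nets = {}
        if not cfg.networks:
            return nets
        if "grass" not in aligned:
            log.warning("no grass table: network stages skipped")
            return nets
        combos = [(dom, [dom]) for dom in MICROBIAL_DOMAINS if dom in aligned]
        if cfg.build_combined_network and len(combos) > 1:
            combos.append(("all", [d for d, _ in combos]))
        for name, doms in combos:
            grass_t = aligned["grass"][0]
            micro_ts = [aligned[d][0] for d in doms]
            shared = set(grass_t.samples)
            for t in micro_ts:
                shared &= set(t.samples)
            fr = frame.select_samples(sorted(shared))
            geo = geographic_distance_matrix(fr)
            art = build_iden(
                grass_t, micro_ts, fr, geo,
                r_threshold=cfg.r_threshold, p_threshold=cfg.p_threshold,
                n_inner=cfg.sparcc_inner, n_boot=cfg.n_boot,
                n_inner_boot=cfg.sparcc_inner_boot,
                seed=cfg.seed + 101, lted=cfg.lted,
            )
            nets[name] = art
            art.pruned.write_edges(outdir / f"network_{name}_edges.tsv")
            art.prune_log.to_csv(outdir / f"network_{name}_pruned.tsv",
                                 sep="\t", index=False)
            try:
                art.pruned.write_graphml(outdir / f"network_{name}.graphml")
            except Exception:  # graphml is a convenience export only
                pass
            runlog["stages"].setdefault("iden", {})[name] = {
                "filtered_edges": art.filtered.n_edges,
                "deconvolved_edges": art.deconvolved.n_edges,
                "final_edges": art.pruned.n_edges,
            }
        return nets

    nets = stage("iden")(do_iden)

    # ---- topology & stability -----------------------------------------
    def do_stability():
        rows = []
        stab = {}
        for name, art in nets.items():
            net = art.pruned
            if not net.edges:
                continue
            topo = topology_summary(net)
            vuln = vulnerability(net)
            null = null_model_ensemble(net, n_null=cfg.n_null, seed=cfg.seed + 211)
            stab[name] = (topo, vuln, null)
            rows.append({
                "network": name, "n_plants": topo.n_plants,
                "n_microbes": topo.n_microbes, "n_edges": topo.n_edges,
                "connectance": topo.connectance, "mean_degree": topo.mean_degree,
                "avg_clustering": topo.avg_clustering, "nodf": topo.nestedness_nodf,
                "robustness": null.robustness,
                "null_robustness_mean": float(np.mean(null.null_distribution)),
                "robustness_vs_null_p": null.empirical_vs_null_p,
                "vulnerability": vuln,
            })
            pd.DataFrame({"fraction_removed": null.fractions_removed,
                          "surviving": null.attack_curve}).to_csv(
                outdir / f"attack_curve_{name}.tsv", sep="\t", index=False)
        pd.DataFrame(rows).to_csv(outdir / "network_summary.tsv", sep="\t", index=False)
        return stab

    stability = stage("network_metrics")(do_stability)

    # ---- connectivity Mantel tests ------------------------------------
    def do_mantel():
        out = {}
        rows = []
        for name, art in nets.items():
            net = art.pruned
            if not net.edges:
                continue
            doms = sorted({net.microbe_nodes[m] for m in net.microbe_nodes})
            use_tables = [aligned["grass"][0]] + [aligned[d][0] for d in doms]
            scores, conn_dm = sample_connectivity_profile(net, use_tables)
            fr = frame.select_samples(conn_dm.labels)
            geo = geographic_distance_matrix(fr)
            soil_vars = [c for c in SOIL_VARS if c in fr.data.columns]
            soil_dm = variable_divergence_matrix(fr, soil_vars) if soil_vars else None
            prod_vars = [c for c in DDR_PRODUCTIVITY_VARS if c in fr.data.columns]
            prod_dm = variable_divergence_matrix(fr, prod_vars) if prod_vars else None
            groups = {"productivity": prod_vars, "diversity": [], "soil": soil_vars}
            for group, vars_ in groups.items():
                for var in vars_:
                    target = variable_divergence_matrix(fr, [var])
                    controls = [geo]
                    if group == "soil" and prod_dm is not None:
                        controls.append(prod_dm)
                    elif group != "soil" and soil_dm is not None:
                        controls.append(soil_dm)
                    res = partial_mantel(conn_dm, target, controls,
                                         n_perm=cfg.n_perm, seed=cfg.seed + 307,
                                         variable=var)
                    out[(name, var)] = res
                    rows.append({"network": name, "group": group, "variable": var,
                                 "r": res.r, "p": res.p})
        pd.DataFrame(rows).to_csv(outdir / "connectivity_mantel.tsv", sep="\t", index=False)
        return out

    mantel_results = stage("network_association")(do_mantel)

    runlog["stages"]["completed"] = results["stages"]
    (outdir / "run_log.json").write_text(json.dumps(runlog, indent=2, default=str))
    results.update({
        "frame": frame, "tables": tables, "alphas": alphas, "bcs": bcs,
        "group_stats": gstats, "ddr_fits": ddr_fits, "ddr_contrasts": ddr_contrasts,
        "vpa": vpa, "networks": nets, "stability": stability,
        "mantel": mantel_results,
    })
    return results
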