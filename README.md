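# graminet

Analysis toolkit for linking grassland plant communities to soil microbial
communities (archaea, bacteria, fungi) across environmental gradients.
Implements, as a tested reusable pipeline:

- **Data model & I/O** — TSV count tables (sample × taxon), sample metadata
  (coordinates, soil chemistry, grass biophysical variables, grassland
  type), distance matrices; per-domain sample alignment
  (`graminet.core`).
- **Synthetic community generator** — study-shaped landscapes (16 sites × 3
  replicates on a ~2,100 km transect, four grassland types) with planted
  ground truth: exact distance-decay turnover rates per organism group,
  direct grass–microbe associations, environment-driven taxa, and
  configurable network structure (`graminet.simulate`).
- **Diversity** — seeded rarefaction without replacement, observed
  richness / Shannon (nats) / Pielou / Margalef, Bray–Curtis matrices
  (`graminet.diversity`).
- **Group statistics** — Kruskal–Wallis with Dunn/Benjamini–Hochberg
  post-hoc compact-letter displays, Spearman correlation screens,
  PERMANOVA (`graminet.group_stats`).
- **Distance decay** — haversine geographic distances, z-scored Euclidean
  variable divergence, OLS distance-decay fits with matrix-permutation
  significance, pooled interaction slope contrasts
  (`graminet.distance_decay`).
- **Variance partitioning** — three-way partition of community inertia
  (grass productivity / grass diversity / soil) via constrained
  correspondence analysis and inclusion–exclusion
  (`graminet.variance_partition`).
- **Inter-domain networks** — SparCC compositional correlation on the
  stacked plant + microbe table, permutation-bootstrap p-values,
  |r|/p filtering, direct-dependency deconvolution via a bounded
  path-transitivity fixed point, and environmental / geographic link
  pruning (`graminet.iden`).
- **Network structure & stability** — connectance, bipartite clustering,
  NODF nestedness, attack-tolerance robustness, vulnerability,
  degree-preserving null ensembles (`graminet.network_metrics`).
- **Connectivity association** — sample-level network-connectivity
  profiles tested against productivity / diversity / soil divergence with
  Mantel and (multi-control) partial Mantel tests
  (`graminet.network_association`).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: brute-force oracle
equivalence (NODF, SparCC basis solve, exhaustive permutation p-values),
closed-form limits, type-I-error calibration, planted-parameter recovery,
and qualitative structure checks.

## CLI

All commands take a YAML run config (fields of
`graminet.pipeline.RunConfig`):

```yaml
# cfg.yaml
seed: 1
outdir: out/
simulate:                 # or use `inputs:` with paths to TSV tables
  n_grass_species: 30
  n_taxa: {archaea: 150, bacteria: 600, fungi: 300}
rarefaction_depths: {archaea: 20828, bacteria: 20828, fungi: 10140}
r_threshold: 0.3
p_threshold: 0.05
n_boot: 100
n_perm: 999
```

```bash
graminet simulate  --config cfg.yaml          # synthetic bundle + ground truth
graminet diversity --config cfg.yaml          # through diversity/DDR/VPA stages
graminet iden      --config cfg.yaml --boot 100 --seed 1
graminet stability --config cfg.yaml --nulls 100
graminet all       --config cfg.yaml          # complete pipeline
```

Every run writes TSV/JSON artifacts plus `run_config.yaml` and
`run_log.json` into the output directory; reruns with the same config and
seed are byte-identical.

To run on real data, replace the `simulate:` block with

```yaml
inputs:
  samples: meta.tsv     # sample_id, latitude, longitude, pH, CD, ...
  grass: grass.tsv      # sample x species counts
  archaea: arch.tsv
  bacteria: bact.tsv
  fungi: its.tsv        # may cover fewer samples; handled per domain
```

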