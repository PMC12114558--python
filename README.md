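# pahsoil

Analysis of bacterial communities in **aged, PAH-polluted saline soils** —
the kind of mosaic of bare and naturally revegetated patches found around
decommissioned oil wells in coastal deltas, where communities sit under dual
stress from salinity and polycyclic aromatic hydrocarbons (PAHs).

The package implements, as a reusable and tested pipeline:

- **PAH toxicity scoring** — LMW (2–3 ring) / HMW (4–6 ring) partition of the
  16 US-EPA priority congeners, the benzo[a]pyrene toxic-equivalent
  concentration TEQ_BaP = Σᵢ cᵢ·TEFᵢ, and total-PAH contamination
  classification (heavily polluted strictly above 1.00 mg·kg⁻¹).
- **Community diversity and ordination** — taxonomic aggregation,
  bias-corrected Chao1 (S_obs + F₁(F₁−1)/(2(F₂+1))), Shannon entropy
  (−Σ pᵢ ln pᵢ), Bray–Curtis dissimilarity, and NMDS minimising Kruskal
  stress-1.
- **qPCR absolute quantification** — standard curves Ct = a·log₁₀N + b with
  amplification efficiency 10^(−1/a) − 1, for 16S rRNA, PAH-RHDα and C12O
  (catechol 1,2-dioxygenase) genes.
- **Environment–community statistics** — Spearman correlation grids,
  permutation Mantel tests, redundancy analysis (RDA) with marginal
  per-variable explained %, and one-way ANOVA with Tukey HSD compact letter
  displays.
- **Co-occurrence networks** — rare-taxon filtering (cumulative relative
  abundance < 0.5% or prevalence < 3 samples removed), edges where
  |Spearman r| > 0.6 and p < 0.01, topology metrics, Louvain modules,
  Erdős–Rényi G(n, m) null ensembles, small-world/modularity verdicts, and
  keystone taxa ranked by betweenness centrality.
- **A synthetic study generator** — three regions (GA/GB/GC) along a salinity
  gradient with paired vegetated/bare samples, genus guilds with plantable
  correlation structure, niche responses to electrical conductivity (EC), and
  functional-gene copy numbers on published scales — so every downstream
  stage is testable without any sequencing download.

## Worked example

```python
from pahsoil import synth, community, network, pah, qpcr

cfg = synth.StudyConfig(seed=42)          # 3 regions x 2 covers x 10 samples
ds = synth.generate_study(cfg, seed=42)

summary = pah.summarize_table(ds.pah)
div = community.diversity_table(ds.abundance)
curves = qpcr.fit_curves(ds.standards)

rel = community.to_relative(ds.abundance)
for cover in ("vegetated", "bare"):
    ids = ds.metadata.index[ds.metadata.cover == cover]
    sub = community.AbundanceTable(data=rel.data[ids], taxonomy=rel.taxonomy,
                                   mode="relative", subset=True)
    net = network.build_network(network.filter_taxa(sub))
    topo = network.network_topology(net, seed=42)
    null = network.er_null_ensemble(topo.n_nodes, topo.n_edges,
                                    n_replicates=100, seed=42)
    verdict = network.small_world_assessment(topo, null)
```

which prints, with the formatting from the example script:

```
TPAH (bare) mean: 2.12
heavily polluted: 77%
Shannon range: 3.4 - 4.37
16S curve: slope -3.3219, efficiency 1.000, r2 1.0000
vegetated: 54 nodes, 276 edges, Q=0.760, positive edges 100.0%, small-world+modular=True
bare: 60 nodes, 7 edges, Q=0.816, positive edges 71.4%, small-world+modular=False
```

Reading this: bare soils average 2.12 mg·kg⁻¹ total PAHs (heavily polluted),
the noiseless dilution series recovers a perfect-efficiency standard curve,
and the vegetated community — generated with stronger genus guilds — yields a
far denser co-occurrence network than the bare one, with clustering and
modularity exceeding its size-matched Erdős–Rényi null (a small-world,
modular topology). The sparse bare network never reaches that verdict.

The same pipeline runs end to end from the command line:

```sh
pahsoil simulate --out bundle --seed 42
pahsoil all --out run --input-dir bundle --seed 42
```

writing per-stage CSVs, GraphML/GEXF networks for Gephi, and a
`manifest.json` (seeds, thresholds, versions) sufficient to reproduce the
run. Real studies are analysed by pointing the readers at a bundle of
abundance TSV + metadata/PAH/qPCR CSVs in the documented formats.

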