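"""Readers, writers, the study bundle, and the end-to-end pipeline.

File formats
------------
- abundance TSV: ``taxon_id`` column, ``taxonomy`` lineage column
  (``k__;p__;c__;o__;f__;g__`` strings), then one numeric column per sample.
- metadata CSV: ``sample_id, region, cover`` plus numeric physicochemistry
  (pH, EC, OM, CAT, AN, AP, TPH); missing numeric cells propagate as NaN.
- PAH CSV: ``sample_id`` plus the 16 congener columns (mg·kg⁻¹).
- TEF CSV: ``congener, tef``.
- qPCR CSVs: standards ``gene, log10_copies, ct``; samples
  ``sample_id, gene, ct``.

``run_pipeline`` orchestrates: (simulate | load) → PAH summaries/TEQ/classes
→ diversity + NMDS → qPCR quantification → correlations/Mantel/RDA/ANOVA →
per-cover co-occurrence networks with Erdős–Rényi nulls, small-world verdicts
and keystone rankings — and writes a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform

from . import assoc, community, network, pah as pahmod, qpcr, synth
from ._seeds import child_int
from .community import AbundanceTable

logger = logging.getLogger(__name__)

_RE_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


def read_abundance(path) -> AbundanceTable:
    """Read an abundance TSV into a counts-mode table."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
    if "taxon_id" not in df.columns or "taxonomy" not in df.columns:
        raise ValueError(f"{path}: need 'taxon_id' and 'taxonomy' columns")
    dup = df["taxon_id"][df["taxon_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated taxon id(s): {dup}")
    for lineno, lineage in enumerate(df["taxonomy"], start=2):
        if not any(p in str(lineage) for p in _RE_RANK_PREFIXES):
            raise ValueError(
                f"{path} line {lineno}: malformed lineage string {lineage!r}"
            )
    data = df.drop(columns=["taxonomy"]).set_index("taxon_id").astype(float)
    if (data.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance value(s)")
    tax = df.set_index("taxon_id")["taxonomy"]
    return AbundanceTable(data=data, taxonomy=tax, mode="counts")


def write_abundance(table: AbundanceTable, path) -> None:
    out = table.data.copy()
    out.insert(0, "taxonomy", table.taxonomy)
    out.rename_axis("taxon_id").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV; validates cover labels."""
    df = pd.read_csv(path, index_col="sample_id")
    bad = set(df["cover"].unique()) - {synth.COVER_VEGETATED, synth.COVER_BARE}
    if bad:
        raise ValueError(
            f"{path}: unknown cover label(s) {sorted(bad)}; "
            f"expected {synth.COVER_VEGETATED!r} or {synth.COVER_BARE!r}"
        )
    return df


def read_pah(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    extra = set(df.columns) - set(pahmod.CONGENERS)
    if extra:
        raise ValueError(f"{path}: unknown congener column(s) {sorted(extra)}")
    return df


def read_qpcr_standards(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_qpcr_samples(path) -> pd.DataFrame:
    return pd.read_csv(path)


def reconcile_samples(metadata: pd.DataFrame, table: AbundanceTable) -> None:
    """Raise when metadata and abundance sample sets disagree."""
    meta = set(metadata.index)
    abund = set(map(str, table.samples))
    missing = sorted(meta - abund)
    extra = sorted(abund - meta)
    if missing or extra:
        raise ValueError(
            "sample sets differ between metadata and abundance table: "
            f"metadata-only={missing}, abundance-only={extra}"
        )


def group_summary(metadata: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Per region × cover group means ± SD of numeric metadata columns."""
    cols = columns or [
        c for c in metadata.columns if pd.api.types.is_numeric_dtype(metadata[c])
    ]
    g = metadata.groupby(["region", "cover"])[cols]
    means, sds = g.mean(), g.std(ddof=1)
    out = pd.concat({"mean": means, "sd": sds}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1)


def write_bundle(dataset: synth.StudyDataset, outdir) -> dict[str, Path]:
    """Write the standard study bundle (TSV/CSV + truth YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.tsv",
        "metadata": outdir / "metadata.csv",
        "pah": outdir / "pah.csv",
        "genes": outdir / "genes.csv",
        "standards": outdir / "standards.csv",
        "truth": outdir / "truth.yaml",
    }
    write_abundance(dataset.abundance, paths["abundance"])
    dataset.metadata.to_csv(paths["metadata"])
    dataset.pah.to_csv(paths["pah"])
    dataset.genes.to_csv(paths["genes"], index=False)
    dataset.standards.to_csv(paths["standards"], index=False)
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(dataset.truth, fh, sort_keys=True)
    return paths


def read_bundle(indir) -> synth.StudyDataset:
    indir = Path(indir)
    with open(indir / "truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    return synth.StudyDataset(
        metadata=read_metadata(indir / "metadata.csv"),
        pah=read_pah(indir / "pah.csv"),
        abundance=read_abundance(indir / "abundance.tsv"),
        genes=pd.read_csv(indir / "genes.csv"),
        standards=pd.read_csv(indir / "standards.csv"),
        truth=truth,
    )


@dataclass
class PipelineConfig:
    """End-to-end run configuration: simulate or load, plus thresholds."""

    outdir: str = "pahsoil_run"
    seed: int = 0
    simulate: synth.StudyConfig | None = None
    input_dir: str | None = None
    r_threshold: float = 0.6
    p_threshold: float = 0.01
    alpha: float = 0.05
    scheme: str = pahmod.SCHEME_FOUR_TIER
    n_null: int = 100
    n_perm: int = 999
    stratify_by: str = "cover"

    def __post_init__(self):
        if self.simulate is None and self.input_dir is None:
            self.simulate = synth.StudyConfig(seed=self.seed)
        if not (0 <= self.r_threshold <= 1) or not (0 < self.p_threshold <= 1):
            raise ValueError("thresholds out of range")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all outputs plus a manifest.

    Any stage failure leaves earlier outputs on disk; the manifest records
    the failure point.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "r_threshold": config.r_threshold,
            "p_threshold": config.p_threshold,
            "alpha": config.alpha,
            "scheme": config.scheme,
        },
        "child_seeds": {
            stage: child_int(config.seed, stage)
            for stage in ("nmds", "mantel", "modules", "null")
        },
        "versions": _versions(),
        "stages": [],
    }
    results: dict = {"manifest": manifest}
    try:
        # --- data ---
        if config.input_dir is not None:
            ds = read_bundle(config.input_dir)
        else:
            ds = synth.generate_study(config.simulate, seed=config.seed)
            write_bundle(ds, outdir / "bundle")
        reconcile_samples(ds.metadata, ds.abundance)
        results["dataset"] = ds
        manifest["stages"].append("data")

        # --- PAH toxicity ---
        pah_summary = pahmod.summarize_table(ds.pah, scheme=config.scheme)
        pah_summary.to_csv(outdir / "pah_summary.csv")
        results["pah_summary"] = pah_summary
        manifest["stages"].append("pah")

        # --- diversity + ordination ---
        rel = community.to_relative(ds.abundance)
        div = community.diversity_table(ds.abundance)
        div.to_csv(outdir / "diversity.csv")
        bc = community.bray_curtis(rel)
        bc.to_csv(outdir / "bray_curtis.csv")
        ord_res = community.nmds(bc, k=2, seed=config.seed)
        ord_res.coordinates.to_csv(outdir / "nmds.csv")
        results.update(diversity=div, bray_curtis=bc, nmds=ord_res)
        manifest["stages"].append("diversity")

        # --- qPCR ---
        curves = qpcr.fit_curves(ds.standards)
        quant = qpcr.quantify_table(ds.genes[["sample_id", "gene", "ct"]], curves)
        quant.to_csv(outdir / "gene_quant.csv", index=False)
        results["gene_quant"] = quant
        manifest["stages"].append("qpcr")

        # --- association statistics ---
        env_cols = [
            c for c in ("pH", "EC", "OM", "CAT", "AN", "AP", "TPH")
            if c in ds.metadata.columns
        ]
        env = ds.metadata[env_cols]
        bio = pd.DataFrame(
            {"shannon": div["shannon"], "chao1": div["chao1"]}, index=div.index
        )
        grid = assoc.correlation_matrix(pd.concat([env, bio], axis=1).T)
        grid.to_csv(outdir / "correlations.csv", index=False)
        env_z = (env - env.mean()) / env.std(ddof=1).replace(0, 1.0)
        env_dist = pd.DataFrame(
            squareform(pdist(env_z.fillna(0.0).to_numpy())),
            index=env.index,
            columns=env.index,
        )
        mantel = assoc.mantel_test(
            bc, env_dist, n_perm=config.n_perm, seed=config.seed
        )
        rda = assoc.rda_explained(bio.dropna(axis=1), env)
        rda.explained.rename("explained_pct").to_csv(outdir / "rda_explained.csv")
        anova = assoc.anova_tukey_letters(
            ds.metadata["EC"], ds.metadata["region"], alpha=config.alpha
        )
        anova.summary.to_csv(outdir / "anova_ec.csv")
        results.update(correlations=grid, mantel=mantel, rda=rda, anova=anova)
        manifest["stages"].append("assoc")

        # --- networks per stratum ---
        strata = {}
        for level, meta_s in ds.metadata.groupby(config.stratify_by):
            sub = AbundanceTable(
                data=rel.data[meta_s.index]
                / rel.data[meta_s.index].sum(axis=0),
                taxonomy=rel.taxonomy,
                mode="relative",
            )
            filtered = network.filter_taxa(sub)
            net = network.build_network(
                filtered,
                r_threshold=config.r_threshold,
                p_threshold=config.p_threshold,
            )
            topo = network.network_topology(net, seed=config.seed)
            null = network.er_null_ensemble(
                topo.n_nodes, topo.n_edges, n_replicates=config.n_null,
                seed=config.seed,
            )
            verdict = network.small_world_assessment(topo, null)
            modules, _ = network.detect_modules(net.graph, seed=config.seed)
            try:
                keystones = network.keystone_taxa(net, top_k=10)
            except ValueError:  # too sparse for a meaningful ranking
                keystones = pd.DataFrame(
                    columns=["taxon_id", "genus", "betweenness", "degree"]
                )
            network.export_network(
                net, outdir / f"network_{level}", modules=modules
            )
            network.topology_report(topo, outdir / f"topology_{level}.json")
            keystones.to_csv(outdir / f"keystones_{level}.csv", index=False)
            strata[level] = {
                "network": net,
                "topology": topo,
                "null": null,
                "small_world": verdict,
                "keystones": keystones,
            }
        results["networks"] = strata
        manifest["network"] = {
            level: {
                "n_nodes": s["topology"].n_nodes,
                "n_edges": s["topology"].n_edges,
                "modularity": s["topology"].modularity,
                "small_world_and_modular": s["small_world"][
                    "small_world_and_modular"
                ],
            }
            for level, s in strata.items()
        }
        manifest["stages"].append("network")
    except Exception as exc:  # record the failure point, keep partial outputs
        manifest["failed_at"] = repr(exc)
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return results


def _versions() -> dict:
    import networkx, scipy, sklearn, statsmodels

    import pahsoil

    return {
        "pahsoil": pahsoil.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
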