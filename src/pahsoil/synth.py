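"""Synthetic study generator.

Emulates a field survey of aged, PAH-polluted saline soils: three sampling
regions (GA, GB, GC) along a salinity (electrical-conductivity) gradient, each
contributing paired vegetated and bare soil samples. Vegetated soils carry
lower EC and PAH burdens and higher catalase activity; genus abundances
respond to the EC niche axis and are organised into correlated guilds (latent
factors) so that co-occurrence structure exists by construction; functional
gene copy numbers decline with salinity on the log scale.

All group-level means default to the published survey summary bundled in
:mod:`pahsoil.datasets`. Multiplicative noise is mean-one lognormal
(``exp(σz − σ²/2)``), so configured means are recovered exactly in
expectation and setting ``noise_sd_log = 0`` switches noise off entirely.
Gene copy numbers are additionally mean-calibrated across the design (an
exact lognormal Jensen correction) so the linear-scale design mean equals the
configured mean.

One study seed is expanded into independent per-stage streams
(see :mod:`pahsoil._seeds`); identical ``(config, seed)`` reproduce the
dataset byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import pah as pahmod
from ._seeds import child_rng
from .community import AbundanceTable, format_lineage

COVER_BARE = "bare"
COVER_VEGETATED = "vegetated"

_DEFAULT_REGIONS = ("GA", "GB", "GC")

# Fixed congener partition weights within the LMW and HMW fractions;
# phenanthrene-dominated LMW, broad 4-6-ring HMW, as is typical of aged
# petrogenic profiles.
_LMW_WEIGHTS = {
    "NAP": 0.15, "ACY": 0.05, "ACE": 0.05, "FLU": 0.15, "PHE": 0.45, "ANT": 0.15,
}
_HMW_WEIGHTS = {
    "FLA": 0.12, "PYR": 0.13, "BaA": 0.10, "CHR": 0.12, "BbF": 0.10,
    "BkF": 0.07, "BaP": 0.12, "IndP": 0.11, "DahA": 0.05, "BghiP": 0.08,
}

_PHYLA = (
    "Proteobacteria", "Actinobacteria", "Firmicutes", "Chloroflexi",
    "Gemmatimonadetes", "Bacteroidetes", "Planctomycetes", "Acidobacteria",
)


class ConfigurationError(ValueError):
    """Invalid study configuration."""


@dataclass(frozen=True)
class StudyConfig:
    """Generating parameters of a synthetic study.

    Region-indexed defaults are the bare-soil group means of the bundled
    field summary; vegetated cells scale them by the vegetation multipliers.
    ``noise_sd_log`` is the lognormal σ applied to positive quantities
    (natural-log scale for physicochemistry/PAHs, log10 scale for gene
    copies).
    """

    n_regions: int = 3
    samples_per_cell: int = 10
    ec_region_means: Sequence[float] = (1.25, 2.06, 7.23)
    vegetation_ec_multiplier: float = 0.41
    pah_region_means: Sequence[float] = (2.30, 2.04, 1.77)
    vegetation_pah_multiplier: float = 0.45
    lmw_fraction: float = 0.20
    n_genera: int = 150
    n_guilds: int = 5
    guild_loading: float = 0.55
    guild_loading_vegetated: float = 0.90
    niche_ec_slopes: Sequence[float] | None = None
    niche_clade_fraction: float = 0.3
    niche_clade_slope: float = -0.2
    gene_mean_16s: float = 4.02e8
    gene_mean_rhd: float = 1.37e6
    gene_mean_c12o: float = 2.26e5
    gene_ec_slope: float = -0.08
    gene_vegetation_offset: float = 0.2
    qpcr_curve_slope: float = -3.3219
    qpcr_curve_intercept: float = 38.0
    depth: int = 60000
    noise_sd_log: float = 0.4
    seed: int = 0
    # physicochemistry (bare-group means per region)
    ph_region_means: Sequence[float] = (7.71, 7.81, 7.96)
    om_region_means: Sequence[float] = (132.65, 169.32, 19.87)
    cat_region_means: Sequence[float] = (4.07, 3.52, 2.39)
    cat_vegetation_multiplier: float = 1.2
    an_region_means: Sequence[float] = (50.37, 47.48, 41.25)
    ap_region_means: Sequence[float] = (7.19, 7.79, 4.05)
    tph_region_means: Sequence[float] = (5.69, 5.88, 1.74)
    tph_vegetation_multiplier: float = 0.45

    def __post_init__(self):
        if self.n_regions < 1 or self.samples_per_cell < 1:
            raise ConfigurationError("region and per-cell sample counts must be >= 1")
        if self.n_genera < 1 or self.n_guilds < 1 or self.depth < 1:
            raise ConfigurationError("n_genera, n_guilds and depth must be >= 1")
        if self.n_genera < self.n_guilds:
            raise ConfigurationError("n_genera must be >= n_guilds")
        for name in ("vegetation_ec_multiplier", "vegetation_pah_multiplier"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        for name in ("guild_loading", "guild_loading_vegetated"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        for name in ("gene_mean_16s", "gene_mean_rhd", "gene_mean_c12o"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.noise_sd_log < 0:
            raise ConfigurationError("noise_sd_log must be >= 0")
        for name in (
            "ec_region_means", "pah_region_means", "ph_region_means",
            "om_region_means", "cat_region_means", "an_region_means",
            "ap_region_means", "tph_region_means",
        ):
            if len(getattr(self, name)) != self.n_regions:
                raise ConfigurationError(
                    f"{name} must have one entry per region ({self.n_regions})"
                )

    @property
    def regions(self) -> tuple[str, ...]:
        if self.n_regions <= len(_DEFAULT_REGIONS):
            return _DEFAULT_REGIONS[: self.n_regions]
        return tuple(
            f"G{chr(ord('A') + i)}" for i in range(self.n_regions)
        )

    def resolved_niche_slopes(self) -> np.ndarray:
        """Per-genus EC slopes: user-supplied, or a salt-sensitive clade.

        By default the first ``niche_clade_fraction`` of genera form a clade
        with a common negative EC response; the rest are EC-neutral.
        """
        if self.niche_ec_slopes is not None:
            slopes = np.asarray(self.niche_ec_slopes, dtype=float)
            if slopes.shape != (self.n_genera,):
                raise ConfigurationError(
                    f"niche_ec_slopes must have length n_genera={self.n_genera}"
                )
            return slopes
        slopes = np.zeros(self.n_genera)
        n_clade = int(round(self.niche_clade_fraction * self.n_genera))
        slopes[:n_clade] = self.niche_clade_slope
        return slopes

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass(frozen=True)
class StudyDataset:
    """A complete synthetic study bundle plus the generating truth record."""

    metadata: pd.DataFrame
    pah: pd.DataFrame
    abundance: AbundanceTable
    genes: pd.DataFrame
    standards: pd.DataFrame
    truth: dict


def _lognorm1(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise; exactly 1 when sigma = 0."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(sigma * rng.standard_normal(size) - sigma**2 / 2.0)


def generate_metadata(config: StudyConfig, seed: int | None = None) -> pd.DataFrame:
    """Sample metadata for the full region × cover design.

    Returns a DataFrame indexed by sample id with columns ``region, cover,
    pH, EC, OM, CAT, AN, AP, TPH`` (units as in the bundled field summary).
    """
    seed = config.seed if seed is None else seed
    rng = child_rng(seed, "metadata")
    sigma = config.noise_sd_log
    rows = []
    for ri, region in enumerate(config.regions):
        for cover in (COVER_VEGETATED, COVER_BARE):
            veg = cover == COVER_VEGETATED
            n = config.samples_per_cell
            ec = (
                config.ec_region_means[ri]
                * (config.vegetation_ec_multiplier if veg else 1.0)
                * _lognorm1(rng, sigma, n)
            )
            ph = config.ph_region_means[ri] + 0.4 * sigma * rng.standard_normal(n)
            om = config.om_region_means[ri] * _lognorm1(rng, sigma, n)
            cat = (
                config.cat_region_means[ri]
                * (config.cat_vegetation_multiplier if veg else 1.0)
                * _lognorm1(rng, 0.5 * sigma, n)
            )
            an = config.an_region_means[ri] * _lognorm1(rng, 0.5 * sigma, n)
            ap = config.ap_region_means[ri] * _lognorm1(rng, 0.5 * sigma, n)
            tph = (
                config.tph_region_means[ri]
                * (config.tph_vegetation_multiplier if veg else 1.0)
                * _lognorm1(rng, sigma, n)
            )
            for i in range(n):
                rows.append(
                    {
                        "sample_id": f"{region}{'V' if veg else 'B'}{i + 1:02d}",
                        "region": region,
                        "cover": cover,
                        "pH": ph[i],
                        "EC": max(ec[i], 0.0),
                        "OM": om[i],
                        "CAT": cat[i],
                        "AN": an[i],
                        "AP": ap[i],
                        "TPH": tph[i],
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_pah_profiles(
    metadata: pd.DataFrame, config: StudyConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-sample 16-congener concentration table (samples × congeners).

    Region totals are partitioned into LMW/HMW fractions and then across
    congeners by fixed weights with per-congener lognormal jitter, rescaled so
    the congeners sum exactly to the sample's total.
    """
    if metadata.empty:
        raise ValueError("metadata is empty")
    seed = config.seed if seed is None else seed
    rng = child_rng(seed, "pah")
    sigma = config.noise_sd_log
    region_mean = dict(zip(config.regions, config.pah_region_means))
    lmw_codes = list(_LMW_WEIGHTS)
    hmw_codes = list(_HMW_WEIGHTS)
    w_lmw = np.array([_LMW_WEIGHTS[c] for c in lmw_codes])
    w_hmw = np.array([_HMW_WEIGHTS[c] for c in hmw_codes])
    out = {}
    for sample_id, row in metadata.iterrows():
        if row["region"] not in region_mean:
            raise KeyError(
                f"sample {sample_id!r}: unknown region label {row['region']!r}"
            )
        veg = row["cover"] == COVER_VEGETATED
        tpah = (
            region_mean[row["region"]]
            * (config.vegetation_pah_multiplier if veg else 1.0)
            * float(_lognorm1(rng, sigma, 1)[0])
        )
        lmw_total = tpah * config.lmw_fraction
        hmw_total = tpah - lmw_total
        jl = w_lmw * _lognorm1(rng, sigma, len(w_lmw))
        jh = w_hmw * _lognorm1(rng, sigma, len(w_hmw))
        conc = dict(zip(lmw_codes, lmw_total * jl / jl.sum()))
        conc.update(zip(hmw_codes, hmw_total * jh / jh.sum()))
        out[sample_id] = conc
    df = pd.DataFrame.from_dict(out, orient="index")
    return df.reindex(columns=list(pahmod.CONGENERS)).rename_axis("sample_id")


def _lineages(config: StudyConfig) -> pd.Series:
    """Fabricated 6-rank lineages; each guild maps to one phylum, and every
    13th genus is left unclassified at genus rank."""
    names, ids = [], []
    for g in range(config.n_genera):
        guild = g % config.n_guilds
        phylum = _PHYLA[guild % len(_PHYLA)]
        genus = "" if g % 13 == 12 else f"Genus_{g + 1:03d}"
        ids.append(f"taxon_{g + 1:03d}")
        names.append(
            format_lineage(
                {
                    "kingdom": "Bacteria",
                    "phylum": phylum,
                    "class": f"{phylum}_class",
                    "order": f"{phylum}_order_{guild + 1}",
                    "family": f"{phylum}_family_{guild + 1}",
                    "genus": genus,
                }
            )
        )
    return pd.Series(names, index=pd.Index(ids, name="taxon_id"))


def generate_abundance_table(
    metadata: pd.DataFrame, config: StudyConfig, seed: int | None = None
) -> AbundanceTable:
    """Genus count table with niche (EC) responses and correlated guilds.

    Per genus g and sample s, log abundance is
    ``baseline_g + slope_g·EC_s + λ_s·F_{guild(g),s} + σ_s·ε`` with F a shared
    standard-normal factor per (guild, sample) and λ the cover-specific guild
    loading; exponentiated scores are turned into counts by a multinomial
    draw of the fixed per-sample depth.

    The idiosyncratic noise scale σ_s is chosen per sample so the total
    latent variance λ_s² + σ_s² is the same in every sample
    (max(λ)² + noise_sd_log²). The vegetated/bare loading contrast therefore
    changes only the correlation structure between genera — not per-sample
    evenness — keeping the diversity gradient attributable to the EC niche
    responses alone.
    """
    seed = config.seed if seed is None else seed
    rng = child_rng(seed, "abundance")
    n_g, n_s = config.n_genera, len(metadata)
    if config.depth < n_g:
        warnings.warn(
            f"sequencing depth {config.depth} < n_genera {n_g}: "
            "many genera will be unobserved",
            stacklevel=2,
        )
    baseline = rng.normal(0.0, 1.0, size=n_g)
    slopes = config.resolved_niche_slopes()
    guild = np.arange(n_g) % config.n_guilds
    ec = metadata["EC"].to_numpy(dtype=float)
    lam = np.where(
        metadata["cover"].to_numpy() == COVER_VEGETATED,
        config.guild_loading_vegetated,
        config.guild_loading,
    )
    factors = rng.standard_normal((config.n_guilds, n_s))
    eps = rng.standard_normal((n_g, n_s))
    total_var = (
        max(config.guild_loading, config.guild_loading_vegetated) ** 2
        + config.noise_sd_log**2
    )
    noise_sd = np.sqrt(np.maximum(total_var - lam**2, 0.0))
    z = (
        baseline[:, None]
        + slopes[:, None] * ec[None, :]
        + lam[None, :] * factors[guild, :]
        + noise_sd[None, :] * eps
    )
    z -= z.max(axis=0, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=0, keepdims=True)
    counts = np.empty((n_g, n_s), dtype=np.int64)
    for j in range(n_s):
        counts[:, j] = rng.multinomial(config.depth, p[:, j])
    tax = _lineages(config)
    data = pd.DataFrame(counts, index=tax.index, columns=metadata.index)
    return AbundanceTable(data=data, taxonomy=tax, mode="counts")


def generate_standards(config: StudyConfig) -> pd.DataFrame:
    """Noiseless dilution series (10³…10⁸ copies) on the configured curve."""
    rows = []
    for gene in ("16S", "PAH-RHDa", "C12O"):
        for lg in range(3, 9):
            rows.append(
                {
                    "gene": gene,
                    "log10_copies": float(lg),
                    "ct": config.qpcr_curve_slope * lg + config.qpcr_curve_intercept,
                }
            )
    return pd.DataFrame(rows)


def generate_gene_quant(
    metadata: pd.DataFrame, config: StudyConfig, seed: int | None = None
) -> pd.DataFrame:
    """Absolute gene copy numbers plus synthetic Ct values.

    log10 copies = log10(configured mean) + EC slope term + vegetation offset
    + noise, mean-calibrated so the linear-scale design mean equals the
    configured mean exactly. Ct values are emitted from the configured
    standard curve for round-trip testing of the quantification module.
    """
    if metadata.empty:
        raise ValueError("metadata is empty")
    seed = config.seed if seed is None else seed
    rng = child_rng(seed, "genes")
    sigma10 = config.noise_sd_log
    ec = metadata["EC"].to_numpy(dtype=float)
    is_veg = (metadata["cover"].to_numpy() == COVER_VEGETATED).astype(float)
    raw = config.gene_ec_slope * ec + config.gene_vegetation_offset * is_veg
    # design-mean calibration: E[mean_i 10^(raw_i + e_i)] / M = 1 exactly
    jensen = np.exp((np.log(10.0) * sigma10) ** 2 / 2.0)
    M = float(np.mean(10.0**raw)) * jensen
    means = {
        "16S": config.gene_mean_16s,
        "PAH-RHDa": config.gene_mean_rhd,
        "C12O": config.gene_mean_c12o,
    }
    rows = []
    for gene, mean in means.items():
        e = sigma10 * rng.standard_normal(len(metadata)) if sigma10 > 0 else 0.0
        copies = mean * 10.0 ** (raw + e) / M
        ct = config.qpcr_curve_slope * np.log10(copies) + config.qpcr_curve_intercept
        for i, sample_id in enumerate(metadata.index):
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": gene,
                    "copies_per_g": float(copies[i]),
                    "ct": float(ct[i]),
                }
            )
    return pd.DataFrame(rows)


def generate_study(config: StudyConfig | None = None, seed: int | None = None) -> StudyDataset:
    """Generate a full study: metadata, PAHs, abundances, gene quantities."""
    config = config or StudyConfig()
    seed = config.seed if seed is None else seed
    metadata = generate_metadata(config, seed)
    return StudyDataset(
        metadata=metadata,
        pah=generate_pah_profiles(metadata, config, seed),
        abundance=generate_abundance_table(metadata, config, seed),
        genes=generate_gene_quant(metadata, config, seed),
        standards=generate_standards(config),
        truth={"config": config.to_dict(), "seed": int(seed)},
    )
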