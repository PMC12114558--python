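"""Taxonomic aggregation, alpha diversity, Bray–Curtis distances, and NMDS.

The central container is :class:`AbundanceTable`, a taxa × samples matrix with
a 6-rank lineage per taxon (kingdom…genus, ``k__;p__;c__;o__;f__;g__``
strings) and a mode flag distinguishing raw counts from relative abundances.

Alpha diversity follows the usual amplicon conventions: bias-corrected Chao1
richness from singleton/doubleton counts, and Shannon entropy in nats
(natural log; base configurable). Beta diversity is Bray–Curtis, ordinated by
non-metric multidimensional scaling (NMDS) minimising Kruskal stress-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from ._seeds import child_seed

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__")))

MODE_COUNTS = "counts"
MODE_RELATIVE = "relative"


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ``k__...;p__...;...;g__...`` string into rank → name.

    Empty or missing levels come back as ``""``.
    """
    out = dict.fromkeys(RANKS, "")
    for part in str(lineage).split(";"):
        part = part.strip()
        for rank, prefix in _RANK_PREFIX.items():
            if part.startswith(prefix):
                out[rank] = part[len(prefix):]
    return out


def format_lineage(names: dict[str, str]) -> str:
    return ";".join(_RANK_PREFIX[r] + names.get(r, "") for r in RANKS)


@dataclass(frozen=True)
class AbundanceTable:
    """Taxa × samples abundance matrix with lineages.

    Parameters
    ----------
    data : DataFrame
        Rows are taxa (unique ids), columns are samples. Counts or relative
        abundances per ``mode``.
    taxonomy : Series
        Lineage string per taxon, aligned with ``data.index``.
    mode : str
        ``"counts"`` or ``"relative"``; relative columns must sum to 1
        unless the table is marked as a ``subset`` (e.g. after taxon
        filtering), in which case they may sum to less.
    """

    data: pd.DataFrame
    taxonomy: pd.Series
    mode: str = MODE_COUNTS
    subset: bool = False

    def __post_init__(self):
        if self.mode not in (MODE_COUNTS, MODE_RELATIVE):
            raise ValueError(f"mode must be counts|relative, got {self.mode!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon id(s): {dups}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance table contains negative entries")
        if self.mode == MODE_RELATIVE and not self.subset:
            sums = self.data.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-mode columns must each sum to 1")
        tax = self.taxonomy.reindex(self.data.index)
        object.__setattr__(self, "taxonomy", tax)

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    def lineage_frame(self) -> pd.DataFrame:
        """Per-taxon rank table parsed from the lineage strings."""
        return pd.DataFrame(
            [parse_lineage(s) for s in self.taxonomy], index=self.data.index
        )


def aggregate(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum taxa sharing the same label at ``rank``.

    Taxa unassigned at that rank pool under ``"unclassified"``. Mode is
    preserved; column sums are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
    labels = table.lineage_frame()[rank].replace("", "unclassified").fillna(
        "unclassified"
    )
    grouped = table.data.groupby(labels.to_numpy()).sum()
    grouped.index.name = rank
    tax = pd.Series(
        [format_lineage({rank: lab}) for lab in grouped.index], index=grouped.index
    )
    return AbundanceTable(data=grouped, taxonomy=tax, mode=table.mode)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalise each sample column to proportions summing to 1."""
    if table.mode == MODE_RELATIVE:
        return table
    totals = table.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample column(s): {zero}")
    return replace(table, data=table.data / totals, mode=MODE_RELATIVE)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate from one sample's counts.

    S_obs + F1·(F1−1) / (2·(F2+1)), with F1/F2 the singleton and doubleton
    counts. Defined even when F2 = 0; equals S_obs whenever F1 ≤ 1. Requires
    integer counts — the estimator is undefined on relative abundances.
    """
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("empty count vector")
    if not np.allclose(c, np.round(c)) or (c < 0).any():
        raise ValueError("chao1 requires nonnegative integer counts")
    c = np.round(c).astype(np.int64)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(abundances, base: float | None = None) -> float:
    """Shannon entropy −Σ p_i log p_i of one sample (natural log by default)."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    total = a.sum()
    if total <= 0:
        raise ValueError("shannon undefined on an all-zero sample")
    p = a[a > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def diversity_table(table: AbundanceTable, base: float | None = None) -> pd.DataFrame:
    """Observed richness, Chao1 and Shannon for each sample.

    Chao1 requires a counts-mode table; in relative mode it is reported as NaN.
    """
    rows = []
    counts_mode = table.mode == MODE_COUNTS
    for s in table.samples:
        col = table.data[s].to_numpy()
        rows.append(
            {
                "sample_id": s,
                "observed_richness": int((col > 0).sum()),
                "chao1": chao1(col) if counts_mode else np.nan,
                "shannon": shannon(col, base=base),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample × sample Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y).

    A pair of all-zero samples has no defined dissimilarity; it is reported
    as 0 with a warning.
    """
    X = table.data.to_numpy(dtype=float).T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(X, metric="braycurtis"))
    if zero_rows.size >= 2:
        warnings.warn(
            "all-zero sample pair(s); their Bray-Curtis distance is set to 0",
            stacklevel=2,
        )
    d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=table.samples, columns=table.samples)


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS configuration with its final Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool
    seed: int | None = None


def kruskal_stress(distances: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Disparities are the isotonic (monotone, ties-averaged) regression of the
    configuration distances on the dissimilarities; stress-1 is
    sqrt(Σ(d − d̂)² / Σ d²) over the upper off-diagonal pairs.
    """
    D = np.asarray(distances, dtype=float)
    iu = np.triu_indices_from(D, k=1)
    diss = D[iu]
    conf = squareform(pdist(np.asarray(coords, dtype=float)))[iu]
    disp = IsotonicRegression().fit_transform(diss, conf)
    denom = float((conf**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((conf - disp) ** 2).sum() / denom))


def nmds(
    distances,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a distance matrix.

    Alternates monotone regression of configuration distances on
    dissimilarity ranks with SMACOF configuration updates; the best of
    ``n_restarts`` random initialisations is kept. The reported stress is
    Kruskal stress-1 recomputed from the returned configuration.
    """
    if isinstance(distances, pd.DataFrame):
        labels = distances.index
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        labels = pd.RangeIndex(D.shape[0])
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distances must be a symmetric square matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")

    streams = child_seed(seed, "nmds").spawn(n_restarts)
    best = None
    for ss in streams:
        rng = np.random.default_rng(ss)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _, n_iter = smacof(
                D,
                metric=False,
                n_components=k,
                init=rng.standard_normal((n, k)),
                n_init=1,
                max_iter=max_iter,
                eps=1e-9,
                normalized_stress=True,
                random_state=0,
                return_n_iter=True,
            )
        stress = kruskal_stress(D, coords)
        if best is None or stress < best[0]:
            best = (stress, coords, n_iter)
    stress, coords, n_iter = best
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=labels, columns=[f"NMDS{i + 1}" for i in range(k)]
        ),
        stress=kruskal_stress(D, coords),
        n_restarts=n_restarts,
        converged=bool(n_iter < max_iter),
        seed=seed,
    )
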