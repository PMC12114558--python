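"""qPCR standard curves and absolute gene quantification.

Quantifies 16S rRNA (total bacteria), PAH-RHDα (ring-hydroxylating
dioxygenase alpha subunit, the initial PAH oxidation step) and C12O
(catechol 1,2-dioxygenase, downstream ring cleavage) gene copies per gram of
dry soil from cycle-threshold (Ct) values.

The standard curve is the ordinary least-squares fit
Ct = slope·log10(copies) + intercept over a dilution series; amplification
efficiency is 10^(−1/slope) − 1 (a perfect doubling per cycle gives slope
−1/log10(2) ≈ −3.3219 and efficiency 1). Extraction normalisation (soil mass,
elution volume, template dilution) collapses into a single multiplicative
``extraction_factor`` converting copies-in-reaction to copies per gram;
its default of 1 is a deliberate "no normalisation applied" stance and is
logged once per quantification call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENES = ("16S", "PAH-RHDa", "C12O")


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line Ct = slope·log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    ct_range: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.slope < 0:
            raise ValueError(
                f"standard-curve slope must be negative (got {self.slope}); "
                "Ct decreases with template amount in a valid assay"
            )


def fit_standard_curve(log10_copies, ct) -> StandardCurve:
    """Fit a standard curve to a dilution series (≥ 3 distinct points)."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size != y.size:
        raise ValueError("log10_copies and ct must have equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 dilution points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10_copies; dilutions must differ")
    if np.ptp(y) == 0:
        raise ValueError("constant Ct across dilutions; degenerate curve")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(10 ** (-1.0 / slope) - 1.0),
        ct_range=(float(y.min()), float(y.max())),
    )


def quantify_copies(
    ct: float,
    curve: StandardCurve,
    extraction_factor: float = 1.0,
) -> tuple[float, bool]:
    """Invert the curve: copies·g⁻¹ = 10^((ct − intercept)/slope) × factor.

    Returns ``(copies_per_g, extrapolated)``; ``extrapolated`` flags Ct values
    outside the fitted dilution range (when the curve records one).
    """
    if extraction_factor == 1.0:
        logger.info(
            "extraction_factor=1: reporting copies in-reaction as copies per gram; "
            "supply soil-mass/elution normalisation if available"
        )
    copies = 10 ** ((ct - curve.intercept) / curve.slope) * extraction_factor
    extrapolated = False
    if curve.ct_range is not None:
        lo, hi = curve.ct_range
        extrapolated = not (lo <= ct <= hi)
    return float(copies), extrapolated


def quantify_table(
    samples: pd.DataFrame,
    curves: dict[str, StandardCurve],
    extraction_factor: float = 1.0,
) -> pd.DataFrame:
    """Quantify a ``sample_id, gene, ct`` table against per-gene curves.

    Returns the table with ``copies_per_g`` and ``extrapolated`` columns.
    """
    missing = sorted(set(samples["gene"]) - set(curves))
    if missing:
        raise KeyError(f"no standard curve for gene(s): {missing}")
    out = samples.copy()
    vals, flags = [], []
    for _, row in samples.iterrows():
        c, e = quantify_copies(row["ct"], curves[row["gene"]], extraction_factor)
        vals.append(c)
        flags.append(e)
    out["copies_per_g"] = vals
    out["extrapolated"] = flags
    return out


def fit_curves(dilutions: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one curve per gene from a ``gene, log10_copies, ct`` table."""
    return {
        gene: fit_standard_curve(grp["log10_copies"], grp["ct"])
        for gene, grp in dilutions.groupby("gene")
    }
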