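"""PAH profile summaries, BaP toxic equivalents, and contamination classes.

Works on profiles of the 16 US-EPA priority polycyclic aromatic hydrocarbons
(PAHs), reported as mg per kg dry soil. Profiles are partitioned into
low-molecular-weight (LMW, 2–3 aromatic rings) and high-molecular-weight
(HMW, 4–6 rings) fractions; toxicity is summarised as the benzo[a]pyrene
toxic-equivalent concentration TEQ_BaP = Σ_i c_i · TEF_i, where TEF_i is the
congener's potency relative to BaP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: The 16 priority congeners, in conventional elution order.
CONGENERS = (
    "NAP", "ACY", "ACE", "FLU", "PHE", "ANT",
    "FLA", "PYR", "BaA", "CHR", "BbF", "BkF",
    "BaP", "IndP", "DahA", "BghiP",
)

#: 2–3-ring congeners (the LMW fraction); the remaining ten are HMW.
LMW_CONGENERS = ("NAP", "ACY", "ACE", "FLU", "PHE", "ANT")
HMW_CONGENERS = tuple(c for c in CONGENERS if c not in LMW_CONGENERS)

#: Default toxic equivalency factors (Nisbet & LaGoy convention, BaP = 1).
DEFAULT_TEF: dict[str, float] = {
    "NAP": 0.001, "ACY": 0.001, "ACE": 0.001, "FLU": 0.001,
    "PHE": 0.001, "ANT": 0.01, "FLA": 0.001, "PYR": 0.001,
    "BaA": 0.1, "CHR": 0.01, "BbF": 0.1, "BkF": 0.1,
    "BaP": 1.0, "IndP": 0.1, "DahA": 1.0, "BghiP": 0.01,
}

#: Four-tier total-PAH contamination scheme (mg·kg⁻¹ boundaries).
#: "heavily" requires tpah strictly above 1.00.
SCHEME_FOUR_TIER = "four-tier"
#: Two-tier scheme collapsing everything ≤ 1.00 to "slightly polluted".
SCHEME_TWO_TIER = "two-tier"

CLASS_UNPOLLUTED = "unpolluted"
CLASS_WEAKLY = "weakly polluted"
CLASS_CONTAMINATED = "contaminated"
CLASS_HEAVILY = "heavily polluted"
CLASS_SLIGHTLY = "slightly polluted"


class PahValidationError(ValueError):
    """Raised on negative concentrations or unknown congener codes."""


@dataclass(frozen=True)
class PahProfile:
    """Per-sample concentrations of the 16 priority PAHs (mg·kg⁻¹ dry soil).

    Missing congeners are filled with 0 (with a warning); unknown codes and
    negative concentrations are rejected.
    """

    sample_id: str
    concentrations: Mapping[str, float]

    def __post_init__(self):
        conc = dict(self.concentrations)
        unknown = sorted(set(conc) - set(CONGENERS))
        if unknown:
            raise PahValidationError(
                f"sample {self.sample_id!r}: unknown congener code(s) {unknown}"
            )
        for code, value in conc.items():
            if value < 0:
                raise PahValidationError(
                    f"sample {self.sample_id!r}: negative concentration for {code}"
                )
        missing = [c for c in CONGENERS if c not in conc]
        if missing:
            warnings.warn(
                f"sample {self.sample_id!r}: congener(s) {missing} absent, treated as 0",
                stacklevel=2,
            )
            for c in missing:
                conc[c] = 0.0
        object.__setattr__(self, "concentrations", conc)

    def __getitem__(self, code: str) -> float:
        return self.concentrations[code]


@dataclass(frozen=True)
class TefTable:
    """Toxic equivalency factors relative to benzo[a]pyrene (TEF(BaP) = 1)."""

    tefs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TEF))

    def __post_init__(self):
        tefs = dict(self.tefs)
        if tefs.get("BaP") != 1.0:
            raise PahValidationError("TEF table must have TEF(BaP) = 1")
        bad = {c: v for c, v in tefs.items() if v <= 0}
        if bad:
            raise PahValidationError(f"TEFs must be positive, got {bad}")
        object.__setattr__(self, "tefs", tefs)

    @classmethod
    def from_csv(cls, path) -> "TefTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["congener"], df["tef"].astype(float))))


@dataclass(frozen=True)
class PahSummary:
    """LMW/HMW/total PAH and TEQ_BaP summary for one sample (mg·kg⁻¹)."""

    sample_id: str
    tpah: float
    lmw: float
    hmw: float
    teq_bap: float | None = None
    contamination_class: str | None = None


def summarize_profile(profile: PahProfile) -> PahSummary:
    """Partition a 16-congener profile into LMW, HMW and total PAH sums."""
    lmw = sum(profile[c] for c in LMW_CONGENERS)
    hmw = sum(profile[c] for c in HMW_CONGENERS)
    return PahSummary(sample_id=profile.sample_id, tpah=lmw + hmw, lmw=lmw, hmw=hmw)


def teq_bap(profile: PahProfile, tef: TefTable | None = None) -> float:
    """TEF-weighted toxic equivalent Σ c_i·TEF_i (mg BaP-equivalent per kg).

    A nonzero congener missing from the TEF table is an error — silently
    weighting it by zero would understate toxicity.
    """
    tef = tef or TefTable()
    missing = [c for c in CONGENERS if profile[c] > 0 and c not in tef.tefs]
    if missing:
        raise PahValidationError(
            f"sample {profile.sample_id!r}: nonzero congener(s) {missing} "
            "have no TEF entry"
        )
    return sum(profile[c] * tef.tefs[c] for c in CONGENERS if profile[c] > 0)


def classify_contamination(tpah: float, scheme: str = SCHEME_FOUR_TIER) -> str:
    """Map a total-PAH concentration to a contamination class.

    Four-tier boundaries at 0.2 / 0.6 / 1.0 mg·kg⁻¹; "heavily polluted" is
    strictly above 1.00. The two-tier scheme collapses the lower three tiers
    into "slightly polluted".
    """
    if tpah < 0:
        raise PahValidationError(f"tpah must be nonnegative, got {tpah}")
    if scheme not in (SCHEME_FOUR_TIER, SCHEME_TWO_TIER):
        raise ValueError(
            f"unknown scheme {scheme!r}; valid: {SCHEME_FOUR_TIER}, {SCHEME_TWO_TIER}"
        )
    if tpah > 1.0:
        return CLASS_HEAVILY
    if scheme == SCHEME_TWO_TIER:
        return CLASS_SLIGHTLY
    if tpah > 0.6:
        return CLASS_CONTAMINATED
    if tpah > 0.2:
        return CLASS_WEAKLY
    return CLASS_UNPOLLUTED


def summarize_table(
    profiles: pd.DataFrame,
    tef: TefTable | None = None,
    scheme: str = SCHEME_FOUR_TIER,
) -> pd.DataFrame:
    """Summarise a samples × congeners concentration table.

    Returns a DataFrame indexed by sample with columns
    ``lmw, hmw, tpah, teq_bap, contamination_class``.
    """
    rows = []
    for sample_id, row in profiles.iterrows():
        prof = PahProfile(str(sample_id), row.to_dict())
        s = summarize_profile(prof)
        rows.append(
            {
                "sample_id": s.sample_id,
                "lmw": s.lmw,
                "hmw": s.hmw,
                "tpah": s.tpah,
                "teq_bap": teq_bap(prof, tef),
                "contamination_class": classify_contamination(s.tpah, scheme),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def check_summary_consistency(
    summary: pd.DataFrame, tolerance: float = 0.01
) -> pd.Index:
    """Flag ingested summary rows where |lmw + hmw − tpah| > tolerance.

    Published group-mean tables occasionally carry rounding or transcription
    slips; these are surfaced as a warning on ingest, not an error.
    """
    gap = (summary["lmw"] + summary["hmw"] - summary["tpah"]).abs()
    bad = summary.index[gap > tolerance + 1e-9]  # epsilon: gaps AT tolerance pass
    if len(bad):
        warnings.warn(
            f"summary rows {list(bad)} violate lmw + hmw = tpah by more than "
            f"{tolerance} mg/kg",
            stacklevel=2,
        )
    return bad
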