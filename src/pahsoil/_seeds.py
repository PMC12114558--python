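"""Deterministic seed expansion.

A single study-level seed is expanded into independent per-stage streams via
``numpy.random.SeedSequence`` spawn keys, using a fixed stage→index registry.
Stages are therefore independently reproducible: regenerating only the
abundance table from the same study seed yields the same table regardless of
whether the other stages were run.
"""

from __future__ import annotations

import numpy as np

#: Fixed registry of named stages; never reorder, only append.
STAGES = (
    "metadata",
    "pah",
    "abundance",
    "genes",
    "nmds",
    "mantel",
    "modules",
    "null",
    "pipeline",
)

_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}


def child_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Return the SeedSequence for a named stage under a study seed."""
    try:
        idx = _STAGE_INDEX[stage]
    except KeyError:
        raise KeyError(f"unknown stage {stage!r}; known stages: {STAGES}") from None
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(idx,))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage under a study seed."""
    return np.random.default_rng(child_seed(seed, stage))


def child_int(seed: int, stage: str) -> int:
    """A 31-bit integer seed for libraries that want a plain int."""
    return int(child_rng(seed, stage).integers(0, 2**31 - 1))
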