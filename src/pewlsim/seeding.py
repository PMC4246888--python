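"""Deterministic per-stage random streams derived from one master seed.

Each simulation stage consumes its own child stream of the master
``SeedSequence`` so that rerunning a single stage (e.g. regenerating the
predictor for an existing cohort) reproduces exactly what the full
pipeline would have produced. Stream order is fixed: population (sex
draws, then the height/log-weight draws), PEWL residuals, predictor
residuals.
"""

from __future__ import annotations

import numpy as np

STAGES = ("population", "pewl", "predictor")


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Return the generator for a named stage under ``master_seed``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return np.random.default_rng(children[STAGES.index(stage)])


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed or generator into a ``numpy`` Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
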