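"""Trial designs for the category-specific repetition/adaptation paradigm.

Stimuli from two categories (human faces ``F`` and cat faces ``C``) are shown
in blocks of three kinds: uniform human, uniform cat, and alternating.  Probes
preceded by a same-category adaptor come from uniform blocks (conditions FF and
CC); alternating blocks yield the between-category conditions (FC: human probe
after cat adaptor; CF: cat probe after human adaptor).  Stimulus duration is
500 ms with a fixed 1000-ms onset-to-onset interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["DesignSpec", "make_design", "BLOCK_TYPES", "TRIALS_PER_BLOCK"]

BLOCK_TYPES = ("uniform_human", "uniform_cat", "alternating")

#: Probe/adaptor condition code implied by (block type, trial category):
#: uniform blocks repeat one category (FF, CC); in alternating blocks the
#: adaptor is always the other category (FC: human probe, cat adaptor;
#: CF: cat probe, human adaptor).
CONDITION_OF_TRIAL = {
    ("uniform_human", "human"): "FF",
    ("uniform_cat", "cat"): "CC",
    ("alternating", "human"): "FC",
    ("alternating", "cat"): "CF",
}

#: Block length (number of trials) by participant group.
TRIALS_PER_BLOCK = {"infant": 24, "adult": 120}

STIMULUS_DURATION_MS = 500
ONSET_TO_ONSET_MS = 1000


@dataclass(frozen=True)
class DesignSpec:
    """Ordered block structure of one recording session."""

    group: str
    block_sequence: tuple[str, ...]
    trials_per_block: int
    stimulus_duration_ms: int = STIMULUS_DURATION_MS
    onset_to_onset_ms: int = ONSET_TO_ONSET_MS
    initial_block_type: int = 0

    def __post_init__(self) -> None:
        if self.group not in TRIALS_PER_BLOCK:
            raise ValueError(f"unknown group {self.group!r}")
        if self.trials_per_block != TRIALS_PER_BLOCK[self.group]:
            raise ValueError(
                f"{self.group} blocks contain {TRIALS_PER_BLOCK[self.group]} trials"
            )
        if self.onset_to_onset_ms != ONSET_TO_ONSET_MS:
            raise ValueError("onset-to-onset interval is fixed at 1000 ms")
        bad = set(self.block_sequence) - set(BLOCK_TYPES)
        if bad:
            raise ValueError(f"unknown block types {bad}")

    @property
    def n_trials(self) -> int:
        return len(self.block_sequence) * self.trials_per_block


def make_design(
    group: str,
    n_iterations: int,
    initial_block_type: int = 0,
    seed: int | None = None,
) -> tuple[DesignSpec, pd.DataFrame]:
    """Build a counterbalanced block sequence and its per-trial table.

    Each iteration presents one block of every type; ``initial_block_type``
    (0, 1 or 2) rotates which type opens the session, implementing the
    between-participant counterbalancing.  Uniform blocks contain a single
    category; alternating blocks strictly alternate categories trial to
    trial, starting with human on even block repetitions and cat on odd ones
    so both categories lead equally often.

    ``seed`` is accepted for interface symmetry with the stochastic
    generator stages; the trial table itself is deterministic.

    Returns
    -------
    (DesignSpec, DataFrame)
        The trial table has one row per trial with columns ``trial``,
        ``block_id``, ``block_type``, and ``category`` ("human"/"cat").
    """
    if group not in TRIALS_PER_BLOCK:
        raise ValueError(f"unknown group {group!r}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if initial_block_type not in (0, 1, 2):
        raise ValueError("initial_block_type must be 0, 1, or 2")

    tpb = TRIALS_PER_BLOCK[group]
    sequence: list[str] = []
    for _ in range(n_iterations):
        for k in range(3):
            sequence.append(BLOCK_TYPES[(initial_block_type + k) % 3])
    spec = DesignSpec(
        group=group,
        block_sequence=tuple(sequence),
        trials_per_block=tpb,
        initial_block_type=initial_block_type,
    )

    rows = []
    trial = 0
    n_alternating_seen = 0
    for block_id, btype in enumerate(sequence):
        if btype == "uniform_human":
            cats = ["human"] * tpb
        elif btype == "uniform_cat":
            cats = ["cat"] * tpb
        else:
            first = ("human", "cat") if n_alternating_seen % 2 == 0 else ("cat", "human")
            cats = [first[i % 2] for i in range(tpb)]
            n_alternating_seen += 1
        for cat in cats:
            rows.append((trial, block_id, btype, cat))
            trial += 1
    table = pd.DataFrame(rows, columns=["trial", "block_id", "block_type", "category"])
    return spec, table
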