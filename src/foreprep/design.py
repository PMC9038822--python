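"""Trial-sequence generation for a two-phase variable-foreperiod experiment.

The experiment presents, on each trial, a warning stimulus (S1: a unique
image of one of two categories) followed after a variable foreperiod (FP)
by a lateralized target (S2) requiring a speeded left/right response.
During the Acquisition phase each S1 category is paired with a biased FP
distribution -- exponential (mostly short FPs) for one category,
anti-exponential (mostly long FPs) for the other.  In the Transfer phase
both categories switch to a uniform FP distribution.

:func:`generate_design` emits, per participant, the exact per-block trial
multiset (FP x S1 type x S2 side counts are deterministic, only the order
and the FP-side pairing are randomized) as a tidy :class:`pandas.DataFrame`
of trial "skeletons": everything except the simulated response columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

PHASE_ACQUISITION = "Acquisition"
PHASE_TRANSFER = "Transfer"

#: Columns of a design skeleton, in output order.
SKELETON_COLUMNS = (
    "participant",
    "block",
    "trial_index",
    "phase",
    "s1_category",
    "s1_type",
    "s1_image_id",
    "fp_ms",
    "s2_side",
    "iti_ms",
)


class DesignError(ValueError):
    """An internally inconsistent design specification."""


@dataclass(frozen=True)
class DesignSpec:
    """Block structure and per-condition trial counts of the experiment.

    Defaults reproduce the study design: 6 Acquisition blocks + 2 Transfer
    blocks of 120 trials each; FPs of 300/600/900/1200 ms; per Acquisition
    block 32/16/8/4 trials per FP for the exponential S1 type and the exact
    reverse for the anti-exponential type; 15 trials per FP per type in
    Transfer; S2 side balanced within S1 type within every block.
    """

    n_acquisition_blocks: int = 6
    n_transfer_blocks: int = 2
    fp_levels_ms: tuple[int, ...] = (300, 600, 900, 1200)
    exp_counts_per_block: tuple[int, ...] = (32, 16, 8, 4)
    uniform_count_per_fp: int = 15
    categories: tuple[str, str] = ("face", "scene")
    #: Fixed category -> S1-type mapping for every participant.  ``None``
    #: counterbalances across participants: odd participant ids map
    #: ``categories[0]`` to the exponential type, even ids the reverse.
    category_to_type: Mapping[str, str] | None = None
    iti_range_ms: tuple[int, int] = (750, 1500)

    @property
    def anti_counts_per_block(self) -> tuple[int, ...]:
        """Anti-exponential per-FP counts: the exact reverse of the
        exponential counts."""
        return tuple(reversed(self.exp_counts_per_block))

    @property
    def n_blocks(self) -> int:
        return self.n_acquisition_blocks + self.n_transfer_blocks

    @property
    def acquisition_block_size(self) -> int:
        return 2 * sum(self.exp_counts_per_block)

    @property
    def transfer_block_size(self) -> int:
        return 2 * len(self.fp_levels_ms) * self.uniform_count_per_fp

    @property
    def n_trials_per_participant(self) -> int:
        return (
            self.n_acquisition_blocks * self.acquisition_block_size
            + self.n_transfer_blocks * self.transfer_block_size
        )

    def phase_of_block(self, block: int) -> str:
        if not 1 <= block <= self.n_blocks:
            raise ValueError(f"block {block} outside 1..{self.n_blocks}")
        return PHASE_ACQUISITION if block <= self.n_acquisition_blocks else PHASE_TRANSFER

    def validate(self) -> None:
        if len(self.fp_levels_ms) < 1:
            raise DesignError("at least one FP level is required")
        if len(set(self.fp_levels_ms)) != len(self.fp_levels_ms):
            raise DesignError("fp_levels_ms must be distinct")
        if len(self.exp_counts_per_block) != len(self.fp_levels_ms):
            raise DesignError(
                "exp_counts_per_block must give one count per FP level "
                f"({len(self.exp_counts_per_block)} counts for "
                f"{len(self.fp_levels_ms)} levels)"
            )
        if any(c < 0 for c in self.exp_counts_per_block) or self.uniform_count_per_fp < 0:
            raise DesignError("trial counts must be non-negative")
        if self.n_acquisition_blocks < 0 or self.n_transfer_blocks < 0:
            raise DesignError("block counts must be non-negative")
        if self.n_blocks == 0:
            raise DesignError("design has no blocks")
        if self.n_acquisition_blocks and sum(self.exp_counts_per_block) == 0:
            raise DesignError("Acquisition blocks have zero trials")
        if self.n_transfer_blocks and self.uniform_count_per_fp == 0:
            raise DesignError("Transfer blocks have zero trials")
        # S2 side is balanced (equal left/right) within each S1 type within
        # each block, which requires an even per-type trial count.
        if self.n_acquisition_blocks and sum(self.exp_counts_per_block) % 2:
            raise DesignError(
                "S2-side balance violated: per-type Acquisition block total "
                f"{sum(self.exp_counts_per_block)} is odd"
            )
        if self.n_transfer_blocks and (
            self.uniform_count_per_fp * len(self.fp_levels_ms)
        ) % 2:
            raise DesignError(
                "S2-side balance violated: per-type Transfer block total "
                f"{self.uniform_count_per_fp * len(self.fp_levels_ms)} is odd"
            )
        if len(self.categories) != 2 or self.categories[0] == self.categories[1]:
            raise DesignError("exactly two distinct S1 categories are required")
        if self.category_to_type is not None:
            if set(self.category_to_type) != set(self.categories) or set(
                self.category_to_type.values()
            ) != {"E", "A"}:
                raise DesignError(
                    "category_to_type must map the two categories onto {'E', 'A'}"
                )
        lo, hi = self.iti_range_ms
        if not 0 < lo <= hi:
            raise DesignError("iti_range_ms must satisfy 0 < lo <= hi")

    def type_mapping(self, participant: int) -> dict[str, str]:
        """Category -> S1-type mapping for one participant (counterbalanced
        across participants unless fixed in the spec)."""
        if self.category_to_type is not None:
            return dict(self.category_to_type)
        first, second = self.categories
        if participant % 2 == 1:
            return {first: "E", second: "A"}
        return {first: "A", second: "E"}


def _per_type_fp_counts(spec: DesignSpec, phase: str, s1_type: str) -> tuple[int, ...]:
    if phase == PHASE_TRANSFER:
        return (spec.uniform_count_per_fp,) * len(spec.fp_levels_ms)
    return spec.exp_counts_per_block if s1_type == "E" else spec.anti_counts_per_block


def generate_design(
    spec: DesignSpec, n_participants: int, seed: int | None = None
) -> pd.DataFrame:
    """Generate trial skeletons for ``n_participants`` participants.

    Within each block the balanced (FP x S1 type x side) multiset is built
    exactly, S2 sides are assigned half left / half right within each S1
    type, and the resulting trial list is jointly permuted.  Every S1 image
    is a unique integer id (each image is seen only once per participant).
    Fully reproducible given ``seed``.
    """
    spec.validate()
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple] = []
    lo, hi = spec.iti_range_ms
    for p in range(1, n_participants + 1):
        mapping = spec.type_mapping(p)
        type_to_cat = {v: k for k, v in mapping.items()}
        trial_index = 0
        image_id = 0
        for block in range(1, spec.n_blocks + 1):
            phase = spec.phase_of_block(block)
            block_rows: list[tuple[str, int, str]] = []
            for s1_type in ("E", "A"):
                counts = _per_type_fp_counts(spec, phase, s1_type)
                fps = np.repeat(spec.fp_levels_ms, counts)
                n_type = len(fps)
                sides = np.array(["left", "right"]).repeat(n_type // 2)
                rng.shuffle(sides)
                for fp, side in zip(fps, sides):
                    block_rows.append((s1_type, int(fp), side))
            order = rng.permutation(len(block_rows))
            itis = rng.integers(lo, hi + 1, size=len(block_rows))
            for iti, idx in zip(itis, order):
                s1_type, fp, side = block_rows[idx]
                trial_index += 1
                image_id += 1
                records.append(
                    (
                        p,
                        block,
                        trial_index,
                        phase,
                        type_to_cat[s1_type],
                        s1_type,
                        image_id,
                        fp,
                        side,
                        int(iti),
                    )
                )
    return pd.DataFrame.from_records(records, columns=SKELETON_COLUMNS)
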