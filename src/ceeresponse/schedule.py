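"""Experimental phase schedule for controlled exposure experiments (CEEs).

A CEE is a before-during-after design: a pre-exposure phase, an exposure
phase (sonar transmission, or silence for controls) and a post-exposure
phase, each typically 10 minutes.  All response variables are analysed on a
common grid of 5 s blocks spanning the three phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PHASES = ("pre", "exp", "post")


@dataclass(frozen=True)
class PhaseSchedule:
    """Contiguous pre/exposure/post phase boundaries on a block grid.

    Times are seconds from CEE start.  Blocks are half-open intervals
    ``[t, t + block_dur)``; every phase duration must be a positive
    multiple of ``block_dur`` so that blocks never straddle a phase
    boundary.
    """

    pre_start: float
    pre_end: float
    exp_start: float
    exp_end: float
    post_start: float
    post_end: float
    block_dur: float = 5.0

    def __post_init__(self) -> None:
        if self.block_dur <= 0:
            raise ValueError("block_dur must be positive")
        bounds = (
            self.pre_start,
            self.pre_end,
            self.exp_start,
            self.exp_end,
            self.post_start,
            self.post_end,
        )
        if self.pre_end != self.exp_start or self.exp_end != self.post_start:
            raise ValueError("phases must be contiguous: pre|exp|post")
        if not (bounds[0] < bounds[1] < bounds[3] < bounds[5]):
            raise ValueError("phases must be ordered pre < exp < post")
        for name, start, end in zip(
            PHASES, bounds[0::2], bounds[1::2], strict=True
        ):
            dur = end - start
            if dur <= 0 or not _is_multiple(dur, self.block_dur):
                raise ValueError(
                    f"{name} phase duration {dur} s is not a positive "
                    f"multiple of block_dur = {self.block_dur} s"
                )

    @property
    def total_duration(self) -> float:
        return self.post_end - self.pre_start

    @property
    def n_blocks(self) -> int:
        return round(self.total_duration / self.block_dur)

    def block_starts(self) -> np.ndarray:
        """Start time of every block, seconds from CEE start."""
        return self.pre_start + self.block_dur * np.arange(self.n_blocks)

    def block_phases(self) -> np.ndarray:
        """Phase label ('pre'/'exp'/'post') of every block."""
        starts = self.block_starts()
        out = np.full(self.n_blocks, "pre", dtype=object)
        out[starts >= self.exp_start] = "exp"
        out[starts >= self.post_start] = "post"
        return out

    def phase_index(self) -> np.ndarray:
        """Integer phase codes (0 = pre, 1 = exp, 2 = post) per block."""
        starts = self.block_starts()
        return (
            (starts >= self.exp_start).astype(np.int64)
            + (starts >= self.post_start).astype(np.int64)
        )

    def phase_blocks(self, phase: str) -> np.ndarray:
        """Block indices belonging to ``phase``."""
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
        return np.flatnonzero(self.block_phases() == phase)


def _is_multiple(duration: float, block: float) -> bool:
    ratio = duration / block
    return abs(ratio - round(ratio)) < 1e-9 and round(ratio) > 0


def make_phase_schedule(
    pre_dur: float,
    exp_dur: float,
    post_dur: float,
    block_dur: float = 5.0,
) -> PhaseSchedule:
    """Build a schedule starting at t = 0 from the three phase durations.

    Parameters
    ----------
    pre_dur, exp_dur, post_dur
        Phase durations in seconds; each must be a positive multiple of
        ``block_dur``.
    block_dur
        Analysis block length in seconds (default 5 s).
    """
    for name, dur in zip(PHASES, (pre_dur, exp_dur, post_dur), strict=True):
        if dur <= 0 or not _is_multiple(dur, block_dur):
            raise ValueError(
                f"{name} phase duration {dur} s is not a positive multiple "
                f"of block_dur = {block_dur} s"
            )
    return PhaseSchedule(
        pre_start=0.0,
        pre_end=pre_dur,
        exp_start=pre_dur,
        exp_end=pre_dur + exp_dur,
        post_start=pre_dur + exp_dur,
        post_end=pre_dur + exp_dur + post_dur,
        block_dur=block_dur,
    )
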