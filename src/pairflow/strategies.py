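"""Conditioning masks for the co-design task modes, and track schedules.

Task modes
----------
Generation always starts from a partially masked protein x0.  Which tokens
are given (and therefore held fixed) defines the task:

* ``unconditional`` — everything masked; free co-design of sequence and
  structure.
* ``folding`` — the sequence is given; the structure track is generated.
* ``inverse_folding`` — the structure is given; the sequence is generated.
* ``motif_scaffolding`` — both tracks are given on a subset of residues
  (the motif); the surrounding scaffold is generated.

Track strategies
----------------
The sampler can update both tracks every step or alternate between them.
Inactive tracks are frozen (identity kernel) and keep their own uniform
time grid over the steps at which they are active, so each track's
unmasking rate dt/(1-t) stays consistent within the track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import (
    SEQUENCE,
    STRUCTURE,
    ConditionMask,
    ProteinTokens,
    TokenTrack,
    Vocabulary,
)

STRATEGIES = ("synchronous", "asynchronous", "sequence_first", "structure_first")

MODES = ("unconditional", "folding", "inverse_folding", "motif_scaffolding")


@dataclass(frozen=True)
class StrategyId:
    """Validated name of a track-scheduling strategy."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.name!r}; expected one of {STRATEGIES}"
            )


@dataclass(frozen=True)
class TaskSpec:
    """Declarative description of a co-design task.

    ``given_seq`` / ``given_struct`` supply the fixed tokens required by
    the mode; ``motif_positions`` restricts them to a residue subset for
    motif scaffolding (0-based indices).
    """

    mode: str
    given_seq: Optional[TokenTrack] = None
    given_struct: Optional[TokenTrack] = None
    motif_positions: Optional[frozenset[int]] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown task mode {self.mode!r}; expected one of {MODES}")
        if self.mode == "folding" and self.given_seq is None:
            raise ValueError("folding requires given_seq")
        if self.mode == "inverse_folding" and self.given_struct is None:
            raise ValueError("inverse_folding requires given_struct")
        if self.mode == "motif_scaffolding":
            if self.given_seq is None or self.given_struct is None:
                raise ValueError("motif_scaffolding requires both given tracks")
            if not self.motif_positions:
                raise ValueError("motif_scaffolding requires motif_positions")
        if self.motif_positions is not None:
            object.__setattr__(self, "motif_positions", frozenset(self.motif_positions))


def _check_given(track: TokenTrack, length: int, vocab: Vocabulary, what: str) -> None:
    if len(track) != length:
        raise ValueError(f"{what} has length {len(track)}, expected {length}")
    track.validate_against(vocab)
    if track.has_mask(vocab):
        raise ValueError(f"{what} must not contain mask tokens")


def make_condition_mask(
    spec: TaskSpec,
    length: int,
    seq_vocab: Vocabulary,
    struct_vocab: Vocabulary,
) -> tuple[ProteinTokens, ConditionMask]:
    """Build the initial protein x0 and conditioning flags for a task.

    Returns a protein whose non-given positions are mask tokens, plus a
    :class:`ConditionMask` flagging exactly the given positions.
    """
    seq = np.full(length, seq_vocab.mask_index, dtype=np.int64)
    struct = np.full(length, struct_vocab.mask_index, dtype=np.int64)
    flag_seq = np.zeros(length, dtype=bool)
    flag_struct = np.zeros(length, dtype=bool)

    if spec.mode == "folding":
        _check_given(spec.given_seq, length, seq_vocab, "given_seq")
        seq[:] = spec.given_seq.tokens
        flag_seq[:] = True
    elif spec.mode == "inverse_folding":
        _check_given(spec.given_struct, length, struct_vocab, "given_struct")
        struct[:] = spec.given_struct.tokens
        flag_struct[:] = True
    elif spec.mode == "motif_scaffolding":
        pos = np.array(sorted(spec.motif_positions), dtype=np.int64)
        if pos.min() < 0 or pos.max() >= length:
            raise ValueError("motif positions out of range")
        for track, vocab, what in (
            (spec.given_seq, seq_vocab, "given_seq"),
            (spec.given_struct, struct_vocab, "given_struct"),
        ):
            if len(track) != pos.size:
                raise ValueError(
                    f"{what} must carry exactly one token per motif position"
                )
            track.validate_against(vocab)
            if track.has_mask(vocab):
                raise ValueError(f"{what} must not contain mask tokens")
        seq[pos] = spec.given_seq.tokens
        struct[pos] = spec.given_struct.tokens
        flag_seq[pos] = True
        flag_struct[pos] = True
    # unconditional: everything stays masked, no flags

    x0 = ProteinTokens(
        TokenTrack(seq, SEQUENCE), TokenTrack(struct, STRUCTURE)
    )
    return x0, ConditionMask(flag_seq, flag_struct)


def active_tracks(strategy: str | StrategyId, step_index: int, steps: int) -> frozenset[str]:
    """Which tracks are updated at a given global step.

    synchronous: both tracks every step.  asynchronous: strict alternation,
    sequence on even steps.  sequence_first / structure_first: one track for
    the first half of the step budget, the other for the second half.
    """
    name = strategy.name if isinstance(strategy, StrategyId) else StrategyId(strategy).name
    if not 0 <= step_index < steps:
        raise ValueError("step_index out of range")
    if name == "synchronous":
        return frozenset((SEQUENCE, STRUCTURE))
    if name == "asynchronous":
        return frozenset((SEQUENCE,)) if step_index % 2 == 0 else frozenset((STRUCTURE,))
    first, second = (
        (SEQUENCE, STRUCTURE) if name == "sequence_first" else (STRUCTURE, SEQUENCE)
    )
    return frozenset((first,)) if step_index < steps // 2 else frozenset((second,))


@dataclass(frozen=True)
class TrackSchedule:
    """Per-track view of the global schedule.

    For each global step k: ``active[k]`` says whether the track moves,
    and when it does, ``t[k]``/``dt[k]`` give the track-internal time and
    step on that track's own uniform grid, with ``is_last[k]`` marking the
    track's final active step (where re-masking is switched off).
    """

    active: np.ndarray
    t: np.ndarray
    dt: np.ndarray
    is_last: np.ndarray

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def build_schedule(strategy: str | StrategyId, steps: int) -> dict[str, TrackSchedule]:
    """Expand a strategy into explicit per-track (active, t, dt) arrays.

    Each track sees a uniform grid t_j = j/m over its m active steps, so
    every track's internal time reaches 1 and no masks survive sampling.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    name = strategy.name if isinstance(strategy, StrategyId) else StrategyId(strategy).name
    if name != "synchronous" and steps < 2:
        raise ValueError(f"strategy {name!r} needs at least 2 steps")
    out: dict[str, TrackSchedule] = {}
    for track in (SEQUENCE, STRUCTURE):
        active = np.array(
            [track in active_tracks(name, k, steps) for k in range(steps)], dtype=bool
        )
        m = int(active.sum())
        t = np.zeros(steps)
        dt = np.zeros(steps)
        is_last = np.zeros(steps, dtype=bool)
        idx = np.flatnonzero(active)
        t[idx] = np.arange(m) / m
        dt[idx] = 1.0 / m
        is_last[idx[-1]] = True
        out[track] = TrackSchedule(active, t, dt, is_last)
    return out
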