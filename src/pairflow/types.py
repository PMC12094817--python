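"""Core value types for discrete masked flows over paired token tracks.

A protein is represented as two equal-length tracks of discrete tokens:
amino-acid (sequence) tokens and local-backbone (structure) tokens, each
drawn from its own vocabulary that includes a distinguished absorbing mask
symbol.  Generation proceeds by progressively replacing masks with real
tokens under a continuous-time Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

SEQUENCE = "sequence"
STRUCTURE = "structure"

_AMINO_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
MASK_SYMBOL = "-"


@dataclass(frozen=True)
class Vocabulary:
    """A token alphabet for one modality, with a distinguished mask index.

    Parameters
    ----------
    symbols
        Ordered, unique token labels, including the mask symbol.
    mask_index
        Position of the mask token within ``symbols``.
    """

    symbols: tuple[str, ...]
    mask_index: int

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("a vocabulary needs at least one real token plus the mask")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("vocabulary symbols must be unique")
        if not 0 <= self.mask_index < len(self.symbols):
            raise ValueError(f"mask_index {self.mask_index} out of range")

    @property
    def size(self) -> int:
        """Number of tokens including the mask."""
        return len(self.symbols)

    @property
    def n_real(self) -> int:
        """Number of non-mask tokens."""
        return self.size - 1

    @property
    def real_indices(self) -> np.ndarray:
        """Indices of non-mask tokens, in order."""
        idx = np.arange(self.size)
        return idx[idx != self.mask_index]

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    @classmethod
    def amino_acids(cls, n_real: int = 6) -> "Vocabulary":
        """Toy amino-acid alphabet: first ``n_real`` letters of the standard
        20 (alphabetical one-letter codes), mask appended last."""
        if not 1 <= n_real <= len(_AMINO_LETTERS):
            raise ValueError(f"n_real must be in [1, {len(_AMINO_LETTERS)}]")
        return cls(tuple(_AMINO_LETTERS[:n_real]) + (MASK_SYMBOL,), n_real)

    @classmethod
    def structure_codes(cls, n_real: int = 8) -> "Vocabulary":
        """Toy structure-code alphabet ``a, b, c, ...`` (stand-ins for
        VQ codebook entries), mask appended last."""
        if not 1 <= n_real <= 26:
            raise ValueError("n_real must be in [1, 26]")
        letters = tuple(chr(ord("a") + i) for i in range(n_real))
        return cls(letters + (MASK_SYMBOL,), n_real)


@dataclass(frozen=True)
class TokenTrack:
    """A length-N run of integer token ids for one modality."""

    tokens: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        tok = np.asarray(self.tokens, dtype=np.int64)
        object.__setattr__(self, "tokens", tok)
        if tok.ndim != 1 or tok.size < 1:
            raise ValueError("tokens must be a non-empty 1-D array")
        if self.modality not in (SEQUENCE, STRUCTURE):
            raise ValueError(f"unknown modality {self.modality!r}")
        if tok.min() < 0:
            raise ValueError("token ids must be nonnegative")

    def __len__(self) -> int:
        return int(self.tokens.size)

    def validate_against(self, vocab: Vocabulary) -> None:
        if self.tokens.max() >= vocab.size:
            raise ValueError("token id outside vocabulary")

    def has_mask(self, vocab: Vocabulary) -> bool:
        return bool(np.any(self.tokens == vocab.mask_index))

    def __eq__(self, other: object) -> bool:  # dataclass eq breaks on arrays
        if not isinstance(other, TokenTrack):
            return NotImplemented
        return self.modality == other.modality and np.array_equal(
            self.tokens, other.tokens
        )


@dataclass(frozen=True)
class ProteinTokens:
    """Paired equal-length sequence and structure tracks: x = (s, r)."""

    seq: TokenTrack
    struct: TokenTrack

    def __post_init__(self) -> None:
        if self.seq.modality != SEQUENCE or self.struct.modality != STRUCTURE:
            raise ValueError("tracks must be (sequence, structure) in that order")
        if len(self.seq) != len(self.struct):
            raise ValueError("sequence and structure tracks must have equal length")

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_arrays(cls, seq: Iterable[int], struct: Iterable[int]) -> "ProteinTokens":
        return cls(
            TokenTrack(np.asarray(list(seq), dtype=np.int64), SEQUENCE),
            TokenTrack(np.asarray(list(struct), dtype=np.int64), STRUCTURE),
        )

    @classmethod
    def fully_masked(
        cls, length: int, seq_vocab: Vocabulary, struct_vocab: Vocabulary
    ) -> "ProteinTokens":
        return cls.from_arrays(
            np.full(length, seq_vocab.mask_index),
            np.full(length, struct_vocab.mask_index),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinTokens):
            return NotImplemented
        return self.seq == other.seq and self.struct == other.struct


_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class CategoricalField:
    """Per-position probability vectors over one vocabulary (N x K)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2:
            raise ValueError("probs must be an N x K matrix")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("each row must sum to 1")

    @property
    def n_positions(self) -> int:
        return self.probs.shape[0]

    @property
    def vocab_size(self) -> int:
        return self.probs.shape[1]

    def mask_mass(self, vocab: Vocabulary) -> np.ndarray:
        return self.probs[:, vocab.mask_index]

    def entropy(self) -> np.ndarray:
        """Per-row Shannon entropy in nats (0 log 0 := 0)."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log(p), 0.0)
        return terms.sum(axis=1)

    def argmax(self) -> np.ndarray:
        return self.probs.argmax(axis=1)


@dataclass(frozen=True)
class FlowTime:
    """A point on the sampling schedule: current time t and step size dt."""

    t: float
    dt: float
    step_index: int
    is_last: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        if not 0.0 < self.dt <= 1.0:
            raise ValueError("dt must lie in (0, 1]")
        if self.t + self.dt > 1.0 + 1e-12:
            raise ValueError("t + dt must not exceed 1")


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling contract of the CTMC Euler loop.

    Attributes
    ----------
    steps
        Number of Euler steps over the uniform grid t_k = k/steps.
    eta
        Balanced-noise rate allowing temporary re-masking; 0 disables it.
    strategy
        Track-scheduling strategy name (see :mod:`pairflow.strategies`).
    temperature
        Power-transform temperature applied to denoiser rows (1 = faithful).
    seed
        Seed for the single RNG driving the trajectory.
    """

    steps: int = 400
    eta: float = 0.0
    strategy: str = "synchronous"
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def with_(self, **kwargs) -> "SamplerConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ConditionMask:
    """Boolean conditioning flags per position, per track.

    Flagged positions carry fixed (given) tokens: they are never resampled
    and never re-masked during sampling.
    """

    seq: np.ndarray
    struct: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.seq, dtype=bool)
        r = np.asarray(self.struct, dtype=bool)
        object.__setattr__(self, "seq", s)
        object.__setattr__(self, "struct", r)
        if s.shape != r.shape or s.ndim != 1:
            raise ValueError("condition flags must be two equal-length 1-D arrays")

    def __len__(self) -> int:
        return int(self.seq.size)

    @classmethod
    def none(cls, length: int) -> "ConditionMask":
        return cls(np.zeros(length, dtype=bool), np.zeros(length, dtype=bool))
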