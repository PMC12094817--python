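"""An enumerable toy protein world with coupled sequence/structure tokens.

Real proteins couple amino-acid identity to local backbone geometry through
secondary structure.  The toy world emulates this with a hidden first-order
Markov chain z_1..z_N (think helix/sheet/coil) that emits, at every
residue, one sequence token and one structure token conditionally
independently given the state.  The construction keeps the joint
distribution over (s, r) exactly computable by forward recursion for small
N, which provides enumeration oracles for the sampler, and it gives the
two tracks positive mutual information so that co-design, folding and
inverse folding are all non-trivially testable.

Also provided: a fast exact-posterior predictor over the hidden chain
(forward–backward), and a co-fold oracle (Viterbi-style max-product
decoding of the structure track from a sequence) standing in for
folding-based consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import (
    SEQUENCE,
    STRUCTURE,
    ProteinTokens,
    TokenTrack,
    Vocabulary,
)

_ENUM_GUARD = 10**6
_ROW_TOL = 1e-9


def _check_stochastic(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=np.float64)
    if np.any(mat < 0):
        raise ValueError(f"{name} must be nonnegative")
    if np.any(np.abs(mat.sum(axis=-1) - 1.0) > _ROW_TOL):
        raise ValueError(f"{name} rows must sum to 1")
    return mat


@dataclass(frozen=True)
class ToyWorldParams:
    """Parameters of the hidden-state toy world.

    Attributes
    ----------
    trans
        H x H row-stochastic hidden transition matrix.
    emit_seq, emit_struct
        H x (K-1) row-stochastic emissions over the non-mask tokens of the
        sequence / structure vocabularies.
    init
        Length-H initial state distribution.
    seed
        Default seed for generation runs that do not pass their own RNG.
    """

    trans: np.ndarray
    emit_seq: np.ndarray
    emit_struct: np.ndarray
    init: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        trans = _check_stochastic(self.trans, "trans")
        emit_seq = _check_stochastic(self.emit_seq, "emit_seq")
        emit_struct = _check_stochastic(self.emit_struct, "emit_struct")
        init = _check_stochastic(self.init, "init")
        h = init.shape[0]
        if trans.shape != (h, h) or emit_seq.shape[0] != h or emit_struct.shape[0] != h:
            raise ValueError("inconsistent hidden-state dimension across parameters")
        for obj, arr in (("trans", trans), ("emit_seq", emit_seq),
                         ("emit_struct", emit_struct), ("init", init)):
            object.__setattr__(self, obj, arr)

    @property
    def n_hidden(self) -> int:
        return int(self.init.shape[0])

    @property
    def n_seq_tokens(self) -> int:
        return int(self.emit_seq.shape[1])

    @property
    def n_struct_tokens(self) -> int:
        return int(self.emit_struct.shape[1])

    @property
    def seq_vocab(self) -> Vocabulary:
        return Vocabulary.amino_acids(self.n_seq_tokens)

    @property
    def struct_vocab(self) -> Vocabulary:
        return Vocabulary.structure_codes(self.n_struct_tokens)

    @classmethod
    def default(
        cls,
        n_hidden: int = 3,
        n_seq_tokens: int = 6,
        n_struct_tokens: int = 8,
        stay: float = 0.8,
        peak: float = 0.7,
        seed: int = 0,
    ) -> "ToyWorldParams":
        """Strongly coupled defaults: diagonal-dominant hidden transitions
        (``stay`` mass on staying put) and peaked emissions (``peak`` mass
        on each state's preferred token, spread over the alphabet)."""
        h = n_hidden
        if h == 1:
            trans = np.ones((1, 1))
        else:
            trans = np.full((h, h), (1.0 - stay) / (h - 1))
            np.fill_diagonal(trans, stay)

        def peaked(n_tokens: int) -> np.ndarray:
            emit = np.full((h, n_tokens), (1.0 - peak) / (n_tokens - 1))
            for state in range(h):
                pref = (
                    int(np.floor(state * (n_tokens - 1) / (h - 1) + 0.5))
                    if h > 1
                    else 0
                )
                emit[state, :] = (1.0 - peak) / (n_tokens - 1)
                emit[state, pref] = peak
            return emit

        return cls(
            trans=trans,
            emit_seq=peaked(n_seq_tokens),
            emit_struct=peaked(n_struct_tokens),
            init=np.full(h, 1.0 / h),
            seed=seed,
        )


def _sample_categorical_rows(
    probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one index per leading entry from rows of ``probs`` (..., K)."""
    u = rng.random(probs.shape[:-1])
    return (probs.cumsum(axis=-1) > u[..., None]).argmax(axis=-1)


def sample_toy_arrays(
    params: ToyWorldParams, n: int, length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised sampling: returns (seq, struct) arrays of shape (n, N)."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    z = np.empty((n, length), dtype=np.int64)
    z[:, 0] = _sample_categorical_rows(np.broadcast_to(params.init, (n, params.n_hidden)), rng)
    for i in range(1, length):
        z[:, i] = _sample_categorical_rows(params.trans[z[:, i - 1]], rng)
    seq = _sample_categorical_rows(params.emit_seq[z], rng)
    struct = _sample_categorical_rows(params.emit_struct[z], rng)
    return seq, struct


def sample_toy_proteins(
    params: ToyWorldParams,
    n: int,
    length: int,
    rng: Optional[np.random.Generator] = None,
) -> list[ProteinTokens]:
    """Draw ``n`` fully observed toy proteins of the given length."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    seq, struct = sample_toy_arrays(params, n, length, rng)
    return [ProteinTokens.from_arrays(s, r) for s, r in zip(seq, struct)]


@dataclass(frozen=True)
class JointTable:
    """Exact joint distribution over all (s, r) outcomes of a small world."""

    probs: np.ndarray  # (O,)
    seq_outcomes: np.ndarray  # (O, N)
    struct_outcomes: np.ndarray  # (O, N)
    seq_vocab: Vocabulary
    struct_vocab: Vocabulary
    length: int

    @property
    def n_outcomes(self) -> int:
        return int(self.probs.shape[0])

    def encode(self, seq: np.ndarray, struct: np.ndarray) -> np.ndarray:
        """Map (batch, N) token arrays to flat outcome indices."""
        ks, kr = self.seq_vocab.n_real, self.struct_vocab.n_real
        digits = np.concatenate([np.asarray(seq), np.asarray(struct)], axis=-1)
        dims = (ks,) * self.length + (kr,) * self.length
        return np.ravel_multi_index(tuple(digits.T), dims)

    def position_marginals(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-position marginals (N, Ks-1) and (N, Kr-1) from the table."""
        n = self.length
        ms = np.zeros((n, self.seq_vocab.n_real))
        mr = np.zeros((n, self.struct_vocab.n_real))
        for i in range(n):
            ms[i] = np.bincount(
                self.seq_outcomes[:, i], weights=self.probs, minlength=ms.shape[1]
            )
            mr[i] = np.bincount(
                self.struct_outcomes[:, i], weights=self.probs, minlength=mr.shape[1]
            )
        return ms, mr

    def mutual_information(self) -> float:
        """Mutual information (nats) between the full sequence and the full
        structure track under the joint."""
        ks, kr = self.seq_vocab.n_real, self.struct_vocab.n_real
        s_idx = np.ravel_multi_index(
            tuple(self.seq_outcomes.T), (ks,) * self.length
        )
        r_idx = np.ravel_multi_index(
            tuple(self.struct_outcomes.T), (kr,) * self.length
        )
        ps = np.bincount(s_idx, weights=self.probs)
        pr = np.bincount(r_idx, weights=self.probs)
        p = self.probs
        good = p > 0
        return float(
            np.sum(p[good] * (np.log(p[good]) - np.log(ps[s_idx][good]) - np.log(pr[r_idx][good])))
        )


def enumerate_joint(params: ToyWorldParams, length: int) -> JointTable:
    """Exact joint probabilities over every (s, r) outcome, by forward
    recursion over the hidden chain, vectorised across outcomes.

    Guarded to at most 10^6 outcomes: ((Ks-1) * (Kr-1)) ** N.
    """
    ks, kr = params.n_seq_tokens, params.n_struct_tokens
    n_out = (ks * kr) ** length
    if n_out > _ENUM_GUARD:
        raise ValueError(
            f"{n_out} outcomes exceed the enumeration guard of {_ENUM_GUARD}"
        )
    dims = (ks,) * length + (kr,) * length
    digits = np.array(np.unravel_index(np.arange(n_out), dims)).T
    seq_out = digits[:, :length]
    struct_out = digits[:, length:]

    alpha = params.init[None, :] * (
        params.emit_seq.T[seq_out[:, 0]] * params.emit_struct.T[struct_out[:, 0]]
    )
    for i in range(1, length):
        alpha = (alpha @ params.trans) * (
            params.emit_seq.T[seq_out[:, i]] * params.emit_struct.T[struct_out[:, i]]
        )
    probs = alpha.sum(axis=1)
    return JointTable(
        probs=probs,
        seq_outcomes=seq_out,
        struct_outcomes=struct_out,
        seq_vocab=params.seq_vocab,
        struct_vocab=params.struct_vocab,
        length=length,
    )


def posterior_fields(
    params: ToyWorldParams, seq_tokens: np.ndarray, struct_tokens: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditionals p(x1 | observed coordinates) by forward–backward.

    ``seq_tokens``/``struct_tokens`` are (batch, N) arrays where the mask
    index marks unobserved coordinates.  Returns probability arrays of
    shape (batch, N, K) over the full vocabularies with zero mask mass —
    identical to table-based posterior summation, but linear in N, so it
    scales to long proteins and big batches.
    """
    sv, rv = params.seq_vocab, params.struct_vocab
    S = np.asarray(seq_tokens)
    R = np.asarray(struct_tokens)
    if S.ndim != 2 or S.shape != R.shape:
        raise ValueError("token arrays must be matching (batch, N) matrices")
    b, n = S.shape
    s_obs = S != sv.mask_index
    r_obs = R != rv.mask_index

    es = np.where(
        s_obs[..., None], params.emit_seq.T[np.where(s_obs, S, 0)], 1.0
    )  # (B, N, H)
    er = np.where(
        r_obs[..., None], params.emit_struct.T[np.where(r_obs, R, 0)], 1.0
    )
    e = es * er

    alpha = np.empty((b, n, params.n_hidden))
    a = params.init[None, :] * e[:, 0]
    norm = a.sum(axis=1, keepdims=True)
    if np.any(norm <= 0):
        raise ValueError("observed tokens have zero probability under the world")
    alpha[:, 0] = a / norm
    for i in range(1, n):
        a = (alpha[:, i - 1] @ params.trans) * e[:, i]
        norm = a.sum(axis=1, keepdims=True)
        if np.any(norm <= 0):
            raise ValueError("observed tokens have zero probability under the world")
        alpha[:, i] = a / norm

    beta = np.empty_like(alpha)
    beta[:, n - 1] = 1.0
    for i in range(n - 2, -1, -1):
        bnext = e[:, i + 1] * beta[:, i + 1]
        beta[:, i] = bnext @ params.trans.T
        beta[:, i] /= beta[:, i].max(axis=1, keepdims=True)

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    out = []
    for obs, tokens, emit, vocab in (
        (s_obs, S, params.emit_seq, sv),
        (r_obs, R, params.emit_struct, rv),
    ):
        probs = np.zeros((b, n, vocab.size))
        pred = gamma @ emit  # (B, N, K-1)
        probs[:, :, : vocab.n_real] = pred / pred.sum(axis=2, keepdims=True)
        onehot = np.zeros((b, n, vocab.size))
        safe = np.where(obs, tokens, 0)
        np.put_along_axis(onehot, safe[..., None], 1.0, axis=2)
        probs = np.where(obs[..., None], onehot, probs)
        out.append(probs)
    return out[0], out[1]


class HMMPosteriorDenoiser:
    """Exact-posterior predictor behind the sampler's denoiser contract,
    computed by forward–backward over the hidden chain (batched)."""

    def __init__(self, params: ToyWorldParams) -> None:
        self.params = params

    def __call__(
        self, seq_tokens: np.ndarray, struct_tokens: np.ndarray, t: float
    ) -> tuple[np.ndarray, np.ndarray]:
        return posterior_fields(self.params, seq_tokens, struct_tokens)


def cofold_oracle(s: TokenTrack, params: ToyWorldParams) -> TokenTrack:
    """Decode the structure track from a sequence by max-product.

    Runs Viterbi over the hidden chain scoring each state by its sequence
    emission times its best structure emission, then reads off each
    state's preferred structure token.  This is the joint MAP of (hidden
    path, structure) given the sequence; ties break to the lowest index.
    Deterministic; a desk-scale stand-in for refolding-based consistency.
    """
    sv = params.seq_vocab
    s.validate_against(sv)
    if s.has_mask(sv):
        raise ValueError("sequence must be fully observed")
    n = len(s)
    best_r = params.emit_struct.argmax(axis=1)  # per-state preferred token
    emit = params.emit_seq.T[s.tokens] * params.emit_struct.max(axis=1)  # (N, H)

    h = params.n_hidden
    log = np.full((n, h), -np.inf)
    back = np.zeros((n, h), dtype=np.int64)
    with np.errstate(divide="ignore"):
        log[0] = np.log(params.init) + np.log(emit[0])
        ltrans = np.log(params.trans)
        lemit = np.log(emit)
    for i in range(1, n):
        scores = log[i - 1][:, None] + ltrans  # (H_prev, H)
        back[i] = scores.argmax(axis=0)
        log[i] = scores.max(axis=0) + lemit[i]
    if not np.isfinite(log[n - 1].max()):
        raise ValueError("sequence has zero likelihood under the world")
    z = np.empty(n, dtype=np.int64)
    z[n - 1] = log[n - 1].argmax()
    for i in range(n - 2, -1, -1):
        z[i] = back[i + 1][z[i + 1]]
    return TokenTrack(best_r[z], STRUCTURE)


# ---------------------------------------------------------------------------
# Closed-form world summaries used as baselines and ceilings


def hidden_state_marginals(params: ToyWorldParams, length: int) -> np.ndarray:
    """p(z_i) for each position, shape (N, H)."""
    m = np.empty((length, params.n_hidden))
    m[0] = params.init
    for i in range(1, length):
        m[i] = m[i - 1] @ params.trans
    return m

def position_marginals(
    params: ToyWorldParams, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-position token marginals (N, Ks-1) and (N, Kr-1)."""
    m = hidden_state_marginals(params, length)
    return m @ params.emit_seq, m @ params.emit_struct


def majority_class_rate(params: ToyWorldParams, length: int) -> float:
    """Accuracy of the best constant-per-position sequence predictor."""
    ms, _ = position_marginals(params, length)
    return float(ms.max(axis=1).mean())


def inverse_folding_bayes_ceiling(
    params: ToyWorldParams,
    length: int,
    n_structures: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Best achievable native-sequence-recovery rate given the structure.

    The optimal predictor sets each residue to argmax_k p(s_i = k | r); its
    expected per-residue accuracy is E_r[ mean_i max_k p(s_i = k | r) ].
    Computed exactly by enumerating structure outcomes when feasible and
    ``n_structures`` is None, otherwise by Monte Carlo over sampled
    structures with exact forward–backward conditionals.
    """
    rv = params.struct_vocab
    if n_structures is None:
        n_out = params.n_struct_tokens**length
        if n_out > _ENUM_GUARD:
            raise ValueError("too many structures; pass n_structures for Monte Carlo")
        dims = (params.n_struct_tokens,) * length
        R = np.array(np.unravel_index(np.arange(n_out), dims)).T
        # p(r): forward over struct emissions only
        alpha = params.init[None, :] * params.emit_struct.T[R[:, 0]]
        for i in range(1, length):
            alpha = (alpha @ params.trans) * params.emit_struct.T[R[:, i]]
        pr = alpha.sum(axis=1)
        weights = pr
    else:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        _, R = sample_toy_arrays(params, n_structures, length, rng)
        weights = np.full(R.shape[0], 1.0 / R.shape[0])
    S = np.full_like(R, params.seq_vocab.mask_index)
    ps, _ = posterior_fields(params, S, R)
    per_struct = ps[:, :, : params.n_seq_tokens].max(axis=2).mean(axis=1)
    return float(per_struct @ weights / weights.sum())
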