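"""Masked linear-interpolation flow and its CTMC Euler sampler.

The generative model is a continuous-time Markov chain on discrete tokens.
The conditional flow interpolates between pure mask at t=0 and a data
point x1 at t=1:

    p(s_t | s_1) = t * f(s_1) + (1 - t) * f(M)

with f the one-hot encoding and M the mask token; sequence and structure
tracks, and residues within a track, interpolate independently.  Sampling
runs the time-discretised posterior kernel forward from x0: a masked
position unmasks into the denoiser's predicted distribution with
probability dt * (1 + eta * t) / (1 - t) per step, and with balanced noise
eta > 0 an unmasked position may temporarily revert to mask with
probability eta * dt — except at its track's final step, where reversion
is switched off so the sample finishes mask-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .strategies import build_schedule
from .types import (
    SEQUENCE,
    STRUCTURE,
    CategoricalField,
    ConditionMask,
    FlowTime,
    ProteinTokens,
    SamplerConfig,
    TokenTrack,
    Vocabulary,
)

_MASK_MASS_TOL = 1e-9


class Denoiser(Protocol):
    """Contract for the predictor queried by the sampler.

    Given batches of (possibly masked) token tracks and the global time t,
    returns two probability arrays of shape (batch, N, vocab_size), each
    row normalised with exactly zero mass on the mask index.
    """

    def __call__(
        self, seq_tokens: np.ndarray, struct_tokens: np.ndarray, t: float
    ) -> tuple[np.ndarray, np.ndarray]: ...


def interpolate_conditional(
    x1_track: TokenTrack, t: float, vocab: Vocabulary
) -> CategoricalField:
    """Conditional flow p(. | x1) at time t for one track.

    Each row puts probability t on the data token and 1 - t on the mask.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    x1_track.validate_against(vocab)
    if x1_track.has_mask(vocab):
        raise ValueError("x1 must be fully observed (no mask tokens)")
    n = len(x1_track)
    probs = np.zeros((n, vocab.size))
    probs[np.arange(n), x1_track.tokens] = t
    probs[:, vocab.mask_index] += 1.0 - t
    return CategoricalField(probs)


def corrupt(
    x1: ProteinTokens,
    t_seq: float,
    t_struct: float,
    rng: np.random.Generator,
    seq_vocab: Vocabulary,
    struct_vocab: Vocabulary,
) -> ProteinTokens:
    """Sample x_t from the conditional flow: independently keep each token
    with probability t (per track), otherwise replace it with the mask."""
    for t in (t_seq, t_struct):
        if not 0.0 <= t <= 1.0:
            raise ValueError("interpolation times must lie in [0, 1]")
    if x1.seq.has_mask(seq_vocab) or x1.struct.has_mask(struct_vocab):
        raise ValueError("x1 must be fully observed (no mask tokens)")
    seq = corrupt_tokens(x1.seq.tokens[None, :], t_seq, rng, seq_vocab.mask_index)[0]
    struct = corrupt_tokens(
        x1.struct.tokens[None, :], t_struct, rng, struct_vocab.mask_index
    )[0]
    return ProteinTokens.from_arrays(seq, struct)


def corrupt_tokens(
    tokens: np.ndarray, t: float | np.ndarray, rng: np.random.Generator, mask_index: int
) -> np.ndarray:
    """Vectorised corruption of a (batch, N) token array at time(s) t.

    ``t`` may be a scalar or a per-row array (broadcast over positions).
    """
    tokens = np.asarray(tokens)
    t = np.asarray(t, dtype=np.float64)
    if t.ndim == 1:
        t = t[:, None]
    keep = rng.random(tokens.shape) < t
    return np.where(keep, tokens, mask_index)


def _apply_temperature(probs: np.ndarray, temperature: float) -> np.ndarray:
    """Power transform p^(1/T), renormalised; zeros stay exactly zero."""
    if temperature == 1.0:
        return probs
    with np.errstate(divide="ignore"):
        logp = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
    z = logp / temperature
    z -= z.max(axis=-1, keepdims=True)
    out = np.exp(z)
    out[~np.isfinite(z)] = 0.0
    return out / out.sum(axis=-1, keepdims=True)


def _kernel_probs(
    tokens: np.ndarray,
    pred: np.ndarray,
    t: float,
    dt: float,
    eta: float,
    is_last: bool,
    mask_index: int,
    cond: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Posterior transition rows for a (batch, N) token array.

    ``pred`` is the denoiser output (batch, N, K) with zero mask mass.
    Conditioning positions get an identity (one-hot) row.
    """
    if t >= 1.0:
        raise ValueError("transition kernel requires t < 1")
    if eta * dt > 1.0:
        raise ValueError("eta * dt must not exceed 1")
    out = np.zeros_like(pred, dtype=np.float64)
    is_mask = tokens == mask_index

    # masked rows: unmask into pred with coefficient c, clamped at 1 so the
    # row stays a distribution on coarse grids near t = 1
    c = min(1.0, dt * (1.0 + eta * t) / (1.0 - t))
    out[is_mask] = c * pred[is_mask]
    out[is_mask, mask_index] = 1.0 - c

    # unmasked rows: stay put, except balanced-noise reversion before the
    # track's last step
    revert = 0.0 if is_last else eta * dt
    nm = ~is_mask
    idx = np.nonzero(nm)
    out[idx[0], idx[1], tokens[nm]] = 1.0 - revert
    if revert:
        out[idx[0], idx[1], mask_index] += revert

    if cond is not None and cond.any():
        cidx = np.nonzero(np.broadcast_to(cond, tokens.shape))
        out[cidx[0], cidx[1], :] = 0.0
        out[cidx[0], cidx[1], tokens[cidx]] = 1.0

    out /= out.sum(axis=-1, keepdims=True)
    return out


def transition_kernel(
    xt_track: TokenTrack,
    f_pred: CategoricalField,
    time: FlowTime,
    eta: float,
    vocab: Vocabulary,
) -> CategoricalField:
    """One-track posterior transition q(x_{t+dt} | x_t) as an N x K field."""
    xt_track.validate_against(vocab)
    if f_pred.n_positions != len(xt_track) or f_pred.vocab_size != vocab.size:
        raise ValueError("f_pred shape does not match track/vocabulary")
    if np.any(f_pred.mask_mass(vocab) > _MASK_MASS_TOL):
        raise ValueError("f_pred must place zero probability on the mask token")
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    rows = _kernel_probs(
        xt_track.tokens[None, :],
        f_pred.probs[None, :, :],
        time.t,
        time.dt,
        eta,
        time.is_last,
        vocab.mask_index,
    )[0]
    return CategoricalField(rows)


@dataclass(frozen=True)
class StepRecord:
    """State after one Euler step, for trajectory inspection."""

    t: float
    seq_tokens: np.ndarray
    struct_tokens: np.ndarray
    seq_token_prob: np.ndarray  # kernel probability of the realised token; NaN if track inactive
    struct_token_prob: np.ndarray
    seq_pred_entropy: np.ndarray  # entropy (nats) of the temperature-adjusted denoiser row
    struct_pred_entropy: np.ndarray


@dataclass(frozen=True)
class Trajectory:
    """Full record of one sampling run, x0 plus per-step states."""

    x0: ProteinTokens
    cond: ConditionMask
    steps: tuple[StepRecord, ...]

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class BatchResult:
    """Lightweight outcome of a batched sampling run.

    ``ent_seq``/``ent_struct`` hold, per sample and position, the Shannon
    entropy (nats) of the temperature-adjusted predictor row in force at
    that position's final unmasking event; NaN where the position was given
    (conditioning) and hence never unmasked.
    """

    seq: np.ndarray
    struct: np.ndarray
    ent_seq: np.ndarray
    ent_struct: np.ndarray
    n_remask_events: int


def _row_entropy(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=-1)


def _validate_x0_arrays(
    S0: np.ndarray,
    R0: np.ndarray,
    cond: ConditionMask,
    seq_vocab: Vocabulary,
    struct_vocab: Vocabulary,
) -> None:
    if S0.ndim != 2 or S0.shape != R0.shape:
        raise ValueError("x0 tracks must be matching (batch, N) arrays")
    if len(cond) != S0.shape[1]:
        raise ValueError("conditioning flags must match protein length")
    for tokens, flags, vocab, name in (
        (S0, cond.seq, seq_vocab, "sequence"),
        (R0, cond.struct, struct_vocab, "structure"),
    ):
        if np.any(tokens[:, flags] == vocab.mask_index):
            raise ValueError(f"conditioning flags point at mask tokens ({name})")
        if np.any(tokens[:, ~flags] != vocab.mask_index):
            raise ValueError(
                f"non-conditioning {name} positions must start as mask tokens"
            )


def euler_sample_arrays(
    denoiser: Denoiser,
    S0: np.ndarray,
    R0: np.ndarray,
    cond: ConditionMask,
    config: SamplerConfig,
    seq_vocab: Vocabulary,
    struct_vocab: Vocabulary,
    record: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[BatchResult, Optional[Trajectory]]:
    """Run the Euler sampler for a batch of starting points.

    ``S0``/``R0`` are (batch, N) token arrays — one independent trajectory
    per row — sharing one set of conditioning flags (the flagged columns
    may carry different given tokens per row, e.g. many structures for
    inverse folding).  One denoiser call per step serves both tracks.
    Within a step the sequence track is updated before the structure
    track, and random draws are consumed in position order, so runs are
    reproducible given ``config.seed`` (or an explicit ``rng``).
    """
    S0 = np.asarray(S0, dtype=np.int64)
    R0 = np.asarray(R0, dtype=np.int64)
    _validate_x0_arrays(S0, R0, cond, seq_vocab, struct_vocab)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sched = build_schedule(config.strategy, config.steps)
    n_samples, n = S0.shape
    x0 = ProteinTokens.from_arrays(S0[0], R0[0])
    state = {
        SEQUENCE: S0.copy(),
        STRUCTURE: R0.copy(),
    }
    vocabs = {SEQUENCE: seq_vocab, STRUCTURE: struct_vocab}
    flags = {SEQUENCE: cond.seq, STRUCTURE: cond.struct}
    ent_last = {
        SEQUENCE: np.full((n_samples, n), np.nan),
        STRUCTURE: np.full((n_samples, n), np.nan),
    }
    n_remask = 0
    records: list[StepRecord] = []

    for k in range(config.steps):
        t_global = k / config.steps
        ps, pr = denoiser(state[SEQUENCE], state[STRUCTURE], t_global)
        pred = {SEQUENCE: np.asarray(ps, np.float64), STRUCTURE: np.asarray(pr, np.float64)}
        step_prob = {}
        step_ent = {}
        for track in (SEQUENCE, STRUCTURE):
            vocab = vocabs[track]
            p = pred[track]
            if p.shape != (n_samples, n, vocab.size):
                raise ValueError(f"denoiser returned wrong shape for {track} track")
            if np.any(p[..., vocab.mask_index] > _MASK_MASS_TOL):
                raise ValueError("denoiser must emit zero mask probability")
            p = _apply_temperature(p, config.temperature)
            pred[track] = p
            step_ent[track] = _row_entropy(p)

            ts = sched[track]
            if not ts.active[k]:
                step_prob[track] = np.full((n_samples, n), np.nan)
                continue
            tokens = state[track]
            kern = _kernel_probs(
                tokens, p, ts.t[k], ts.dt[k], config.eta, ts.is_last[k],
                vocab.mask_index, cond=flags[track],
            )
            u = rng.random((n_samples, n))
            new = (kern.cumsum(axis=-1) > u[..., None]).argmax(axis=-1)
            unmask = (tokens == vocab.mask_index) & (new != vocab.mask_index)
            n_remask += int(((tokens != vocab.mask_index) & (new == vocab.mask_index)).sum())
            ent_last[track][unmask] = step_ent[track][unmask]
            step_prob[track] = np.take_along_axis(kern, new[..., None], axis=-1)[..., 0]
            state[track] = new

        if record:
            records.append(
                StepRecord(
                    t=t_global,
                    seq_tokens=state[SEQUENCE][0].copy(),
                    struct_tokens=state[STRUCTURE][0].copy(),
                    seq_token_prob=step_prob[SEQUENCE][0].copy(),
                    struct_token_prob=step_prob[STRUCTURE][0].copy(),
                    seq_pred_entropy=step_ent[SEQUENCE][0].copy(),
                    struct_pred_entropy=step_ent[STRUCTURE][0].copy(),
                )
            )

    result = BatchResult(
        seq=state[SEQUENCE],
        struct=state[STRUCTURE],
        ent_seq=ent_last[SEQUENCE],
        ent_struct=ent_last[STRUCTURE],
        n_remask_events=n_remask,
    )
    traj = Trajectory(x0=x0, cond=cond, steps=tuple(records)) if record else None
    return result, traj


def euler_sample_batch(
    denoiser: Denoiser,
    x0: ProteinTokens,
    cond: ConditionMask,
    config: SamplerConfig,
    seq_vocab: Vocabulary,
    struct_vocab: Vocabulary,
    n_samples: int = 1,
    record: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[BatchResult, Optional[Trajectory]]:
    """Run ``n_samples`` independent trajectories sharing one x0 and one
    set of conditioning flags; see :func:`euler_sample_arrays`."""
    return euler_sample_arrays(
        denoiser,
        np.tile(x0.seq.tokens, (n_samples, 1)),
        np.tile(x0.struct.tokens, (n_samples, 1)),
        cond, config, seq_vocab, struct_vocab,
        record=record, rng=rng,
    )


def euler_sample(
    denoiser: Denoiser,
    x0: ProteinTokens,
    cond: ConditionMask,
    config: SamplerConfig,
    seq_vocab: Vocabulary,
    struct_vocab: Vocabulary,
) -> tuple[ProteinTokens, Trajectory]:
    """Sample one trajectory from x0 to a fully unmasked protein.

    Returns the final sample together with its full per-step trajectory
    record (tokens, realised-token probabilities and predictor-row
    entropies at every step).
    """
    result, traj = euler_sample_batch(
        denoiser, x0, cond, config, seq_vocab, struct_vocab,
        n_samples=1, record=True,
    )
    out = ProteinTokens.from_arrays(result.seq[0], result.struct[0])
    assert traj is not None
    return out, traj


# ---------------------------------------------------------------------------
# Reference denoisers


class DeltaDenoiser:
    """Degenerate predictor: one-hot rows on a fixed target x1.

    With this predictor the sampler must reproduce the target exactly —
    a useful end-to-end check of the kernel and schedule plumbing.
    """

    def __init__(
        self, target: ProteinTokens, seq_vocab: Vocabulary, struct_vocab: Vocabulary
    ) -> None:
        if target.seq.has_mask(seq_vocab) or target.struct.has_mask(struct_vocab):
            raise ValueError("target must be fully observed")
        self._ps = np.zeros((len(target), seq_vocab.size))
        self._ps[np.arange(len(target)), target.seq.tokens] = 1.0
        self._pr = np.zeros((len(target), struct_vocab.size))
        self._pr[np.arange(len(target)), target.struct.tokens] = 1.0

    def __call__(
        self, seq_tokens: np.ndarray, struct_tokens: np.ndarray, t: float
    ) -> tuple[np.ndarray, np.ndarray]:
        b = seq_tokens.shape[0]
        return (
            np.broadcast_to(self._ps, (b,) + self._ps.shape).copy(),
            np.broadcast_to(self._pr, (b,) + self._pr.shape).copy(),
        )


def exact_posterior_denoiser(
    joint, xt: ProteinTokens
) -> tuple[CategoricalField, CategoricalField]:
    """Ideal predictor p(x1 | observed coordinates of xt) by table summation.

    ``joint`` is an enumerated joint distribution (see
    :func:`pairflow.synthetic_data.enumerate_joint`) exposing ``probs``,
    ``seq_outcomes``, ``struct_outcomes`` and the two vocabularies.  Non-mask
    tokens of ``xt`` are treated as observed x1 coordinates; each returned
    row is the per-position conditional of x1 given those observations, with
    zero mass on the mask index.
    """
    n = len(xt)
    if n != joint.length:
        raise ValueError("xt length does not match the enumerated joint")
    sv: Vocabulary = joint.seq_vocab
    rv: Vocabulary = joint.struct_vocab
    xt.seq.validate_against(sv)
    xt.struct.validate_against(rv)

    s_obs = xt.seq.tokens != sv.mask_index
    r_obs = xt.struct.tokens != rv.mask_index
    compat = np.all(
        (joint.seq_outcomes == xt.seq.tokens) | ~s_obs, axis=1
    ) & np.all((joint.struct_outcomes == xt.struct.tokens) | ~r_obs, axis=1)
    w = joint.probs * compat
    z = w.sum()
    if z <= 0.0:
        raise ValueError("observed tokens have zero probability under the joint")

    fields = []
    for outcomes, obs, tokens, vocab in (
        (joint.seq_outcomes, s_obs, xt.seq.tokens, sv),
        (joint.struct_outcomes, r_obs, xt.struct.tokens, rv),
    ):
        probs = np.zeros((n, vocab.size))
        for i in range(n):
            if obs[i]:
                probs[i, tokens[i]] = 1.0
            else:
                marg = np.bincount(outcomes[:, i], weights=w, minlength=vocab.size)
                probs[i] = marg / z
        probs[:, vocab.mask_index] = 0.0
        fields.append(CategoricalField(probs / probs.sum(axis=1, keepdims=True)))
    return fields[0], fields[1]


class ExactPosteriorDenoiser:
    """Batch adapter putting :func:`exact_posterior_denoiser` behind the
    sampler's denoiser contract (loops over the batch; for small tables)."""

    def __init__(self, joint) -> None:
        self.joint = joint

    def __call__(
        self, seq_tokens: np.ndarray, struct_tokens: np.ndarray, t: float
    ) -> tuple[np.ndarray, np.ndarray]:
        ps, pr = [], []
        for s, r in zip(seq_tokens, struct_tokens):
            xt = ProteinTokens.from_arrays(s, r)
            fs, fr = exact_posterior_denoiser(self.joint, xt)
            ps.append(fs.probs)
            pr.append(fr.probs)
        return np.stack(ps), np.stack(pr)
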