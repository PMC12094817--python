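"""Desk-scale evaluation metrics for the joint discrete flow.

Covers the measurable analogues of the full-scale protein benchmarks:
generation entropy (sampler confidence), unmasking accuracy as a function
of flow time, native sequence recovery for inverse folding, total
variation against an enumerated joint distribution, and co-fold
self-consistency on the toy world.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .flow_core import BatchResult, Denoiser, Trajectory, corrupt_tokens
from .synthetic_data import JointTable, ToyWorldParams, cofold_oracle
from .types import ProteinTokens, TokenTrack, Vocabulary


@dataclass(frozen=True)
class MetricReport:
    """One measured quantity with its sample size and dispersion."""

    name: str
    value: float
    n: int
    dispersion: float
    config: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


def generation_entropy(traj: Trajectory, per_residue: bool = True) -> float:
    """Sampler confidence: summed entropy at unmasking events.

    For every position of both tracks, takes the Shannon entropy (nats)
    of the predictor row in force at the step where that position was
    last unmasked, sums over positions and tracks, and (by default)
    divides by the protein length.  Positions given from the start
    (conditioning) have no unmasking event and contribute zero.  Raises
    if any position is still masked at the end of the trajectory.
    """
    if not traj.steps:
        raise ValueError("empty trajectory")
    n = len(traj.x0)
    total = 0.0
    for x0_tokens, flags, attr_tok, attr_ent in (
        (traj.x0.seq.tokens, traj.cond.seq, "seq_tokens", "seq_pred_entropy"),
        (traj.x0.struct.tokens, traj.cond.struct, "struct_tokens", "struct_pred_entropy"),
    ):
        free = ~np.asarray(flags)
        if not free.any():
            continue  # whole track given: nothing was generated
        # free positions start as the mask token (sampler precondition)
        mask_val = int(x0_tokens[free][0])
        history = [x0_tokens] + [getattr(s, attr_tok) for s in traj.steps]
        ent_steps = [getattr(s, attr_ent) for s in traj.steps]
        if np.any(history[-1][free] == mask_val):
            raise ValueError("trajectory left positions masked")
        last_unmask = np.full(n, -1)
        for k in range(len(traj.steps)):
            unmask = (history[k] == mask_val) & (history[k + 1] != mask_val)
            last_unmask[unmask & free] = k
        if np.any(last_unmask[free] < 0):
            raise ValueError("a free position was never unmasked")
        total += float(
            sum(ent_steps[last_unmask[i]][i] for i in np.flatnonzero(free))
        )
    return total / n if per_residue else total


def generation_entropy_batch(
    result: BatchResult, per_residue: bool = True
) -> np.ndarray:
    """Per-sample generation entropy from a batched sampling run."""
    n = result.seq.shape[1]
    total = np.nansum(result.ent_seq, axis=1) + np.nansum(result.ent_struct, axis=1)
    return total / n if per_residue else total


def unmasking_accuracy(
    denoiser: Denoiser,
    dataset: tuple[np.ndarray, np.ndarray] | Sequence[ProteinTokens],
    t_grid: Sequence[float],
    seq_vocab: Vocabulary,
    struct_vocab: Vocabulary,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Masked-token prediction accuracy per time and track.

    For each t in the grid the clean proteins are corrupted at that time,
    the denoiser is queried once, and the per-row argmax is compared with
    the truth at the masked positions.  Returns arrays over the grid for
    both tracks plus the masked-position counts behind each estimate.
    """
    t_grid = np.asarray(list(t_grid), dtype=np.float64)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if np.any(t_grid <= 0) or np.any(t_grid >= 1):
        raise ValueError("t grid must lie strictly inside (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    if not isinstance(dataset, tuple):
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        S1 = np.stack([x.seq.tokens for x in dataset])
        R1 = np.stack([x.struct.tokens for x in dataset])
    else:
        S1, R1 = dataset
        if S1.shape[0] == 0:
            raise ValueError("empty dataset")

    acc = {"sequence": [], "structure": []}
    counts = {"sequence": [], "structure": []}
    for t in t_grid:
        st = corrupt_tokens(S1, t, rng, seq_vocab.mask_index)
        rt = corrupt_tokens(R1, t, rng, struct_vocab.mask_index)
        ps, pr = denoiser(st, rt, float(t))
        for name, xt, x1, probs, vocab in (
            ("sequence", st, S1, ps, seq_vocab),
            ("structure", rt, R1, pr, struct_vocab),
        ):
            masked = xt == vocab.mask_index
            pred = probs.argmax(axis=-1)
            hits = (pred == x1) & masked
            n_masked = int(masked.sum())
            acc[name].append(hits.sum() / n_masked if n_masked else np.nan)
            counts[name].append(n_masked)
    return {
        "t": t_grid,
        "sequence": np.asarray(acc["sequence"]),
        "structure": np.asarray(acc["structure"]),
        "n_sequence": np.asarray(counts["sequence"]),
        "n_structure": np.asarray(counts["structure"]),
    }


def recovery_rate(predicted_seq: TokenTrack, true_seq: TokenTrack) -> float:
    """Native sequence recovery: fraction of identical positions."""
    if len(predicted_seq) != len(true_seq):
        raise ValueError("tracks must have equal length")
    return float(np.mean(predicted_seq.tokens == true_seq.tokens))


def tv_distance(counts: np.ndarray, joint: JointTable) -> float:
    """Total variation 0.5 * sum |phat - p| between an empirical counts
    table (aligned with the joint's outcome order) and the exact joint."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != joint.probs.shape:
        raise ValueError("counts do not match the joint's outcome space")
    total = counts.sum()
    if total <= 0:
        raise ValueError("counts table is empty")
    return float(0.5 * np.abs(counts / total - joint.probs).sum())


def empirical_counts(
    joint: JointTable, seq: np.ndarray, struct: np.ndarray
) -> np.ndarray:
    """Histogram sampled (seq, struct) arrays over the joint's outcomes."""
    idx = joint.encode(seq, struct)
    return np.bincount(idx, minlength=joint.n_outcomes).astype(np.float64)


def plot_entropy_vs_steps(
    steps: Sequence[int],
    means: Sequence[float],
    std_errs: Sequence[float],
    path: str,
) -> None:
    """Generation entropy against the sampling-step budget."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.errorbar(steps, means, yerr=std_errs, marker="o", capsize=3)
    ax.set_xscale("log")
    ax.set_xlabel("sampling steps")
    ax.set_ylabel("generation entropy (nats / residue)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_accuracy_vs_time(result: Mapping[str, np.ndarray], path: str) -> None:
    """Unmasking accuracy per track over the flow-time grid, as produced
    by :func:`unmasking_accuracy`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for track in ("sequence", "structure"):
        ax.plot(result["t"], result[track], marker="o", label=track)
    ax.set_xlabel("flow time t (unmasked fraction)")
    ax.set_ylabel("masked-token accuracy")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def self_consistency(
    samples: Sequence[ProteinTokens], params: ToyWorldParams
) -> float:
    """Mean per-position agreement between each sample's structure track
    and the co-fold oracle's decoding of its sequence — the toy analogue
    of refolding a designed sequence and comparing structures."""
    if len(samples) == 0:
        raise ValueError("no samples")
    rv = params.struct_vocab
    agree = []
    for x in samples:
        if x.seq.has_mask(params.seq_vocab) or x.struct.has_mask(rv):
            raise ValueError("samples must be fully observed")
        decoded = cofold_oracle(x.seq, params)
        agree.append(np.mean(decoded.tokens == x.struct.tokens))
    return float(np.mean(agree))
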