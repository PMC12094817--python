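"""Time-conditioned transformer denoiser for the joint discrete flow.

A compact bidirectional transformer reads the partially masked sequence
and structure tracks (their embeddings are summed with a learned position
embedding) together with the flow time t, and predicts for every residue
two categorical distributions over the non-mask tokens of each
vocabulary.  Time enters as Fourier features injected additively at the
input of every block ("layer-wise"), so the network can adapt its
behaviour along the trajectory.  Training minimises cross-entropy of the
predictions against the clean protein x1 at corrupted positions, with
the corruption time drawn uniformly per example.

Implemented directly on numpy via :mod:`pairflow.autodiff`; runs on a
single CPU at toy scale (a few blocks, model dim around 128).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .flow_core import corrupt_tokens
from .types import ProteinTokens, Vocabulary

__all__ = [
    "DenoiserConfig",
    "TrainConfig",
    "fourier_time_features",
    "TransformerDenoiser",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyper-parameters (defaults are desk scale)."""

    seq_vocab_size: int
    struct_vocab_size: int
    n_blocks: int = 4
    model_dim: int = 128
    n_heads: int = 4
    time_feature_dim: int = 32
    max_len: int = 64

    def __post_init__(self) -> None:
        if self.time_feature_dim % 2 != 0 or self.time_feature_dim < 2:
            raise ValueError("time_feature_dim must be even and >= 2")
        if self.model_dim % self.n_heads != 0:
            raise ValueError("model_dim must be divisible by n_heads")
        if min(self.seq_vocab_size, self.struct_vocab_size) < 2:
            raise ValueError("vocabularies must have at least 2 tokens")


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop knobs.

    ``loss_positions`` selects where cross-entropy is accumulated:
    ``masked_only`` (default — unmasked positions are given and carry no
    learning signal under the flow factorisation) or ``all``.
    ``shared_time`` corrupts both tracks at one sampled t per example;
    set False for independent per-track times.
    """

    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    loss_positions: str = "masked_only"
    shared_time: bool = True
    lr_schedule: str = "cosine"
    ema_decay: float = 0.998

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.loss_positions not in ("masked_only", "all"):
            raise ValueError("loss_positions must be 'masked_only' or 'all'")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must lie in [0, 1)")


_FREQ_LO, _FREQ_HI = 1.0, 1000.0


def fourier_time_features(t: float, dim: int) -> np.ndarray:
    """Sinusoidal encoding of the flow time.

    ``dim/2`` log-spaced frequencies in [1, 1000]; per frequency the pair
    (sin 2*pi*f*t, cos 2*pi*f*t) is emitted, interleaved.  Deterministic
    in (t, dim); at t=0 all sines are 0 and all cosines 1.
    """
    if dim % 2 != 0 or dim < 2:
        raise ValueError("dim must be even and >= 2")
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    return _fourier_matrix(np.asarray([t]), dim)[0]


def _fourier_matrix(ts: np.ndarray, dim: int) -> np.ndarray:
    """Vectorised feature rows for an array of times, shape (len(ts), dim)."""
    freqs = np.logspace(np.log10(_FREQ_LO), np.log10(_FREQ_HI), dim // 2)
    phase = 2.0 * np.pi * ts[:, None] * freqs[None, :]
    out = np.empty((ts.shape[0], dim))
    out[:, 0::2] = np.sin(phase)
    out[:, 1::2] = np.cos(phase)
    return out


class TransformerDenoiser:
    """Bidirectional transformer emitting two per-residue distributions.

    Satisfies the sampler's denoiser contract: calling the model on
    (batch, N) token arrays and a time t returns two (batch, N, K)
    probability arrays whose rows sum to 1 with exactly zero mass at each
    vocabulary's mask index (mask logits are excluded before the softmax,
    not merely suppressed).
    """

    def __init__(self, config: DenoiserConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.model_dim
        tfd = config.time_feature_dim
        ks, kr = config.seq_vocab_size, config.struct_vocab_size

        def w(*shape: int, scale: float = 0.02) -> ad.Tensor:
            return ad.parameter(rng.normal(0.0, scale, shape).astype(np.float32))

        def zeros(*shape: int) -> ad.Tensor:
            return ad.parameter(np.zeros(shape, dtype=np.float32))

        def ones(*shape: int) -> ad.Tensor:
            return ad.parameter(np.ones(shape, dtype=np.float32))

        p: dict[str, ad.Tensor] = {
            "emb_seq": w(ks, d),
            "emb_struct": w(kr, d),
            "emb_pos": w(config.max_len, d),
            "ln_f_g": ones(d),
            "ln_f_b": zeros(d),
            "head_seq_w": w(d, ks - 1),
            "head_seq_b": zeros(ks - 1),
            "head_struct_w": w(d, kr - 1),
            "head_struct_b": zeros(kr - 1),
        }
        for i in range(config.n_blocks):
            p[f"b{i}_time_w"] = w(tfd, d)
            p[f"b{i}_time_b"] = zeros(d)
            p[f"b{i}_ln1_g"] = ones(d)
            p[f"b{i}_ln1_b"] = zeros(d)
            p[f"b{i}_wq"] = w(d, d)
            p[f"b{i}_wk"] = w(d, d)
            p[f"b{i}_wv"] = w(d, d)
            p[f"b{i}_wo"] = w(d, d)
            p[f"b{i}_bo"] = zeros(d)
            p[f"b{i}_ln2_g"] = ones(d)
            p[f"b{i}_ln2_b"] = zeros(d)
            p[f"b{i}_mlp_w1"] = w(d, 4 * d)
            p[f"b{i}_mlp_b1"] = zeros(4 * d)
            p[f"b{i}_mlp_w2"] = w(4 * d, d)
            p[f"b{i}_mlp_b2"] = zeros(d)
        self.params = p

    # -- forward ----------------------------------------------------------

    def _trunk(
        self, seq_tokens: np.ndarray, struct_tokens: np.ndarray, t: float | np.ndarray
    ) -> tuple[ad.Tensor, ad.Tensor]:
        """Run the network; returns the two logit tensors over non-mask
        tokens, shapes (batch, N, Ks-1) and (batch, N, Kr-1).

        ``t`` may be a scalar (one time for the whole batch) or a length-
        batch array of per-example times.
        """
        cfg = self.config
        S = np.asarray(seq_tokens)
        R = np.asarray(struct_tokens)
        if S.shape != R.shape or S.ndim != 2:
            raise ValueError("token tracks must be matching (batch, N) arrays")
        b, n = S.shape
        if n > cfg.max_len:
            raise ValueError(f"length {n} exceeds max_len {cfg.max_len}")
        p = self.params
        d, h = cfg.model_dim, cfg.n_heads
        hd = d // h

        ts = np.atleast_1d(np.asarray(t, dtype=np.float64))
        if np.any(ts < 0) or np.any(ts > 1):
            raise ValueError("t must lie in [0, 1]")
        tf = ad.Tensor(
            _fourier_matrix(ts, cfg.time_feature_dim)[:, None, :].astype(np.float32)
        )  # (1 or b, 1, tfd) — broadcasts over positions
        x = ad.add(
            ad.add(ad.embedding(p["emb_seq"], S), ad.embedding(p["emb_struct"], R)),
            ad.embedding(p["emb_pos"], np.arange(n)),
        )
        for i in range(cfg.n_blocks):
            tproj = ad.add(ad.matmul(tf, p[f"b{i}_time_w"]), p[f"b{i}_time_b"])
            x = ad.add(x, tproj)  # layer-wise time injection at block input

            a = ad.layer_norm(x, p[f"b{i}_ln1_g"], p[f"b{i}_ln1_b"])

            def heads(tensor: ad.Tensor) -> ad.Tensor:
                return ad.transpose(ad.reshape(tensor, (b, n, h, hd)), (0, 2, 1, 3))

            q = heads(ad.matmul(a, p[f"b{i}_wq"]))
            k = heads(ad.matmul(a, p[f"b{i}_wk"]))
            v = heads(ad.matmul(a, p[f"b{i}_wv"]))
            scores = ad.mul_scalar(
                ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(hd)
            )
            att = ad.matmul(ad.softmax(scores), v)  # (b, h, n, hd)
            att = ad.reshape(ad.transpose(att, (0, 2, 1, 3)), (b, n, d))
            x = ad.add(x, ad.add(ad.matmul(att, p[f"b{i}_wo"]), p[f"b{i}_bo"]))

            m = ad.layer_norm(x, p[f"b{i}_ln2_g"], p[f"b{i}_ln2_b"])
            m = ad.gelu(ad.add(ad.matmul(m, p[f"b{i}_mlp_w1"]), p[f"b{i}_mlp_b1"]))
            x = ad.add(x, ad.add(ad.matmul(m, p[f"b{i}_mlp_w2"]), p[f"b{i}_mlp_b2"]))

        xf = ad.layer_norm(x, p["ln_f_g"], p["ln_f_b"])
        logit_s = ad.add(ad.matmul(xf, p["head_seq_w"]), p["head_seq_b"])
        logit_r = ad.add(ad.matmul(xf, p["head_struct_w"]), p["head_struct_b"])
        return logit_s, logit_r

    @staticmethod
    def _to_probs(logits: np.ndarray, vocab_size: int) -> np.ndarray:
        """Softmax over non-mask logits, mask column (last index) pinned to
        exactly zero, rows renormalised in float64."""
        z = logits.astype(np.float64)
        z -= z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        probs = np.zeros(logits.shape[:-1] + (vocab_size,))
        probs[..., : vocab_size - 1] = e / e.sum(axis=-1, keepdims=True)
        return probs

    def __call__(
        self,
        seq_tokens: np.ndarray,
        struct_tokens: np.ndarray,
        t: float,
        chunk: int = 512,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Inference: probability arrays (batch, N, K) per track.

        Assumes each vocabulary's mask index is its last index (the
        package's vocabulary constructors guarantee this).  Batches are
        processed in chunks to bound memory.
        """
        cfg = self.config
        S = np.asarray(seq_tokens)
        R = np.asarray(struct_tokens)
        ps_parts, pr_parts = [], []
        with ad.no_grad():
            for lo in range(0, S.shape[0], chunk):
                ls, lr = self._trunk(S[lo : lo + chunk], R[lo : lo + chunk], t)
                ps_parts.append(self._to_probs(ls.data, cfg.seq_vocab_size))
                pr_parts.append(self._to_probs(lr.data, cfg.struct_vocab_size))
        return np.concatenate(ps_parts), np.concatenate(pr_parts)

    @property
    def param_list(self) -> list[ad.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    # -- training ---------------------------------------------------------

    def fit(
        self,
        dataset: Sequence[ProteinTokens] | tuple[np.ndarray, np.ndarray],
        tcfg: TrainConfig,
        seq_vocab: Optional[Vocabulary] = None,
        struct_vocab: Optional[Vocabulary] = None,
    ) -> np.ndarray:
        """Train in place; returns the per-epoch mean loss trace.

        Each example is corrupted at a freshly drawn t ~ Uniform(0, 1)
        (shared across tracks by default) and the model is asked to
        recover the clean tokens; the loss is the sum over tracks of the
        masked-position mean cross-entropy.  Optimisation is Adam with a
        cosine learning-rate decay by default, and an exponential moving
        average of the weights is swapped in at the end of training
        (``ema_decay = 0`` disables the average); both stabilise the
        calibration of the predicted distributions.
        """
        cfg = self.config
        S1, R1 = _dataset_arrays(dataset)
        if S1.shape[0] == 0:
            raise ValueError("training dataset is empty")
        if np.any(S1 >= cfg.seq_vocab_size - 1) or np.any(R1 >= cfg.struct_vocab_size - 1):
            raise ValueError("training items must be fully observed (no masks)")
        mask_s = cfg.seq_vocab_size - 1
        mask_r = cfg.struct_vocab_size - 1

        rng = np.random.default_rng(tcfg.seed)
        opt = ad.Adam(self.param_list, lr=tcfg.learning_rate)
        n = S1.shape[0]
        n_batches = int(np.ceil(n / tcfg.batch_size))
        total_steps = tcfg.epochs * n_batches
        ema = (
            [p.data.copy() for p in self.param_list]
            if tcfg.ema_decay > 0
            else None
        )
        step = 0
        trace = []
        for _ in range(tcfg.epochs):
            perm = rng.permutation(n)
            losses = []
            for lo in range(0, n, tcfg.batch_size):
                idx = perm[lo : lo + tcfg.batch_size]
                s1, r1 = S1[idx], R1[idx]
                t_s = rng.random(idx.size)
                t_r = t_s if tcfg.shared_time else rng.random(idx.size)
                st = corrupt_tokens(s1, t_s, rng, mask_s)
                rt = corrupt_tokens(r1, t_r, rng, mask_r)
                if tcfg.loss_positions == "masked_only":
                    ws = (st == mask_s).astype(np.float64)
                    wr = (rt == mask_r).astype(np.float64)
                else:
                    ws = np.ones_like(st, dtype=np.float64)
                    wr = np.ones_like(rt, dtype=np.float64)
                if ws.sum() == 0 and wr.sum() == 0:
                    continue
                # per-example time conditioning (mean of the two track
                # times; identical to t_s under shared_time)
                ls, lr = self._trunk(st, rt, (t_s + t_r) / 2.0)
                opt.zero_grad()
                terms = []
                if ws.sum() > 0:
                    loss_s, _ = ad.masked_cross_entropy(ls, s1, ws)
                    terms.append(loss_s)
                if wr.sum() > 0:
                    loss_r, _ = ad.masked_cross_entropy(lr, r1, wr)
                    terms.append(loss_r)
                total = terms[0] if len(terms) == 1 else ad.add(terms[0], terms[1])
                total.backward()
                if tcfg.lr_schedule == "cosine":
                    opt.lr = tcfg.learning_rate * 0.5 * (
                        1.0 + np.cos(np.pi * step / max(total_steps - 1, 1))
                    )
                opt.step()
                step += 1
                if ema is not None:
                    d = tcfg.ema_decay
                    for shadow, p in zip(ema, self.param_list):
                        shadow *= d
                        shadow += (1 - d) * p.data
                losses.append(float(total.data))
            # an epoch can (rarely) skip every batch when no positions were
            # masked; carry the previous epoch's mean forward in that case
            if losses:
                trace.append(float(np.mean(losses)))
            else:
                trace.append(trace[-1] if trace else float("nan"))
        if ema is not None:
            # shadow starts from the initial weights, so no bias correction
            for shadow, p in zip(ema, self.param_list):
                p.data = shadow.astype(np.float32)
        return np.asarray(trace)


def _dataset_arrays(
    dataset: Sequence[ProteinTokens] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        S, R = dataset
        return np.asarray(S, dtype=np.int64), np.asarray(R, dtype=np.int64)
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    lengths = {len(x) for x in dataset}
    if len(lengths) != 1:
        raise ValueError("training items must share one length")
    S = np.stack([x.seq.tokens for x in dataset])
    R = np.stack([x.struct.tokens for x in dataset])
    return S, R


def uniform_baseline_loss(seq_vocab: Vocabulary, struct_vocab: Vocabulary) -> float:
    """Cross-entropy of the uniform distribution over non-mask tokens,
    summed over the two tracks: log(Ks-1) + log(Kr-1)."""
    return float(np.log(seq_vocab.n_real) + np.log(struct_vocab.n_real))


def train(
    dataset: Sequence[ProteinTokens] | tuple[np.ndarray, np.ndarray],
    dcfg: DenoiserConfig,
    tcfg: TrainConfig,
) -> tuple[TransformerDenoiser, np.ndarray]:
    """Build a fresh model (seeded from the train config) and fit it."""
    model = TransformerDenoiser(dcfg, seed=tcfg.seed)
    trace = model.fit(dataset, tcfg)
    return model, trace


def save_checkpoint(model: TransformerDenoiser, path: str) -> None:
    """Single-file checkpoint: config header plus all weight arrays."""
    arrays = {k: t.data for k, t in model.params.items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    ), **arrays)


def load_checkpoint(path: str) -> TransformerDenoiser:
    with np.load(path) as data:
        cfg = DenoiserConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = TransformerDenoiser(cfg, seed=0)
        for k, t in model.params.items():
            t.data = data[k].astype(np.float32)
    return model
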