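# Methods

## Model

pairflow implements a joint discrete generative flow over paired token
tracks.  A protein is x = (s, r): s are amino-acid tokens, r are discrete
structure tokens (codes for local backbone geometry, as produced by a
vector-quantised autoencoder in full-scale systems; here a toy alphabet).
Both tracks share the residue index i = 1..N and each vocabulary carries
an absorbing mask symbol (Ms, Mr).

The flow interpolates between pure mask at time t = 0 and a data point at
t = 1.  Per residue and track, the conditional flow is linear:

    p(s_t | s_1) = t · f(s_1) + (1 − t) · f(Ms)

with f the one-hot encoding; sequence and structure, and residues within
a track, interpolate independently.  Marginalising over the data
distribution defines the path p_t = E_{x1~p_data} p(x_t | x1).

Sampling integrates the continuous-time Markov chain forward with Euler
steps of size Δt.  For a masked position the posterior kernel is

    q(x_{t+Δt} | x_t = M) = c · f_θ + (1 − c) · f(M),
    c = Δt (1 + η t) / (1 − t),

where f_θ is the denoiser's predicted categorical distribution over
non-mask tokens.  For an unmasked position the kernel keeps the token,
except that balanced noise η > 0 reverts it to mask with probability
η Δt — but never at the track's final step, so samples finish mask-free.
η = 0 recovers the absorbing case where unmasked tokens are frozen
(Δt/(1−t) unmask rate only).

The denoiser is a compact bidirectional transformer (default 4 blocks,
model dim 128, 4 heads) over the summed sequence/structure/position
embeddings, with sinusoidal time features injected additively at the
input of every block.  Two linear heads emit per-residue logits over the
non-mask tokens of each vocabulary; the mask column is excluded before
the softmax, so predicted mask mass is exactly zero by construction.
Training draws t ~ Uniform(0, 1) per example, corrupts both tracks at
that time, and minimises cross-entropy against the clean tokens at the
masked positions (unmasked positions are given under the flow
factorisation and carry no signal; an `all`-positions switch exists for
ablation).

Conditioning is by partial masking: a task supplies given tokens
(folding: the whole sequence; inverse folding: the whole structure;
motif scaffolding: both tracks on a residue subset) and those positions
are flagged.  Flagged positions get an identity kernel — they are never
resampled and never η-reverted, which keeps the task contract intact.

## Numerical and design choices

* **Time schedule.** Uniform grid t_k = k/steps, Δt = 1/steps.  On this
  grid Δt/(1 − t_k) ≤ 1 always; with η > 0 the unmask coefficient can
  exceed 1 near t = 1 and is clamped to 1, which preserves a valid
  distribution and forces full unmasking.
* **Track strategies.**  `synchronous` updates both tracks every step;
  `asynchronous` alternates strictly, sequence on even steps;
  `sequence_first`/`structure_first` split the step budget 50/50.  An
  inactive track is frozen and keeps its own uniform time grid over the
  steps at which it is active, so each track's unmask rate Δt/(1 − t)
  is internally consistent and reaches t = 1.  The denoiser is
  conditioned on global progress k/steps.
* **Temperature.** A power transform p^(1/T), renormalised, applied to
  denoiser rows before the kernel; default T = 1 (faithful sampling).
  It is held fixed across strategy comparisons.
* **RNG discipline.** One seeded generator per run; draws are consumed
  in position order, sequence track before structure track within a
  step, so trajectories are bit-reproducible given the seed.
* **Fourier time features.** dim/2 log-spaced frequencies in [1, 1000];
  per frequency the (sin, cos) pair is emitted.  Layer-wise injection =
  a learned linear projection of the feature vector added to each
  block's input.
* **Optimiser.** Adam with cosine learning-rate decay to zero and an
  exponential moving average of the weights (decay 0.998) swapped in at
  the end of training.  The averaging matters: a constant-rate run
  reaches nearly the same cross-entropy but leaves the predicted
  distributions miscalibrated, and because unconditional sampling
  composes ~N sequential conditionals, small per-step calibration errors
  compound into visible marginal drift.  With averaging, sampled
  per-position marginals sit close to the sampling-noise floor.
* **Numerics.** The transformer runs in float32 (single-CPU speed);
  probability fields handed to the sampler are renormalised in float64,
  and all kernel rows sum to 1 within 1e-12.  The engine behind the
  transformer is a small reverse-mode autodiff on numpy, gradient-checked
  against central finite differences.
* **Greedy decoding for sequence recovery.**  Native-sequence-recovery
  (NSR) evaluation uses temperature → 0 (argmax decoding).  The Bayes
  ceiling it is compared against is the accuracy of the per-position MAP
  predictor, E_r[mean_i max_k p(s_i = k | r)]; faithful temperature-1
  sampling cannot approach that ceiling even with a perfect model (its
  asymptote is E[Σ_k p(s_i = k | r)²]), so greedy decoding — the field's
  standard for recovery metrics — is used for this metric only.
  Distribution-recovery metrics always use temperature 1.
* **Generation entropy.** Natural log; the Shannon entropy of the
  (temperature-adjusted) predictor row in force at each position's final
  unmasking event, summed over positions and both tracks and divided by
  N (per-residue normalisation, making lengths comparable).  Positions
  given as conditioning contribute zero.

## The synthetic world

Real proteins couple amino-acid identity to local backbone geometry via
secondary structure.  The toy world emulates that coupling with a hidden
first-order Markov chain z (H = 3 states by default, think
helix/sheet/coil) emitting one sequence token (6-letter alphabet) and
one structure token (8-letter alphabet) per residue, conditionally
independently given the state.  Defaults are strongly coupled: the
hidden chain stays in its state with probability 0.8, and each state
puts 0.7 of its emission mass on a state-specific preferred token.
These defaults give the two tracks clearly positive mutual information
and leave headroom between the majority-class baseline (~0.27) and the
inverse-folding Bayes ceiling (~0.62), so recovery metrics are
informative.

The construction is chosen for exactness, not realism: the joint
distribution over (s, r) is computable by forward recursion (enumeration
guard: 10^6 outcomes), per-position conditionals given any observation
pattern come from forward–backward, and a Viterbi-style max-product
"co-fold" oracle decodes a structure track from a sequence as a
deterministic stand-in for refolding-based consistency checks.  What the
toy world does not emulate: 3-D geometry and its metrics (RMSD, TM-score),
long-range contacts beyond the first-order hidden chain, length
variation within a dataset, and the heavy-tailed residue statistics of
real proteins.  Tests passing here show the flow machinery is correct
and that the learning problem it defines is solved near-optimally; they
do not certify performance on real proteins.

## Problem sizes

All experiments run on one CPU.  The trained-model study uses 5000
training proteins of length 16, a 4-block/128-dim denoiser, 20 epochs of
Adam (batch 128) — about five minutes of training.  Distribution-recovery
runs use 20 000 sampler draws on an N = 3 world (H = 2, 3 + 3 tokens,
729 outcomes) where the joint is enumerable, at 200 Euler steps.
Unconditional marginal recovery uses 2000 draws at 100 steps; entropy
ablations use 200 draws per condition (steps 50 vs 400; synchronous vs
asynchronous).  At 20 000 draws, the sampling-noise floor of the total
variation to a 729-outcome joint is ≈ 0.062 (exact binomial expectation);
observed TVs at that n sit on the floor and shrink as 1/√n, which is the
evidence that the sampler is unbiased.

## Known limitations

* The denoiser is desk-scale; it substitutes a 4-block numpy transformer
  for a large pretrained multi-modal language model, and its absolute
  metric values are meaningful only relative to the toy world's
  enumerated baselines and ceilings.
* The strategy definitions beyond `synchronous` follow the package's own
  conventions (strict alternation starting with the sequence track;
  50/50 sequential split); other conventions exist.
* η is user-configurable with default 0; correctness laws with closed
  forms (mask-fraction, absorption) hold at η = 0, while η > 0 is
  exercised as a property (re-mask events occur, outputs still finish
  mask-free, distribution recovery unchanged).
* Only equal-length datasets are supported in training batches.
* At N = 16 the entropy-vs-steps ablation has a very small effect size:
  with 50 steps the sampler is already close to one-token-at-a-time
  decoding, so most of the context benefit of extra steps is saturated.
  The comparison is therefore directional, evaluated with paired seeds
  and a three-standard-error reversal rule over 200 samples; at longer
  lengths the trend would separate further.
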