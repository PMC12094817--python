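# pairflow

Joint discrete flow matching for protein sequence–structure co-design,
at desk scale.

Protein design increasingly treats a protein as two aligned strings: the
amino-acid sequence s = s¹..sᴺ and a track of discrete structure tokens
r = r¹..rᴺ encoding local backbone geometry.  Generating the two tracks
*jointly* — rather than structure-then-sequence — lets information flow
both ways across the sequence–structure landscape.  pairflow implements
the generative machinery for this setting as a small, fully tested
library: researchers who want to study masked discrete flows, their
samplers and their conditioning behaviour can run every experiment on a
laptop CPU against exact enumeration oracles instead of a GPU cluster
and a folding model.

## The model

A masked linear-interpolation flow per residue and track,

    p(sₜ | s₁) = t·f(s₁) + (1 − t)·f(Mₛ),

bridges pure mask (t = 0) and data (t = 1); f is one-hot encoding and
Mₛ the absorbing mask token.  Sampling integrates the posterior
continuous-time Markov chain with Euler steps: a masked position unmasks
into the denoiser's predicted distribution f_θ with probability
Δt(1 + ηt)/(1 − t), and balanced noise η > 0 lets placed tokens revert
to mask (never at the final step), enabling self-correction.  The
denoiser is a bidirectional transformer over both tracks with Fourier
time features injected at every block, trained with cross-entropy on
masked positions at t ~ Uniform(0, 1).  Conditioning is by partial
masking: fix the sequence to fold, fix the structure to inverse-fold,
fix a motif on both tracks to scaffold it.

Because full-scale metrics (scRMSD, pTM, TM-score) need external folding
models, pairflow ships an exactly solvable synthetic world instead: a
hidden Markov chain (helix/sheet/coil-like) emits coupled sequence and
structure tokens, so the joint distribution, all conditionals, the
inverse-folding Bayes ceiling and a co-fold oracle are all computable in
closed form and every claim about the sampler can be checked against
enumeration.

## Worked example

```python
from pairflow import (
    ToyWorldParams, HMMPosteriorDenoiser, ProteinTokens, ConditionMask,
    SamplerConfig, euler_sample, generation_entropy, enumerate_joint,
)

world = ToyWorldParams.default(n_hidden=2, n_seq_tokens=3, n_struct_tokens=3)
den = HMMPosteriorDenoiser(world)            # exact p(x1 | observed)
x0 = ProteinTokens.fully_masked(3, world.seq_vocab, world.struct_vocab)
cfg = SamplerConfig(steps=200, eta=0.0, seed=1)
sample, traj = euler_sample(den, x0, ConditionMask.none(3),
                            cfg, world.seq_vocab, world.struct_vocab)
joint = enumerate_joint(world, 3)
print("sequence tokens :", sample.seq.tokens)
print("structure tokens:", sample.struct.tokens)
print("entropy/residue :", round(generation_entropy(traj), 3))
print("P(sample) exact :", round(float(joint.probs[
    joint.encode(sample.seq.tokens[None], sample.struct.tokens[None])[0]]), 5))
```

prints

```
sequence tokens : [1 0 0]
structure tokens: [0 0 0]
entropy/residue : 1.889
P(sample) exact : 0.00865
```

— an all-mask start unmasked into a typical protein of this world
(mostly the state-0 preferred tokens), with a per-residue generation
entropy of 1.89 nats (the sampler's average uncertainty at the moments
tokens were placed); the enumerated joint assigns that exact outcome
probability 0.0087.  Training and sampling the transformer denoiser
works the same way from Python, or from the shell:

```bash
pairflow generate-data --seed 1 --n 5000 --length 16 --out data/
pairflow train --data data/ --out run/
pairflow sample --checkpoint run/checkpoint.npz --world-params data/world.yaml \
                --task unconditional --n 100 --steps 400 --out samples/
pairflow evaluate --samples samples/ --world-params data/world.yaml --out metrics/
```

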