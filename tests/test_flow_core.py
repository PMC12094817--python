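"""Unit and property tests for the flow mathematics and the Euler sampler."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairflow import flow_core as fc
from pairflow import synthetic_data as sd
from pairflow.types import (
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

AA4 = Vocabulary.amino_acids(4)
SC4 = Vocabulary.structure_codes(4)


def uniform_pred(n: int, vocab: Vocabulary) -> CategoricalField:
    probs = np.full((n, vocab.size), 1.0 / vocab.n_real)
    probs[:, vocab.mask_index] = 0.0
    return CategoricalField(probs)


class TestInterpolateConditional:
    def test_endpoints_exact(self):
        x1 = TokenTrack(np.array([0, 2, 1]), SEQUENCE)
        at0 = fc.interpolate_conditional(x1, 0.0, AA4)
        assert np.array_equal(at0.probs[:, AA4.mask_index], np.ones(3))
        at1 = fc.interpolate_conditional(x1, 1.0, AA4)
        assert np.array_equal(at1.argmax(), x1.tokens)
        assert np.all(at1.probs.max(axis=1) == 1.0)

    def test_linear_mixture(self):
        x1 = TokenTrack(np.array([2]), SEQUENCE)
        f = fc.interpolate_conditional(x1, 0.25, AA4)
        assert f.probs[0, 2] == pytest.approx(0.25)
        assert f.probs[0, AA4.mask_index] == pytest.approx(0.75)
        assert f.probs[0, [0, 1]] == pytest.approx([0.0, 0.0])

    def test_rejects_bad_inputs(self):
        x1 = TokenTrack(np.array([0]), SEQUENCE)
        with pytest.raises(ValueError):
            fc.interpolate_conditional(x1, 1.5, AA4)
        masked = TokenTrack(np.array([AA4.mask_index]), SEQUENCE)
        with pytest.raises(ValueError):
            fc.interpolate_conditional(masked, 0.5, AA4)

    @given(st.floats(0.0, 1.0))
    def test_rows_normalised(self, t):
        x1 = TokenTrack(np.array([0, 1, 2, 3]), SEQUENCE)
        f = fc.interpolate_conditional(x1, t, AA4)
        assert np.abs(f.probs.sum(axis=1) - 1.0).max() <= 1e-12


class TestCorrupt:
    def test_extremes(self, rng):
        x1 = ProteinTokens.from_arrays([0, 1, 2], [3, 2, 1])
        same = fc.corrupt(x1, 1.0, 1.0, rng, AA4, SC4)
        assert same == x1
        gone = fc.corrupt(x1, 0.0, 0.0, rng, AA4, SC4)
        assert np.all(gone.seq.tokens == AA4.mask_index)
        assert np.all(gone.struct.tokens == SC4.mask_index)

    def test_mask_fraction_concentration(self, rng):
        # binomial law: masked fraction ~ 1 - t within 3 sigma
        n = 1000
        tokens = rng.integers(0, 4, n)
        masked = fc.corrupt_tokens(tokens[None, :], 0.5, rng, AA4.mask_index)
        frac = np.mean(masked == AA4.mask_index)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_rejects_masked_input(self, rng):
        bad = ProteinTokens.from_arrays([AA4.mask_index], [0])
        with pytest.raises(ValueError):
            fc.corrupt(bad, 0.5, 0.5, rng, AA4, SC4)


class TestTransitionKernel:
    def test_masked_row_eta0(self):
        # unmask coefficient dt/(1-t) = 0.2 spread over uniform prediction
        xt = TokenTrack(np.array([AA4.mask_index]), SEQUENCE)
        time = FlowTime(t=0.5, dt=0.1, step_index=5, is_last=False)
        kern = fc.transition_kernel(xt, uniform_pred(1, AA4), time, 0.0, AA4)
        assert kern.probs[0, :4] == pytest.approx(np.full(4, 0.05))
        assert kern.probs[0, AA4.mask_index] == pytest.approx(0.8)

    def test_unmasked_row_eta0_is_point_mass(self):
        xt = TokenTrack(np.array([1]), SEQUENCE)
        time = FlowTime(t=0.3, dt=0.1, step_index=3, is_last=False)
        kern = fc.transition_kernel(xt, uniform_pred(1, AA4), time, 0.0, AA4)
        assert kern.probs[0, 1] == 1.0

    def test_balanced_noise_reversion(self):
        xt = TokenTrack(np.array([1]), SEQUENCE)
        time = FlowTime(t=0.3, dt=0.01, step_index=30, is_last=False)
        kern = fc.transition_kernel(xt, uniform_pred(1, AA4), time, 2.0, AA4)
        assert kern.probs[0, AA4.mask_index] == pytest.approx(0.02)
        assert kern.probs[0, 1] == pytest.approx(0.98)

    def test_balanced_noise_unmask_bonus(self):
        # total unmask mass dt * (1 + eta*t) / (1-t) = 0.4
        xt = TokenTrack(np.array([AA4.mask_index]), SEQUENCE)
        time = FlowTime(t=0.5, dt=0.1, step_index=5, is_last=False)
        kern = fc.transition_kernel(xt, uniform_pred(1, AA4), time, 2.0, AA4)
        assert kern.probs[0, :4].sum() == pytest.approx(0.4)
        assert kern.probs[0, AA4.mask_index] == pytest.approx(0.6)

    def test_last_step_blocks_reversion(self):
        xt = TokenTrack(np.array([1]), SEQUENCE)
        time = FlowTime(t=0.9, dt=0.1, step_index=9, is_last=True)
        kern = fc.transition_kernel(xt, uniform_pred(1, AA4), time, 2.0, AA4)
        assert kern.probs[0, 1] == 1.0

    def test_unmask_coefficient_clamps_to_one(self):
        # with eta > 0 the raw coefficient can exceed 1; rows stay distributions
        xt = TokenTrack(np.array([AA4.mask_index]), SEQUENCE)
        time = FlowTime(t=0.9, dt=0.1, step_index=9, is_last=True)
        kern = fc.transition_kernel(xt, uniform_pred(1, AA4), time, 5.0, AA4)
        assert kern.probs[0, AA4.mask_index] == pytest.approx(0.0)
        assert kern.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_contract_violations(self):
        xt = TokenTrack(np.array([0]), SEQUENCE)
        time = FlowTime(t=0.5, dt=0.1, step_index=0, is_last=False)
        leaky = np.array([[0.2, 0.2, 0.2, 0.2, 0.2]])
        with pytest.raises(ValueError):
            fc.transition_kernel(xt, CategoricalField(leaky), time, 0.0, AA4)
        with pytest.raises(ValueError):
            fc.transition_kernel(xt, uniform_pred(1, AA4), time, 20.0, AA4)

    @given(
        st.integers(1, 398),
        st.integers(2, 400),
        st.floats(0.0, 3.0),
        st.integers(0, 2**31 - 1),
    )
    def test_rows_always_normalised(self, k, steps, eta, seed):
        # random (t, dt, eta, f_pred) draws: rows sum to 1 within 1e-12
        k = k % steps
        t, dt = k / steps, 1.0 / steps
        g = np.random.default_rng(seed)
        raw = g.random((5, AA4.n_real))
        probs = np.zeros((5, AA4.size))
        probs[:, : AA4.n_real] = raw / raw.sum(axis=1, keepdims=True)
        tokens = g.integers(0, AA4.size, 5)
        time = FlowTime(t=t, dt=dt, step_index=k, is_last=(k == steps - 1))
        if eta * dt > 1:
            return
        kern = fc.transition_kernel(
            TokenTrack(tokens, SEQUENCE), CategoricalField(probs), time, eta, AA4
        )
        assert np.abs(kern.probs.sum(axis=1) - 1.0).max() <= 1e-12


class TestEulerSampler:
    def test_delta_denoiser_reproduces_target(self):
        target = ProteinTokens.from_arrays([0, 1, 2, 3, 0], [3, 2, 1, 0, 3])
        den = fc.DeltaDenoiser(target, AA4, SC4)
        x0 = ProteinTokens.fully_masked(5, AA4, SC4)
        out, traj = fc.euler_sample(
            den, x0, ConditionMask.none(5), SamplerConfig(steps=17, seed=0), AA4, SC4
        )
        assert out == target
        assert len(traj) == 17

    def test_no_masks_under_noise_and_absorption_without(self):
        target = ProteinTokens.from_arrays([0, 1, 2, 3], [3, 2, 1, 0])
        den = fc.DeltaDenoiser(target, AA4, SC4)
        x0 = ProteinTokens.fully_masked(4, AA4, SC4)
        out, traj = fc.euler_sample(
            den, x0, ConditionMask.none(4), SamplerConfig(steps=25, eta=0.0, seed=3),
            AA4, SC4,
        )
        # absorption: once unmasked, a position never changes when eta = 0
        prev = x0.seq.tokens
        for rec in traj.steps:
            fixed = prev != AA4.mask_index
            assert np.array_equal(rec.seq_tokens[fixed], prev[fixed])
            prev = rec.seq_tokens
        noisy, _ = fc.euler_sample(
            den, x0, ConditionMask.none(4), SamplerConfig(steps=25, eta=1.5, seed=3),
            AA4, SC4,
        )
        assert not noisy.seq.has_mask(AA4) and not noisy.struct.has_mask(SC4)

    def test_conditioning_immutable_and_validated(self, tiny_world):
        den = sd.HMMPosteriorDenoiser(tiny_world)
        sv, rv = tiny_world.seq_vocab, tiny_world.struct_vocab
        seq = np.array([0, sv.mask_index, 1, sv.mask_index])
        struct = np.full(4, rv.mask_index)
        x0 = ProteinTokens.from_arrays(seq, struct)
        cond = ConditionMask(np.array([1, 0, 1, 0], bool), np.zeros(4, bool))
        result, _ = fc.euler_sample_batch(
            den, x0, cond, SamplerConfig(steps=11, eta=1.0, seed=5), sv, rv,
            n_samples=32,
        )
        assert np.all(result.seq[:, [0, 2]] == [0, 1])
        bad_cond = ConditionMask(np.array([1, 1, 0, 0], bool), np.zeros(4, bool))
        with pytest.raises(ValueError):
            fc.euler_sample_batch(den, x0, bad_cond,
                                  SamplerConfig(steps=5), sv, rv)

    def test_denoiser_mask_mass_rejected(self):
        def leaky(S, R, t):
            ps = np.full((S.shape[0], S.shape[1], AA4.size), 1.0 / AA4.size)
            pr = np.full((R.shape[0], R.shape[1], SC4.size), 1.0 / SC4.size)
            return ps, pr

        x0 = ProteinTokens.fully_masked(3, AA4, SC4)
        with pytest.raises(ValueError):
            fc.euler_sample(leaky, x0, ConditionMask.none(3),
                            SamplerConfig(steps=4), AA4, SC4)

    def test_seeded_runs_reproducible(self, tiny_world):
        den = sd.HMMPosteriorDenoiser(tiny_world)
        sv, rv = tiny_world.seq_vocab, tiny_world.struct_vocab
        x0 = ProteinTokens.fully_masked(4, sv, rv)
        cfg = SamplerConfig(steps=19, eta=0.7, seed=42)
        a, _ = fc.euler_sample_batch(den, x0, ConditionMask.none(4), cfg, sv, rv, 8)
        b, _ = fc.euler_sample_batch(den, x0, ConditionMask.none(4), cfg, sv, rv, 8)
        assert np.array_equal(a.seq, b.seq) and np.array_equal(a.struct, b.struct)


class TestExactPosterior:
    def test_fully_observed_is_one_hot(self, small_world):
        jt = sd.enumerate_joint(small_world, 3)
        xt = ProteinTokens.from_arrays([0, 1, 2], [2, 1, 0])
        fs, fr = fc.exact_posterior_denoiser(jt, xt)
        assert np.array_equal(fs.argmax(), xt.seq.tokens)
        assert np.array_equal(fr.argmax(), xt.struct.tokens)
        assert np.all(fs.probs.max(axis=1) == 1.0)

    def test_independent_world_gives_marginals(self):
        world = sd.ToyWorldParams.default(n_hidden=1, n_seq_tokens=3, n_struct_tokens=3)
        jt = sd.enumerate_joint(world, 2)
        sv, rv = world.seq_vocab, world.struct_vocab
        xt = ProteinTokens.fully_masked(2, sv, rv)
        fs, fr = fc.exact_posterior_denoiser(jt, xt)
        assert fs.probs[:, :3] == pytest.approx(
            np.tile(world.emit_seq[0], (2, 1)), abs=1e-12
        )
        assert fr.probs[:, :3] == pytest.approx(
            np.tile(world.emit_struct[0], (2, 1)), abs=1e-12
        )

    def test_matches_brute_force_bayes(self, small_world):
        # independent oracle: explicit sum over all outcomes via itertools
        jt = sd.enumerate_joint(small_world, 2)
        sv, rv = small_world.seq_vocab, small_world.struct_vocab
        xt = ProteinTokens.from_arrays([1, sv.mask_index], [rv.mask_index, 2])
        fs, fr = fc.exact_posterior_denoiser(jt, xt)

        lut = {}
        for o in range(jt.n_outcomes):
            key = (tuple(jt.seq_outcomes[o]), tuple(jt.struct_outcomes[o]))
            lut[key] = jt.probs[o]
        num_s = np.zeros(3)
        num_r = np.zeros(3)
        z = 0.0
        for s in itertools.product(range(3), repeat=2):
            for r in itertools.product(range(3), repeat=2):
                if s[0] == 1 and r[1] == 2:
                    pr = lut[(s, r)]
                    z += pr
                    num_s[s[1]] += pr
                    num_r[r[0]] += pr
        assert fs.probs[1, :3] == pytest.approx(num_s / z, abs=1e-12)
        assert fr.probs[0, :3] == pytest.approx(num_r / z, abs=1e-12)

    def test_zero_probability_observation_rejected(self):
        world = sd.ToyWorldParams(
            trans=np.eye(2),
            emit_seq=np.array([[1.0, 0.0], [0.0, 1.0]]),
            emit_struct=np.array([[1.0, 0.0], [0.0, 1.0]]),
            init=np.array([1.0, 0.0]),
        )
        jt = sd.enumerate_joint(world, 2)
        xt = ProteinTokens.from_arrays([1, 1], [2, 2])  # impossible under init
        with pytest.raises(ValueError):
            fc.exact_posterior_denoiser(jt, xt)


class TestOracleRecovery:
    @pytest.mark.parametrize("eta", [0.0, 1.0])
    def test_sampler_reproduces_enumerable_world(self, tiny_world, eta):
        # 2 positions, 2+2 symbols: 16 outcomes; TV < 0.05 at 20k samples
        jt = sd.enumerate_joint(tiny_world, 2)
        den = sd.HMMPosteriorDenoiser(tiny_world)
        sv, rv = tiny_world.seq_vocab, tiny_world.struct_vocab
        x0 = ProteinTokens.fully_masked(2, sv, rv)
        cfg = SamplerConfig(steps=200, eta=eta, seed=17)
        res, _ = fc.euler_sample_batch(
            den, x0, ConditionMask.none(2), cfg, sv, rv, n_samples=20000
        )
        emp = np.bincount(jt.encode(res.seq, res.struct), minlength=jt.n_outcomes)
        tv = 0.5 * np.abs(emp / 20000 - jt.probs).sum()
        assert tv < 0.05

    def test_table_and_forward_backward_posteriors_agree(self, small_world, rng):
        jt = sd.enumerate_joint(small_world, 3)
        sv, rv = small_world.seq_vocab, small_world.struct_vocab
        for _ in range(20):
            s = rng.integers(0, sv.size, 3)
            r = rng.integers(0, rv.size, 3)
            xt = ProteinTokens.from_arrays(s, r)
            fs, fr = fc.exact_posterior_denoiser(jt, xt)
            ps, pr = sd.posterior_fields(small_world, s[None, :], r[None, :])
            np.testing.assert_allclose(fs.probs, ps[0], atol=1e-12)
            np.testing.assert_allclose(fr.probs, pr[0], atol=1e-12)

    def test_remask_events_occur_but_output_clean(self, default_world):
        den = sd.HMMPosteriorDenoiser(default_world)
        sv, rv = default_world.seq_vocab, default_world.struct_vocab
        x0 = ProteinTokens.fully_masked(16, sv, rv)
        cfg = SamplerConfig(steps=50, eta=1.0, seed=9)
        res, _ = fc.euler_sample_batch(
            den, x0, ConditionMask.none(16), cfg, sv, rv, n_samples=100
        )
        assert res.n_remask_events > 0
        assert np.all(res.seq != sv.mask_index)
        assert np.all(res.struct != rv.mask_index)
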