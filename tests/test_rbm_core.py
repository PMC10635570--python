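from itertools import product

import numpy as np
import pytest

from genomeforge.rbm_core import (
    RBMParams,
    RdmKConfig,
    exact_log_likelihood,
    gibbs_k,
    hidden_conditional,
    rdmk_gradient,
    sample_rbm,
    train_rbm,
    visible_conditional,
    save_rbm,
    load_rbm,
)
from genomeforge.synthetic_data import PopSimConfig, simulate_structured_haplotypes


def random_machine(nv, nh, seed, scale=0.8):
    rng = np.random.default_rng(seed)
    return RBMParams(rng.normal(0, scale, (nv, nh)),
                     rng.normal(0, 0.5, nv), rng.normal(0, 0.5, nh))


def enumerate_joint(params: RBMParams):
    """Exhaustive joint distribution over all (visible, hidden) states."""
    nv, nh = params.n_visible, params.n_hidden
    vs = np.array(list(product((0.0, 1.0), repeat=nv)))
    hs = np.array(list(product((0.0, 1.0), repeat=nh)))
    energy = vs @ params.w @ hs.T + (vs @ params.theta)[:, None] + (hs @ params.eta)[None, :]
    p = np.exp(energy)
    return vs, hs, p / p.sum()


class TestConditionals:
    @pytest.mark.parametrize("nv,nh", [(3, 2), (4, 3), (2, 5), (6, 4), (5, 5)])
    def test_match_enumeration(self, nv, nh):
        params = random_machine(nv, nh, seed=nv * 10 + nh)
        vs, hs, joint = enumerate_joint(params)
        v = vs[3 % len(vs)]
        row = np.all(vs == v, axis=1)
        pv = joint[row].ravel()
        oracle_h = (hs * (pv / pv.sum())[:, None]).sum(axis=0)
        assert np.allclose(hidden_conditional(params, v), oracle_h)
        h = hs[1]
        col = np.all(hs == h, axis=1)
        ph = joint[:, col].ravel()
        oracle_v = (vs * (ph / ph.sum())[:, None]).sum(axis=0)
        assert np.allclose(visible_conditional(params, h), oracle_v)

    def test_zero_weights_give_half(self):
        params = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        assert np.allclose(hidden_conditional(params, np.ones(4)), 0.5)
        assert np.allclose(visible_conditional(params, np.zeros(3)), 0.5)

    def test_bias_saturation(self):
        params = RBMParams(np.zeros((2, 2)), np.array([-20.0, 0.0]), np.array([20.0, 0.0]))
        assert hidden_conditional(params, np.zeros(2))[0] == pytest.approx(1.0, abs=1e-8)
        assert visible_conditional(params, np.zeros(2))[0] == pytest.approx(0.0, abs=1e-8)

    def test_shape_mismatch_rejected(self):
        params = random_machine(3, 2, 0)
        with pytest.raises(ValueError):
            hidden_conditional(params, np.zeros(4))


class TestGibbs:
    def test_k_zero_rejected(self):
        params = random_machine(2, 2, 0)
        with pytest.raises(ValueError):
            gibbs_k(params, np.zeros(2), 0, np.random.default_rng(0))

    def test_uniform_model_gives_uniform_marginals(self):
        params = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        rng = np.random.default_rng(1)
        out = gibbs_k(params, np.zeros((4000, 3)), 2, rng)
        assert np.allclose(out.mean(axis=0), 0.5, atol=0.03)

    def test_long_chain_matches_exact_marginal(self):
        # k large: chain distribution approaches the model's visible marginal
        params = random_machine(3, 2, seed=7, scale=1.0)
        vs, _, joint = enumerate_joint(params)
        marginal = joint.sum(axis=1)
        rng = np.random.default_rng(2)
        v0 = (rng.random((50_000, 3)) < 0.5).astype(float)
        out = gibbs_k(params, v0, 100, rng)
        codes = out @ [4, 2, 1]
        emp = np.bincount(codes.astype(int), minlength=8) / len(codes)
        exact = np.zeros(8)
        for state, p in zip(vs, marginal):
            exact[int(state @ [4, 2, 1])] = p
        assert 0.5 * np.abs(emp - exact).sum() < 0.02  # total variation


class TestGradient:
    def test_analytic_zero_machine(self):
        # all-ones batch at zero weights: positive moment 0.5, model moment 0.25
        params = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        cfg = RdmKConfig(k_steps=5, n_hidden=2, seed=0)
        rng = np.random.default_rng(0)
        gws = [rdmk_gradient(params, np.ones((256, 3)), cfg, rng)[0] for _ in range(30)]
        assert np.allclose(np.mean(gws, axis=0), 0.25, atol=0.02)

    def test_empty_batch_rejected(self):
        params = random_machine(3, 2, 0)
        with pytest.raises(ValueError):
            rdmk_gradient(params, np.empty((0, 3)), RdmKConfig(seed=0), np.random.default_rng(0))

    def test_zero_at_self_generated_data(self):
        # batch sampled by the same Rdm-k process => expected gradient ~ 0
        params = random_machine(4, 3, seed=3, scale=0.6)
        cfg = RdmKConfig(k_steps=30, n_hidden=3, seed=0)
        rng = np.random.default_rng(5)
        grads = []
        for _ in range(40):
            batch = gibbs_k(params, (rng.random((512, 4)) < 0.5).astype(float), cfg.k_steps, rng)
            grads.append(rdmk_gradient(params, batch, cfg, rng)[0])
        mean_grad = np.mean(grads, axis=0)
        assert np.abs(mean_grad).max() < 0.01

    def test_matches_exact_likelihood_gradient(self):
        # large k: Rdm-k negative phase converges to the model expectation
        params = random_machine(3, 2, seed=11, scale=0.7)
        vs, hs, joint = enumerate_joint(params)
        # exact model moment <v h> under the joint
        moment = np.zeros((3, 2))
        for i, v in enumerate(vs):
            for j, h in enumerate(hs):
                moment += joint[i, j] * np.outer(v, h)
        rng = np.random.default_rng(8)
        data = (rng.random((2000, 3)) < 0.5).astype(float)
        ph = hidden_conditional(params, data)
        exact_grad = data.T @ ph / len(data) - moment
        cfg = RdmKConfig(k_steps=200, n_hidden=2, seed=0)
        mc = np.mean([rdmk_gradient(params, data, cfg, rng)[0] for _ in range(30)], axis=0)
        assert np.abs(mc - exact_grad).max() < 0.02


class TestExactLikelihood:
    def test_uniform_model(self):
        params = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        ll = exact_log_likelihood(params, np.array([[0, 1, 0, 1]]))
        assert ll == pytest.approx(-4 * np.log(2))

    def test_single_unit_closed_form(self):
        params = RBMParams(np.zeros((1, 1)), np.array([np.log(3.0)]), np.zeros(1))
        # P(s=1) = (3 + 3)/(1 + 1 + 3 + 3) = 0.75
        assert exact_log_likelihood(params, np.array([[1]])) == pytest.approx(np.log(0.75))

    def test_matches_double_enumeration(self):
        params = random_machine(6, 3, seed=5)
        vs, hs, joint = enumerate_joint(params)
        marg = joint.sum(axis=1)
        rng = np.random.default_rng(1)
        data = (rng.random((7, 6)) < 0.5).astype(float)
        oracle = np.mean([np.log(marg[np.all(vs == d, axis=1)][0]) for d in data])
        assert exact_log_likelihood(params, data) == pytest.approx(oracle)

    def test_large_machine_refused(self):
        params = RBMParams(np.zeros((25, 25)), np.zeros(25), np.zeros(25))
        with pytest.raises(ValueError, match="intractable"):
            exact_log_likelihood(params, np.zeros((1, 25)))


class TestTraining:
    def test_likelihood_increases_on_two_mode_data(self):
        rng = np.random.default_rng(0)
        modes = np.array([[1, 1, 1, 1, 1, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]], float)
        data = modes[rng.integers(0, 2, 500)]
        data = np.abs(data - (rng.random(data.shape) < 0.1))
        cfg = RdmKConfig(k_steps=20, learning_rate=0.05, n_hidden=4, epochs=50,
                         batch_size=128, seed=0)
        params, log = train_rbm(data, cfg, track_exact_ll=True)
        ll = np.array(log.exact_log_likelihood)
        moving = np.convolve(ll, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(moving) > -1e-3)  # monotone up to MC noise
        assert ll[-1] > ll[0] + 0.1

    def test_marginals_match_data_frequencies(self):
        data = simulate_structured_haplotypes(PopSimConfig(
            n_pops=1, n_hap_per_pop=400, n_snps=30, copy_switch_prob=0.3, seed=9))
        cfg = RdmKConfig(k_steps=20, learning_rate=0.05, n_hidden=16, epochs=120,
                         batch_size=128, seed=1)
        params, _ = train_rbm(data, cfg)
        samp = sample_rbm(params, 3000, cfg, seed=4)
        r = np.corrcoef(samp.frequencies(), data.frequencies())[0, 1]
        assert r > 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 2, (60, 8)).astype(float)
        cfg = RdmKConfig(k_steps=5, learning_rate=0.02, n_hidden=3, epochs=4,
                         batch_size=32, seed=7)
        p1, _ = train_rbm(data, cfg)
        p2, _ = train_rbm(data, cfg)
        assert np.array_equal(p1.w, p2.w)
        assert np.array_equal(p1.theta, p2.theta)

    def test_singular_values_logged(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 2, (60, 8)).astype(float)
        cfg = RdmKConfig(k_steps=3, n_hidden=3, epochs=5, batch_size=32, seed=0)
        _, log = train_rbm(data, cfg)
        assert len(log.top_singular_values) == 5


class TestSampling:
    def test_uniform_machine_frequencies(self):
        params = RBMParams(np.zeros((5, 3)), np.zeros(5), np.zeros(3))
        cfg = RdmKConfig(k_steps=3, n_hidden=3, seed=0)
        samp = sample_rbm(params, 4000, cfg, seed=1)
        assert np.allclose(samp.frequencies(), 0.5, atol=0.03)

    def test_same_seed_identical(self):
        params = random_machine(6, 3, 2)
        cfg = RdmKConfig(k_steps=10, n_hidden=3, seed=0)
        a = sample_rbm(params, 50, cfg, seed=5)
        b = sample_rbm(params, 50, cfg, seed=5)
        assert np.array_equal(a.alleles, b.alleles)

    def test_pairwise_joint_matches_enumeration(self):
        # Rdm-k sampling with large k approaches the exact 2-site joints
        params = random_machine(2, 2, seed=13, scale=1.0)
        vs, _, joint = enumerate_joint(params)
        marg = joint.sum(axis=1)
        cfg = RdmKConfig(k_steps=150, n_hidden=2, seed=0)
        samp = sample_rbm(params, 20_000, cfg, seed=3).alleles
        codes = samp @ [2, 1]
        emp = np.bincount(codes.astype(int), minlength=4) / len(codes)
        exact = np.zeros(4)
        for state, p in zip(vs, marg):
            exact[int(state @ [2, 1])] = p
        assert 0.5 * np.abs(emp - exact).sum() < 0.03


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        params = random_machine(5, 3, 1)
        cfg = RdmKConfig(k_steps=7, n_hidden=3, seed=2)
        save_rbm(tmp_path / "m.npz", params, cfg)
        p2, c2 = load_rbm(tmp_path / "m.npz")
        assert np.array_equal(params.w, p2.w)
        assert c2 == cfg
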