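from itertools import product

import numpy as np
import pytest

from genomeforge.haplotype_io import HaplotypeMatrix
from genomeforge.rbm_core import RBMParams, RdmKConfig, hidden_conditional, sample_rbm
from genomeforge.crbm_chain import (
    CRBMChain,
    CRBMParams,
    WindowPlan,
    crbm_hidden_conditional,
    crbm_rdmk_gradient,
    plan_windows,
    sample_chain,
    sample_crbm,
    train_chain,
    train_crbm,
    save_chain,
    load_chain,
)


def random_crbm(n_inf, n_pin, n_h, seed, scale=0.8):
    rng = np.random.default_rng(seed)
    base = RBMParams(rng.normal(0, scale, (n_inf, n_h)),
                     rng.normal(0, 0.5, n_inf), rng.normal(0, 0.5, n_h))
    return CRBMParams(base, rng.normal(0, scale, (n_pin, n_h)))


class TestPlanWindows:
    def test_published_worked_example(self):
        plan = plan_windows(100_000, 10_000, 10_000, 5_000)
        assert plan.first_window == (0, 10_000)
        assert plan.crbm_windows[0] == (5_000, 10_000, 10_000, 15_000)
        assert plan.crbm_windows[1] == (10_000, 15_000, 15_000, 20_000)
        assert plan.crbm_windows[-1][3] == 100_000
        plan.validate()

    def test_exact_fit_gives_zero_crbms(self):
        plan = plan_windows(50, 50, 20, 5)
        assert plan.crbm_windows == []

    def test_non_divisible_end_aligned(self):
        plan = plan_windows(23, 10, 10, 5)
        assert plan.crbm_windows == [(5, 10, 10, 15), (10, 15, 15, 20), (15, 20, 20, 23)]
        plan.validate()

    def test_inferred_ranges_tile_exactly(self):
        plan = plan_windows(97, 20, 15, 7)
        covered = list(range(*plan.first_window))
        for _, _, istart, iend in plan.crbm_windows:
            covered.extend(range(istart, iend))
        assert covered == list(range(97))

    def test_impossible_tilings_rejected(self):
        with pytest.raises(ValueError):
            plan_windows(10, 5, 20, 4)
        with pytest.raises(ValueError):
            plan_windows(10, 5, 8, 8)
        with pytest.raises(ValueError):
            plan_windows(10, 2, 8, 4)  # first_width < overlap


class TestConditional:
    def test_matches_enumeration(self):
        params = random_crbm(3, 2, 2, seed=1)
        x = np.array([1.0, 0.0])
        s = np.array([0.0, 1.0, 1.0])
        hs = [np.array(h, float) for h in product((0, 1), repeat=2)]

        def weight(h):
            b = params.base
            return np.exp(s @ b.w @ h + b.theta @ s + b.eta @ h + (x @ params.w_pin) @ h)

        z = sum(weight(h) for h in hs)
        oracle = [sum(weight(h) for h in hs if h[a] == 1) / z for a in range(2)]
        assert np.allclose(crbm_hidden_conditional(params, s, x), oracle)

    def test_zero_pin_reduces_to_unconditional(self):
        params = random_crbm(4, 3, 2, seed=2)
        params.w_pin[:] = 0.0
        s = np.array([1.0, 0.0, 1.0, 1.0])
        assert np.allclose(crbm_hidden_conditional(params, s, np.ones(3)),
                           hidden_conditional(params.base, s))

    def test_zero_pinned_values_annihilate_term(self):
        params = random_crbm(4, 3, 2, seed=3)
        s = np.array([1.0, 0.0, 1.0, 0.0])
        assert np.allclose(crbm_hidden_conditional(params, s, np.zeros(3)),
                           hidden_conditional(params.base, s))

    def test_width_mismatch_rejected(self):
        params = random_crbm(3, 2, 2, seed=4)
        with pytest.raises(ValueError):
            crbm_hidden_conditional(params, np.zeros(3), np.zeros(5))


class TestSampleCrbm:
    def test_zero_machine_gives_half_marginals(self):
        params = CRBMParams(RBMParams(np.zeros((4, 2)), np.zeros(4), np.zeros(2)),
                            np.zeros((3, 2)))
        out = sample_crbm(params, np.zeros((3000, 3)), 3, np.random.default_rng(0))
        assert np.allclose(out.mean(axis=0), 0.5, atol=0.04)

    def test_strong_pinned_coupling_copies_pattern(self):
        n = 2
        params = CRBMParams(
            RBMParams(np.eye(n) * 10, np.full(n, -5.0), np.full(n, -25.0)),
            np.eye(n) * 40)
        rng = np.random.default_rng(1)
        pin = (rng.random((500, n)) < 0.5).astype(float)
        out = sample_crbm(params, pin, 30, np.random.default_rng(2))
        assert (out == pin).mean() > 0.99


class TestTrainCrbm:
    def test_constant_zero_pinned_columns_have_zero_pin_gradient(self):
        params = random_crbm(4, 3, 2, seed=5)
        rng = np.random.default_rng(0)
        s = rng.integers(0, 2, (64, 4)).astype(float)
        x = np.zeros((64, 3))
        _, _, _, gpin = crbm_rdmk_gradient(params, s, x, RdmKConfig(k_steps=3, seed=0), rng)
        assert np.all(gpin == 0)

    def test_copy_task_recovery(self):
        # inferred block duplicates the pinned block; the trained CRBM must
        # reproduce pinned input on fresh data
        rng = np.random.default_rng(1)
        data = (rng.random((400, 10)) < np.linspace(0.2, 0.8, 10)).astype(float)
        full = np.hstack([data, data])
        cfg = RdmKConfig(k_steps=15, learning_rate=0.3, n_hidden=32, epochs=600,
                         batch_size=128, seed=0)
        params, _ = train_crbm(full, ((0, 10), (10, 20)), cfg)
        samp = sample_crbm(params, data[:200], cfg.k_steps, np.random.default_rng(5))
        assert (samp == data[:200]).mean() > 0.95

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        data = rng.integers(0, 2, (50, 8)).astype(float)
        cfg = RdmKConfig(k_steps=4, learning_rate=0.05, n_hidden=4, epochs=3,
                         batch_size=32, seed=3)
        p1, _ = train_crbm(data, ((0, 4), (4, 8)), cfg)
        p2, _ = train_crbm(data, ((0, 4), (4, 8)), cfg)
        assert np.array_equal(p1.base.w, p2.base.w)
        assert np.array_equal(p1.w_pin, p2.w_pin)


class TestChain:
    def test_zero_crbm_chain_equals_sample_rbm(self):
        rng = np.random.default_rng(0)
        params = RBMParams(rng.normal(0, 0.5, (8, 4)), np.zeros(8), np.zeros(4))
        cfg = RdmKConfig(k_steps=10, n_hidden=4, seed=0)
        chain = CRBMChain(params, [], WindowPlan((0, 8), [], 8), cfg)
        out = sample_chain(chain, 40, seed=9)
        assert out.alleles.shape == (40, 8)
        # distributional identity: same machine, same process
        big_chain = sample_chain(chain, 5000, seed=9).frequencies()
        big_rbm = sample_rbm(params, 5000, cfg, seed=10).frequencies()
        assert np.allclose(big_chain, big_rbm, atol=0.03)

    def test_cross_window_rule_propagates(self):
        # data obey site j = site j - overlap: train a 3-window toy chain and
        # check the deterministic rule survives chained sampling
        rng = np.random.default_rng(4)
        base = (rng.random((400, 10)) < np.linspace(0.2, 0.8, 10)).astype(np.int8)
        data = np.hstack([base, base, base])  # 30 SNPs, rule with period 10
        plan = plan_windows(30, 10, 20, 10)
        assert len(plan.crbm_windows) == 2
        cfg = RdmKConfig(k_steps=15, learning_rate=0.3, n_hidden=32, epochs=600,
                         batch_size=128, seed=2)
        chain = train_chain(HaplotypeMatrix(data), plan, cfg)
        out = sample_chain(chain, 300, seed=11).alleles
        agree1 = (out[:, 10:20] == out[:, 0:10]).mean()
        agree2 = (out[:, 20:30] == out[:, 10:20]).mean()
        assert agree1 > 0.9
        assert agree2 > 0.9

    def test_chain_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 2, (60, 12)).astype(np.int8)
        plan = plan_windows(12, 6, 6, 3)
        cfg = RdmKConfig(k_steps=3, learning_rate=0.05, n_hidden=4, epochs=2,
                         batch_size=32, seed=1)
        chain = train_chain(HaplotypeMatrix(data), plan, cfg)
        save_chain(tmp_path / "c.npz", chain)
        loaded = load_chain(tmp_path / "c.npz")
        assert np.array_equal(loaded.first.w, chain.first.w)
        assert len(loaded.rest) == len(chain.rest)
        assert np.array_equal(loaded.rest[0].w_pin, chain.rest[0].w_pin)
        a = sample_chain(chain, 20, seed=3)
        b = sample_chain(loaded, 20, seed=3)
        assert np.array_equal(a.alleles, b.alleles)

    def test_with_zero_pin_couplings_windows_are_independent_rbms(self):
        # reduction property: w_pin = 0 makes each window an independent RBM
        rng = np.random.default_rng(5)
        first = RBMParams(rng.normal(0, 0.5, (6, 3)), rng.normal(0, 0.3, 6), np.zeros(3))
        sub = RBMParams(rng.normal(0, 0.5, (4, 3)), rng.normal(0, 0.3, 4), np.zeros(3))
        crbm = CRBMParams(sub, np.zeros((3, 3)))
        plan = plan_windows(10, 6, 7, 3)
        cfg = RdmKConfig(k_steps=40, n_hidden=3, seed=0)
        chain = CRBMChain(first, [crbm], plan, cfg)
        chained = sample_chain(chain, 8000, seed=1).alleles[:, 6:]
        rng2 = np.random.default_rng(2)
        standalone = sample_crbm(crbm, np.zeros((8000, 3)), cfg.k_steps, rng2)
        assert np.allclose(chained.mean(axis=0), standalone.mean(axis=0), atol=0.03)
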