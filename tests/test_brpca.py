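import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import subtypeflow as sf
from subtypeflow.brpca import HIGH, LOW, markov_pi_regime, markov_scores


class TestMarkovRegime:
    def test_interior_neighbours_active_reaches_threshold(self):
        # both neighbours active, centre inactive: score 0.25+0.25 = 0.5 -> HIGH
        B = np.zeros((1, 3))
        B[0, 0] = B[0, 2] = 1
        assert markov_pi_regime(B, 0, 1) == HIGH

    def test_all_inactive_is_low(self):
        assert markov_pi_regime(np.zeros((1, 3)), 0, 1) == LOW

    def test_boundary_uses_single_neighbour_twice(self):
        # first column: 0.5*b1 + 0.5*b2 = 0.5 -> HIGH
        B = np.zeros((1, 4))
        B[0, 1] = 1
        assert markov_pi_regime(B, 0, 0) == HIGH
        # last column symmetric
        B2 = np.zeros((1, 4))
        B2[0, 2] = 1
        assert markov_pi_regime(B2, 0, 3) == HIGH

    def test_errors_on_bad_index_and_single_column(self):
        B = np.zeros((2, 3))
        with pytest.raises(IndexError):
            markov_pi_regime(B, 5, 0)
        with pytest.raises(ValueError):
            markov_scores(np.zeros((2, 1)))

    @given(st.integers(0, 2 ** 12 - 1))
    def test_scores_lie_in_unit_interval_and_match_scalar(self, bits):
        B = np.array([[(bits >> k) & 1 for k in range(4)],
                      [(bits >> (k + 4)) & 1 for k in range(4)],
                      [(bits >> (k + 8)) & 1 for k in range(4)]], dtype=float)
        s = markov_scores(B)
        assert s.min() >= 0.0 and s.max() <= 1.0
        for p in range(3):
            for i in range(4):
                assert (markov_pi_regime(B, p, i) == HIGH) == (s[p, i] >= 0.5)


class TestDecompose:
    def test_zero_matrix_yields_near_zero_components(self):
        hp = sf.BRPCAHyperparams.for_shape(50, 10, K=5, n_burn=50, n_collect=25, seed=3)
        dec = sf.decompose(np.zeros((50, 10)), hp)
        assert np.abs(dec.L_hat).max() < 1e-3
        assert np.abs(dec.S_hat).max() < 1e-3

    def test_recovers_planted_support_and_rank(self, bench):
        em, truth, hp, dec = bench
        Bh = dec.B_mean > 0.5
        tp = (Bh & truth.support).sum()
        fp = (Bh & ~truth.support).sum()
        fn = (~Bh & truth.support).sum()
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.9
        assert 1.5 <= dec.rank_estimate <= 2.5

    def test_additivity_is_exact(self, bench):
        em, truth, hp, dec = bench
        # E_hat is the residual Y - L_hat - S_hat, so this holds bitwise
        assert np.array_equal(em.values - dec.L_hat - dec.S_hat, dec.E_hat)
        assert np.abs(em.values - (dec.L_hat + dec.S_hat + dec.E_hat)).max() < 1e-12

    def test_same_seed_is_byte_identical(self):
        em, _ = sf.generate_dataset(sf.SyntheticSpec(
            n_genes=60, n_samples=20, n_subtypes=2, samples_per_subtype=6,
            n_normal=8, sparse_fraction=0.1, seed=8))
        hp = sf.BRPCAHyperparams.for_shape(60, 20, K=4, n_burn=20, n_collect=10, seed=11)
        a = sf.decompose(em.values, hp)
        b = sf.decompose(em.values, hp)
        assert a.L_hat.tobytes() == b.L_hat.tobytes()
        assert a.S_hat.tobytes() == b.S_hat.tobytes()
        assert a.rank_estimate == b.rank_estimate

    def test_hyperparameter_validation(self):
        from dataclasses import replace
        # for_shape clamps K to min(P, N); a hand-built K beyond it must fail
        hp_big = replace(sf.BRPCAHyperparams.for_shape(10, 5, K=5), K=8)
        with pytest.raises(ValueError):
            sf.decompose(np.zeros((10, 5)), hp_big)
        hp = sf.BRPCAHyperparams.for_shape(10, 5, K=3, n_collect=0)
        with pytest.raises(ValueError):
            sf.decompose(np.zeros((10, 5)), hp)


class TestGibbsStep:
    def test_precisions_stay_positive_and_state_finite(self):
        em, _ = sf.generate_dataset(sf.SyntheticSpec(
            n_genes=40, n_samples=16, n_subtypes=2, samples_per_subtype=5,
            n_normal=6, sparse_fraction=0.1, seed=4))
        hp = sf.BRPCAHyperparams.for_shape(40, 16, K=3, seed=5)
        rng = np.random.default_rng(5)
        state = sf.init_state(em.values, hp, rng)
        for _ in range(300):
            state = sf.gibbs_step(state, em.values, hp, rng)
            assert state.tau > 0 and state.nu > 0 and np.all(state.gamma > 0)
        assert np.isfinite(state.low_rank()).all()
        assert set(np.unique(state.B)) <= {0.0, 1.0}
        assert set(np.unique(state.z)) <= {0.0, 1.0}

    def test_zero_data_zero_support_keeps_sparse_part_null(self):
        Y = np.zeros((20, 8))
        hp = sf.BRPCAHyperparams.for_shape(20, 8, K=2, seed=1)
        rng = np.random.default_rng(1)
        state = sf.init_state(Y, hp, rng)
        state.pi = np.full((20, 8), 1e-12)  # support prior switched off
        new = sf.gibbs_step(state, Y, hp, rng)
        assert np.all(new.sparse() == 0.0)


def test_sparsity_grows_with_markov_prior_mean():
    """Raising the prior mean pi of the active-neighbourhood regime never
    lowers the posterior sparsity fraction (sub-threshold amplitude, where
    the prior actually governs activation), averaged over 5 seeds."""
    em, _ = sf.generate_dataset(sf.SyntheticSpec(
        n_genes=100, n_samples=30, n_subtypes=2, samples_per_subtype=10,
        n_normal=10, sparse_fraction=0.1, sparse_amplitude=0.3, seed=3))
    means = []
    for frac in (0.05, 0.5, 0.95):
        vals = []
        for s in range(5):
            hp = sf.BRPCAHyperparams.for_shape(
                100, 30, K=5, n_burn=80, n_collect=40, seed=s,
                alphaH=frac * 100, betaH=(1 - frac) * 100)
            vals.append(sf.decompose(em.values, hp).sparsity_fraction)
        means.append(np.mean(vals))
    assert means[1] >= means[0] - 0.02
    assert means[2] >= means[1] - 0.02
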