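"""Tests of marker selection, chain mechanics and full deconvolution."""

import math

import numpy as np
import pytest

from bedwars import (
    ChainState,
    Hyperparameters,
    SamplerConfig,
    deconvolve,
    evaluate_proportions,
    init_chain,
    log_posterior,
    mh_step,
    run_chain,
    score_chain,
    select_markers,
    simulate_truth,
    SyntheticSpec,
)
from bedwars.sampler import chain_rng

from conftest import make_bulk, make_proportions, make_signature, random_instance


def tiny_config(**kw):
    base = dict(n_chains=4, n_iterations=50, burn_in_fraction=0.5, seed=7)
    base.update(kw)
    return SamplerConfig(**base)


class TestSelectMarkers:
    @pytest.mark.parametrize(
        "row,fold,is_marker",
        [
            ((8.0, 1.0), 4.0, True),
            ((4.0, 1.0), 4.0, True),  # boundary inclusive
            ((3.9, 1.0), 4.0, False),
            ((8.0, 1.0, 3.0), 4.0, False),  # 8 < 4*3
            ((12.0, 1.0, 3.0), 4.0, True),
        ],
    )
    def test_fold_rule(self, row, fold, is_marker):
        S = make_signature(np.array([row]))
        assert (select_markers(S, fold) == ["g0"]) == is_marker

    def test_brute_force_agreement(self, rng):
        _, _, S_ref, _, _, _, _ = random_instance(rng, G=50, C=4)
        got = set(select_markers(S_ref, 4.0))
        expected = set()
        for g in range(S_ref.n_genes):
            row = S_ref.values[g]
            for c in range(len(row)):
                if all(row[c] >= 4.0 * row[o] for o in range(len(row)) if o != c):
                    expected.add(S_ref.gene_ids[g])
        assert got == expected

    def test_single_cell_type_error(self):
        with pytest.raises(ValueError):
            select_markers(make_signature([[1.0], [2.0]]), 4.0)


class TestInitChain:
    def test_sigma_c_groups(self, rng, hp):
        S_ref = make_signature(np.exp(rng.normal(1.5, 1, (10, 3))))
        expected = {0: 0.01, 1: 0.1, 2: 1.0}
        for idx, value in expected.items():
            st = init_chain(S_ref, hp, idx, 8, np.random.default_rng(0))
            np.testing.assert_allclose(st.sigma_c, value)
        st3 = init_chain(S_ref, hp, 3, 8, np.random.default_rng(0))
        assert len(set(np.round(st3.sigma_c, 12))) > 1  # prior draws vary

    def test_remainder_chains_draw_from_prior(self, rng, hp):
        S_ref = make_signature(np.exp(rng.normal(1.5, 1, (10, 3))))
        # chains 4..5 of 6 are the remainder: prior draws, not 0.01/0.1
        st = init_chain(S_ref, hp, 4, 6, np.random.default_rng(1))
        assert not np.allclose(st.sigma_c, 0.01)

    def test_state_matches_reference_and_w0(self, rng, hp):
        S_ref = make_signature(np.exp(rng.normal(1.5, 1, (10, 3))))
        st = init_chain(S_ref, hp, 0, 4, np.random.default_rng(0),
                        sample_ids=["a", "b"])
        np.testing.assert_array_equal(st.S.values, S_ref.values)
        np.testing.assert_allclose(st.W.values, 1 / 3)
        assert 0 <= st.alpha <= 30 and st.sigma > 0

    def test_deterministic_given_seed(self, rng, hp):
        S_ref = make_signature(np.exp(rng.normal(1.5, 1, (10, 3))))
        a = init_chain(S_ref, hp, 3, 8, np.random.default_rng(5))
        b = init_chain(S_ref, hp, 3, 8, np.random.default_rng(5))
        np.testing.assert_array_equal(a.sigma_c, b.sigma_c)
        assert a.alpha == b.alpha and a.sigma == b.sigma


class TestMHStep:
    def _instance(self, rng):
        X, S, S_ref, W, sigma_c, sigma, alpha = random_instance(rng, G=8, C=3, N=4)
        state = ChainState(S=S, W=W, sigma_c=sigma_c, sigma=sigma, alpha=alpha)
        return X, S_ref, state

    def test_zero_step_scales_leave_state_unchanged(self, rng, hp):
        X, S_ref, state = self._instance(rng)
        cfg = tiny_config(
            proposal_scales={k: 0.0 for k in ("S", "W", "sigma_c", "sigma", "alpha")}
        )
        new, rates = mh_step(state, X, S_ref, hp, cfg, np.random.default_rng(0))
        assert all(r == 1.0 for r in rates.values())
        np.testing.assert_array_equal(new.S.values, state.S.values)
        np.testing.assert_array_equal(new.W.values, state.W.values)
        assert new.sigma == state.sigma and new.alpha == state.alpha

    def test_posterior_stays_finite_and_in_domain(self, rng, hp):
        X, S_ref, state = self._instance(rng)
        cfg = tiny_config()
        gen = np.random.default_rng(3)
        for _ in range(200):
            state, _ = mh_step(state, X, S_ref, hp, cfg, gen)
            assert math.isfinite(log_posterior(X, state, S_ref, hp))
            np.testing.assert_allclose(state.W.values.sum(axis=0), 1.0, atol=1e-9)
            assert np.all(state.W.values > 0)
            assert np.all(state.sigma_c > 0) and state.sigma > 0
            assert hp.alpha_min <= state.alpha <= hp.alpha_max

    def test_invalid_start_state_rejected(self, rng, hp):
        X, S_ref, state = self._instance(rng)
        state.alpha = 31.0  # outside uniform support
        with pytest.raises(ValueError):
            mh_step(state, X, S_ref, hp, tiny_config(), np.random.default_rng(0))

    def test_sigma_update_acceptance_matches_hand_ratio(self, hp):
        """Monte-Carlo acceptance of the 1-D sigma block equals the expected
        min(1, posterior ratio x log-walk Jacobian) averaged over proposals,
        with the ratio computed independently from log_posterior."""
        X = make_bulk([[3.0]])
        S = make_signature([[2.0]])
        W = make_proportions([[1.0]])
        state = ChainState(S=S, W=W, sigma_c=np.array([0.5]), sigma=1.2, alpha=5.0)
        S_ref = S
        step = 0.4
        scales = {"S": 0.0, "W": 0.0, "sigma_c": 0.0, "sigma": step, "alpha": 0.0}
        cfg = tiny_config(proposal_scales=scales)

        def log_target(sigma):
            st = ChainState(S=S, W=W, sigma_c=np.array([0.5]), sigma=sigma, alpha=5.0)
            return log_posterior(X, st, S_ref, hp) + math.log(sigma)

        # expected acceptance: integrate min(1, ratio) over eps ~ N(0, step)
        eps = np.linspace(-5 * step, 5 * step, 4001)
        dens = np.exp(-0.5 * (eps / step) ** 2) / (step * math.sqrt(2 * math.pi))
        ratios = np.array(
            [min(1.0, math.exp(log_target(1.2 * math.exp(e)) - log_target(1.2)))
             for e in eps]
        )
        expected_p = float(np.trapezoid(ratios * dens, eps))

        gen = np.random.default_rng(99)
        n_trials = 10_000
        accepted = 0
        for _ in range(n_trials):
            _, rates = mh_step(state, X, S_ref, hp, cfg, gen)
            accepted += rates["sigma"]
        phat = accepted / n_trials
        se = math.sqrt(expected_p * (1 - expected_p) / n_trials)
        assert abs(phat - expected_p) <= 3 * se


class TestScoreChain:
    def test_exact_reconstruction_scores_zero(self, rng):
        X, S, _, W, _, _, _ = random_instance(rng)
        X_exact = make_bulk(S.values @ W.values)
        assert score_chain(X_exact, S, W, [X.gene_ids[0]]) == 0.0

    def test_single_marker_definition(self):
        S = make_signature([[1.0], [1.0]])
        W = make_proportions([[1.0]])
        X = make_bulk([[3.0], [1.0]])  # residual 2 on g0
        assert score_chain(X, S, W, ["g0"]) == pytest.approx(4.0)

    def test_matches_brute_force(self, rng):
        X, S, _, W, _, _, _ = random_instance(rng, G=12, C=3, N=4)
        markers = [X.gene_ids[i] for i in (1, 4, 7)]
        recon = S.values @ W.values
        total = 0.0
        for g in (1, 4, 7):
            for n in range(4):
                total += (X.values[g, n] - recon[g, n]) ** 2
        assert score_chain(X, S, W, markers) == pytest.approx(total / 12)

    def test_empty_marker_set_guidance(self, rng):
        X, S, _, W, _, _, _ = random_instance(rng)
        with pytest.raises(ValueError, match="marker_fold"):
            score_chain(X, S, W, [])


class TestRunChain:
    def test_running_mean_matches_stored_trace(self, rng, hp):
        X, _, S_ref, _, _, _, _ = random_instance(rng, G=10, C=3, N=5)
        cfg = tiny_config(n_iterations=40, adapt=False)
        trace = run_chain(X, S_ref, hp, cfg, 1, chain_rng(cfg.seed, 1))
        # replay with mh_step on an identical rng stream and average manually
        gen = chain_rng(cfg.seed, 1)
        state = init_chain(S_ref, hp, 1, cfg.n_chains, gen, sample_ids=X.sample_ids)
        kept = []
        for t in range(cfg.n_iterations):
            state, _ = mh_step(state, X, S_ref, hp, cfg, gen)
            if t >= cfg.burn_in:
                kept.append(
                    (state.S.values.copy(), state.W.values.copy(),
                     state.sigma_c.copy(), state.sigma, state.alpha)
                )
        assert trace.n_kept == len(kept)
        np.testing.assert_allclose(
            trace.S_mean, np.mean([k[0] for k in kept], axis=0), rtol=1e-12
        )
        np.testing.assert_allclose(
            trace.W_mean, np.mean([k[1] for k in kept], axis=0), rtol=1e-12
        )
        assert trace.sigma_mean == pytest.approx(np.mean([k[3] for k in kept]))
        assert trace.alpha_mean == pytest.approx(np.mean([k[4] for k in kept]))

    def test_fixed_seed_bit_identical(self, rng, hp):
        X, _, S_ref, _, _, _, _ = random_instance(rng, G=10, C=3, N=5)
        cfg = tiny_config(n_iterations=60)
        a = run_chain(X, S_ref, hp, cfg, 2, chain_rng(cfg.seed, 2))
        b = run_chain(X, S_ref, hp, cfg, 2, chain_rng(cfg.seed, 2))
        np.testing.assert_array_equal(a.S_mean, b.S_mean)
        np.testing.assert_array_equal(a.W_mean, b.W_mean)
        assert a.marker_mse == b.marker_mse

    def test_recovers_proportions_with_true_signature(self, hp):
        spec = SyntheticSpec(G=120, C=3, N=16, bulk_noise_sd=0.05, seed=42)
        S, W, X = simulate_truth(spec)
        cfg = SamplerConfig(n_chains=4, n_iterations=3000, seed=5)
        res = deconvolve(X, S, hp, cfg)
        err = np.abs(res.W_hat.values - W.values).max(axis=0)
        assert err.max() < 0.05


class TestDeconvolve:
    def test_best_chain_attains_minimum(self, hp):
        spec = SyntheticSpec(G=60, C=3, N=12, seed=2)
        S, W, X = simulate_truth(spec)
        res = deconvolve(X, S, hp, tiny_config(n_iterations=100))
        assert res.chain_scores[res.best_chain_index] == res.chain_scores.min()
        assert len(res.chain_scores) == 4

    def test_chain_execution_order_invariance(self, hp):
        """Chains use index-keyed RNG streams, so per-chain traces are
        identical whether computed in order or reversed."""
        spec = SyntheticSpec(G=40, C=3, N=8, seed=3)
        S, _, X = simulate_truth(spec)
        cfg = tiny_config(n_iterations=80)
        from bedwars import harmonize
        from bedwars.sampler import select_markers

        Xh, Sh = harmonize(X, S)
        markers = select_markers(Sh, cfg.marker_fold)
        forward = [
            run_chain(Xh, Sh, hp, cfg, i, chain_rng(cfg.seed, i), markers)
            for i in range(4)
        ]
        backward = [
            run_chain(Xh, Sh, hp, cfg, i, chain_rng(cfg.seed, i), markers)
            for i in reversed(range(4))
        ][::-1]
        for a, b in zip(forward, backward):
            np.testing.assert_array_equal(a.W_mean, b.W_mean)
            assert a.marker_mse == b.marker_mse

    def test_single_cell_type_returns_unit_proportions(self, hp):
        spec = SyntheticSpec(G=40, C=1, N=6, seed=4)
        S, _, X = simulate_truth(spec)
        res = deconvolve(X, S, hp, tiny_config(n_iterations=100))
        np.testing.assert_allclose(res.W_hat.values, 1.0, atol=1e-12)

    def test_warns_on_few_samples(self, hp):
        spec = SyntheticSpec(G=40, C=3, N=4, seed=5)
        S, _, X = simulate_truth(spec)
        with pytest.warns(UserWarning, match="4x"):
            deconvolve(X, S, hp, tiny_config(n_iterations=20))

    def test_no_overlapping_genes_error(self, hp, rng):
        spec = SyntheticSpec(G=20, C=3, N=4, seed=6)
        S, _, X = simulate_truth(spec)
        S.gene_ids = [f"other{i}" for i in range(20)]
        with pytest.raises(ValueError, match="share no genes"):
            deconvolve(X, S, hp, tiny_config(n_iterations=20))

    def test_monotone_degradation_with_bulk_noise(self, hp):
        """More injected bulk noise gives worse average proportion recovery."""
        mean_pcc = []
        for noise in (0.1, 2.0, 8.0):
            pccs = []
            for seed in range(5):
                spec = SyntheticSpec(
                    G=80, C=3, N=16, bulk_noise_sd=noise, seed=100 + seed
                )
                S, W, X = simulate_truth(spec)
                res = deconvolve(
                    X, S, hp, tiny_config(n_iterations=800, seed=seed)
                )
                pccs.append(evaluate_proportions(res.W_hat, W).mean_pcc)
            mean_pcc.append(np.mean(pccs))
        assert mean_pcc[0] > mean_pcc[1] > mean_pcc[2]


class TestSamplerConfig:
    def test_rejects_fewer_than_four_chains(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_chains=3)

    def test_rejects_bad_burn_in(self):
        with pytest.raises(ValueError):
            SamplerConfig(burn_in_fraction=1.0)
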