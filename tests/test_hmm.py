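"""Two-chromosome HMM: transition structure, filters, smoother.

The filter/smoother recursions are certified against two independent
references (tests/oracles.py): exact hidden-path enumeration at tiny n,
and a non-incremental unpruned NumPy implementation at moderate n.
"""

import numpy as np
import pytest
from oracles import UnprunedReference, enumerate_posterior

from conftest import emit, make_track
from pscn.hmm import (ASSIGNMENT, HmmHyperParams, backward_filter,
                      emission_mean, forward_filter, smooth,
                      stationary_distribution, transition_matrix)
from pscn.io import AA, AB, BA, BB, NP


class TestTransitionMatrix:
    def test_rows_sum_to_one(self):
        P = transition_matrix(0.001, 0.005, 0.0001)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_stationary_and_detailed_balance(self):
        p, r, s = 0.01, 0.03, 0.004
        P = transition_matrix(p, r, s)
        pi = stationary_distribution(p, r, s)
        assert np.allclose(pi @ P, pi, atol=1e-14)
        # reversibility: pi_i P_ij = pi_j P_ji elementwise
        F = pi[:, None] * P
        assert np.allclose(F, F.T, atol=1e-15)

    def test_equal_rates_give_half_quarter_quarter(self):
        pi = stationary_distribution(0.02, 0.02, 0.001)
        assert np.allclose(pi, [0.5, 0.25, 0.25])

    def test_absorbing_normal_state_at_p_zero(self):
        P = transition_matrix(0.0, 0.005, 0.0001)
        assert np.allclose(P[0], [1.0, 0.0, 0.0])

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(0.1, 0.7, 0.4)   # 1 - r - s <= 0
        with pytest.raises(ValueError):
            transition_matrix(1.2, 0.1, 0.0)


class TestEmission:
    @pytest.mark.parametrize("g,theta,expected", [
        (AA, (1.0, 1.0), (2.0, 0.0)),
        (AB, (1.5, 0.5), (1.5, 0.5)),
        (BA, (1.5, 0.5), (0.5, 1.5)),
        (BB, (1.0, 1.0), (0.0, 2.0)),
        (NP, (1.5, 0.5), (1.0, 1.0)),
    ])
    def test_assignment_means(self, g, theta, expected):
        assert emission_mean(g, theta) == pytest.approx(expected)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            emission_mean(7, (1.0, 1.0))

    def test_assignment_total_mass(self):
        # every matrix routes the full two-chromosome signal somewhere
        for A in ASSIGNMENT:
            assert A.sum() == pytest.approx(2.0)


class TestFilters:
    def test_baseline_dominates_at_baseline_data(self):
        hp = HmmHyperParams(p=0.01, r=0.02, s=0.001,
                            sigma={c: np.diag([1e-4, 1e-4])
                                   for c in ("AA", "AB", "BA", "BB")})
        u = emit([AB, AB], hp.mu0)
        fs = forward_filter(make_track(u), [AB, AB], hp, M=5, K=2)
        st = fs[0]
        assert st.baseline_weight > st.weights.max()

    def test_weights_normalized_everywhere(self, rng, hp_loose):
        g = rng.integers(0, 4, size=40)
        u = emit(g, (1.0, 1.0), rng)
        track = make_track(u)
        for fs in (forward_filter(track, g, hp_loose, M=10, K=4),
                   backward_filter(track, g, hp_loose, M=10, K=4)):
            for t in range(len(track)):
                assert fs[t].total_weight == pytest.approx(1.0, abs=1e-9)

    def test_backward_is_reversed_forward(self, rng, hp_loose):
        g = rng.integers(0, 4, size=30)
        u = emit(g, (1.3, 0.7), rng)
        track = make_track(u)
        bwd = backward_filter(track, g, hp_loose, M=8, K=3)
        fwd_rev = forward_filter(make_track(u[::-1]), g[::-1], hp_loose,
                                 M=8, K=3)
        n = len(track)
        for t in range(n):
            a, b = bwd[t], fwd_rev[n - 1 - t]
            assert a.baseline_weight == pytest.approx(b.baseline_weight)
            assert a.weights == pytest.approx(b.weights)

    def test_constant_track_filters_mirror(self, hp_loose):
        u = emit([AB] * 20, (1.0, 1.0))
        track = make_track(u)
        g = [AB] * 20
        fwd = forward_filter(track, g, hp_loose, M=25, K=5)
        bwd = backward_filter(track, g, hp_loose, M=25, K=5)
        for t in range(20):
            assert fwd[t].baseline_weight == pytest.approx(
                bwd[19 - t].baseline_weight, abs=1e-12)


class TestOracleEquivalence:
    def test_exact_path_enumeration_tiny_n(self, rng):
        hp = HmmHyperParams(p=0.05, r=0.08, s=0.02)
        g = rng.integers(0, 4, size=8)
        theta = np.where(np.arange(8)[:, None] < 4, (1.0, 1.0), (2.0, 0.5))
        u = emit(g, theta, rng)
        th_ref, base_ref = enumerate_posterior(u, g, hp)
        post = smooth(make_track(u), g, hp, M=9, K=3)
        assert np.abs(post.theta_hat - th_ref).max() < 1e-8
        assert np.abs(post.baseline_mass - base_ref).max() < 1e-8

    def test_unpruned_reference_n50(self, rng):
        hp = HmmHyperParams(p=0.02, r=0.05, s=0.005)
        n = 50
        g = rng.integers(0, 4, size=n)
        theta = np.where((np.arange(n) >= 20)[:, None]
                         & (np.arange(n) < 35)[:, None],
                         (1.8, 0.4), (1.0, 1.0))
        u = emit(g, theta, rng)
        ref = UnprunedReference(u, g, hp)
        # forward filter weights
        fs = forward_filter(make_track(u), g, hp, M=n + 1, K=5)
        rstates = ref.forward()
        for t in range(n):
            st = fs[t]
            assert abs(st.baseline_weight - rstates[t]["base"]) < 1e-8
            for i, j in enumerate(st.origin_index):
                assert abs(st.weights[i] - rstates[t].get(int(j), 0.0)) \
                    < 1e-8
        # smoother
        th_ref, base_ref = ref.smooth()
        post = smooth(make_track(u), g, hp, M=n + 1, K=5)
        assert np.abs(post.theta_hat - th_ref).max() < 1e-8
        assert np.abs(post.baseline_mass - base_ref).max() < 1e-8

    def test_bcmix_matches_unpruned_n500(self, rng):
        hp = HmmHyperParams(p=5e-3, r=1e-2, s=1e-3)
        n = 500
        g = rng.integers(0, 4, size=n)
        theta = np.where((np.arange(n) >= 200)[:, None]
                         & (np.arange(n) < 320)[:, None],
                         (1.7, 0.3), (1.0, 1.0))
        u = emit(g, theta, rng)
        track = make_track(u)
        full = smooth(track, g, hp, M=n + 1, K=10)
        pruned = smooth(track, g, hp, M=20, K=10)
        assert np.abs(full.theta_hat - pruned.theta_hat).max() < 0.01


class TestSmootherProperties:
    def test_baseline_limit_small_p(self, rng):
        hp = HmmHyperParams(p=1e-6, r=5e-3, s=1e-4)
        g = rng.integers(0, 4, size=200)
        u = emit(g, (1.0, 1.0), rng)
        post = smooth(make_track(u), g, hp, M=20, K=10)
        assert np.linalg.norm(post.theta_hat - hp.mu0, axis=1).max() < 0.05

    def test_noiseless_variant_recovered(self, rng):
        theta_star = (1.9, 0.6)
        n = 60
        g = rng.integers(0, 4, size=n)
        sig = {c: np.diag([1e-6, 1e-6]) for c in ("AA", "AB", "BA", "BB")}
        hp = HmmHyperParams(p=0.01, r=0.02, s=0.001, sigma=sig)
        u = emit(g, theta_star)
        post = smooth(make_track(u), g, hp, M=20, K=10)
        inner = slice(5, n - 5)
        # hets pin both coordinates; homs only the total
        het = (g[inner] == AB) | (g[inner] == BA)
        assert np.abs(post.theta_hat[inner][het]
                      - theta_star).max() < 1e-3

    def test_reversal_invariance(self, rng, hp_loose):
        n = 80
        g = rng.integers(0, 4, size=n)
        theta = np.where((np.arange(n) >= 30)[:, None]
                         & (np.arange(n) < 60)[:, None],
                         (1.6, 0.5), (1.0, 1.0))
        u = emit(g, theta, rng)
        post = smooth(make_track(u), g, hp_loose, M=90, K=10)
        post_rev = smooth(make_track(u[::-1]), g[::-1], hp_loose,
                          M=90, K=10)
        assert np.abs(post.theta_hat
                      - post_rev.theta_hat[::-1]).max() < 1e-6

    def test_ab_swap_invariance(self, rng, hp_loose):
        """Relabeling the arrayed A/B alleles does not touch the parents.

        Swapping x with y while mapping AA<->BB and AB<->BA rewrites the
        same parental configuration in the other allele labeling
        (J A(AB) = A(BA) at identical theta), so the parent-specific
        posterior means are unchanged.
        """
        n = 60
        g = rng.integers(0, 4, size=n)
        theta = np.where((np.arange(n) >= 20)[:, None],
                         (1.5, 0.8), (1.0, 1.0))
        u = emit(g, theta, rng)
        swap_g = np.array([BB, BA, AB, AA, NP])[g]
        post = smooth(make_track(u), g, hp_loose, M=70, K=10)
        post_sw = smooth(make_track(u[:, ::-1]), swap_g,
                         hp_loose.swapped_alleles(), M=70, K=10)
        assert np.abs(post.theta_hat - post_sw.theta_hat).max() < 1e-8
        assert np.abs(post.baseline_mass
                      - post_sw.baseline_mass).max() < 1e-8

    def test_parent_relabel_exchangeability(self, rng, hp_loose):
        n = 50
        g = rng.integers(0, 4, size=n)
        u = emit(g, (1.4, 0.7), rng)
        relab = np.array([AA, BA, AB, BB, NP])[g]
        post = smooth(make_track(u), g, hp_loose, M=60, K=10)
        post_rl = smooth(make_track(u), relab,
                         hp_loose.swapped_parents(), M=60, K=10)
        assert np.abs(post.theta_hat
                      - post_rl.theta_hat[:, ::-1]).max() < 1e-8
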