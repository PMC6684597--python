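"""Core semi-Markov quantities and the KLD entropy-production decomposition."""

import numpy as np
import pytest
import scipy.linalg

import epwtd
from epwtd.semimarkov import ReducibleChainError, _affinity_from_arrays

from conftest import random_jump_chain


class TestVisitDistribution:
    def test_two_state_symmetry(self):
        R = epwtd.visit_distribution(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(R, [0.5, 0.5], atol=1e-12)

    def test_deterministic_three_cycle(self):
        p = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=float)
        np.testing.assert_allclose(epwtd.visit_distribution(p),
                                   np.full(3, 1 / 3), atol=1e-12)

    def test_four_state_jump_chain_vs_null_space(self, four_state):
        """R of the embedded chain equals an independent dense null-space solve."""
        p = four_state.jump_matrix()
        R = epwtd.visit_distribution(p)
        ns = scipy.linalg.null_space(p - np.eye(4))
        assert ns.shape[1] == 1
        expected = ns[:, 0] / ns[:, 0].sum()
        np.testing.assert_allclose(R, expected, atol=1e-10)

    def test_fixed_point_residual(self, four_state):
        p = four_state.jump_matrix()
        R = epwtd.visit_distribution(p)
        assert np.max(np.abs(p @ R - R)) < 1e-10
        assert abs(R.sum() - 1.0) < 1e-12

    def test_reducible_chain_names_blocks(self):
        p = np.zeros((4, 4))
        p[1, 0] = p[0, 1] = 1.0   # block {0,1}
        p[3, 2] = p[2, 3] = 1.0   # block {2,3}
        with pytest.raises(ReducibleChainError, match=r"\[0, 1\].*\[2, 3\]"):
            epwtd.visit_distribution(p)


class TestStepTimeAndOccupancy:
    def test_uniform_waits(self):
        assert epwtd.mean_step_time(np.array([0.3, 0.7]), np.ones(2)) == 1.0

    def test_weighted_arithmetic(self):
        assert epwtd.mean_step_time(np.array([0.5, 0.5]),
                                    np.array([1.0, 3.0])) == 2.0
        np.testing.assert_allclose(
            epwtd.stationary_distribution(np.array([0.5, 0.5]),
                                          np.array([1.0, 3.0])),
            [0.25, 0.75])

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            epwtd.mean_step_time(np.array([1.0]), np.array([0.0]))

    def test_uniform_tau_gives_pi_equal_R(self):
        R = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(
            epwtd.stationary_distribution(R, np.full(3, 2.0)), R)

    def test_markov_occupancy_matches_generator_null_vector(self, four_state):
        """tau R / T of the embedded chain is the master-equation steady state."""
        p = four_state.jump_matrix()
        tau = four_state.tau()
        R = epwtd.visit_distribution(p)
        pi = epwtd.stationary_distribution(R, tau)
        ns = scipy.linalg.null_space(four_state.generator())
        expected = ns[:, 0] / ns[:, 0].sum()
        np.testing.assert_allclose(pi, expected, atol=1e-10)


class TestSteadyCurrent:
    def test_detailed_balance_is_currentless(self):
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        J = epwtd.steady_current(p, epwtd.visit_distribution(p))
        np.testing.assert_allclose(J, 0.0, atol=1e-14)

    def test_three_cycle_carries_third_per_step(self):
        p = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=float)
        J = epwtd.steady_current(p, np.full(3, 1 / 3))
        assert J[1, 0] == pytest.approx(1 / 3)
        assert J[2, 1] == pytest.approx(1 / 3)
        assert J[0, 2] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_antisymmetry_and_kirchhoff(self, seed):
        p = random_jump_chain(seed)
        R = epwtd.visit_distribution(p)
        J = epwtd.steady_current(p, R)
        np.testing.assert_allclose(J, -J.T, atol=1e-14)
        np.testing.assert_allclose(J.sum(axis=0), 0.0, atol=1e-10)


class TestModelValidation:
    def test_column_sum_violation_rejected(self):
        dens = epwtd.exponential_density(1.0)
        with pytest.raises(ValueError, match="sum to 1"):
            epwtd.SemiMarkovModel(states=["a", "b"],
                                  p=np.array([[0.0, 0.9], [1.0, 0.0]]),
                                  wtd={("a", "b"): dens, ("b", "a"): dens})

    def test_missing_density_rejected(self):
        dens = epwtd.exponential_density(1.0)
        with pytest.raises(ValueError, match="missing waiting-time density"):
            epwtd.SemiMarkovModel(states=["a", "b"],
                                  p=np.array([[0.0, 1.0], [1.0, 0.0]]),
                                  wtd={("a", "b"): dens})

    def test_pair_chaining_enforced_for_tuple_states(self):
        dens = epwtd.exponential_density(1.0)
        states = [("1", "2"), ("2", "1"), ("1", "3")]
        p = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        p[0, 2] = 1.0   # ("1","3") -> ("1","2") breaks the middle label
        wtd = {(a, b): dens for a in states for b in states}
        with pytest.raises(ValueError, match="chaining"):
            epwtd.SemiMarkovModel(states=states, p=p, wtd=wtd, order=2)

    def test_tau_computed_from_densities(self):
        wtd = {("a", "b"): epwtd.exponential_density(2.0),
               ("b", "a"): epwtd.exponential_density(4.0)}
        m = epwtd.SemiMarkovModel(states=["a", "b"],
                                  p=np.array([[0.0, 1.0], [1.0, 0.0]]),
                                  wtd=wtd)
        np.testing.assert_allclose(m.tau, [0.5, 0.25], rtol=1e-5)


class TestAffinityRate:
    def test_symmetric_chain_vanishes(self):
        p = random_jump_chain(3)
        p = (p + p.T) / 2
        p = p / p.sum(axis=0, keepdims=True)  # symmetric => detailed balanced
        dens = epwtd.exponential_density(1.0)
        grid = dens.t
        wtd = {(str(a), str(b)): dens for a in range(4) for b in range(4) if a != b}
        m = epwtd.SemiMarkovModel(states=[str(i) for i in range(4)], p=p, wtd=wtd)
        assert epwtd.affinity_entropy_rate(m) == pytest.approx(0.0, abs=1e-12)

    def test_zero_reverse_probability_is_inf_with_warning(self):
        p = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=float)
        R = np.full(3, 1 / 3)
        with pytest.warns(RuntimeWarning, match="zero reverse"):
            total, _ = _affinity_from_arrays(p, R, 1.0, np.arange(3),
                                             ["1", "2", "3"])
        assert np.isinf(total)

    @pytest.mark.parametrize("seed", range(20))
    def test_nonnegative_for_identity_reversal(self, seed):
        """sum x ln(x/y) over matched forward/reverse pairs is a KLD, >= 0."""
        p = random_jump_chain(seed + 100)
        R = epwtd.visit_distribution(p)
        total, _ = _affinity_from_arrays(p, R, 1.0, np.arange(4),
                                         list("abcd"))
        assert total >= -1e-13


class TestWtdRate:
    def test_markov_exits_contribute_nothing(self):
        """Exponential waits independent of the destination give S_wtd = 0."""
        m = epwtd.markov_semimarkov_model(epwtd.random_network(5))
        assert epwtd.wtd_entropy_rate(m) == 0.0

    def test_exponential_closed_form_by_quadrature(self):
        """D[Exp(1)||Exp(2)] = ln(1/2) + 2 - 1, reproduced to 1e-6."""
        f = epwtd.exponential_density(1.0)
        g = epwtd.DensityOnGrid(f.t, 2.0 * np.exp(-2.0 * f.t))
        expected = np.log(0.5) + 2.0 - 1.0
        assert epwtd.kld_between_densities(f, g) == pytest.approx(expected,
                                                                  abs=1e-6)

    def test_second_order_rate_from_closed_form_divergences(self):
        """A two-direction step model with exponential dwell laws reproduces
        the hand-computed weighted divergence sum (D of exponentials in
        closed form)."""
        grid = epwtd.log_time_grid(1.0)
        e = {r: epwtd.exponential_density(r, grid).normalized()
             for r in (1.0, 1.5, 2.0)}
        states = ["up", "down"]
        p = np.array([[0.6, 0.4], [0.4, 0.6]])
        wtd = {("up", "up"): e[1.0], ("down", "down"): e[2.0],
               ("up", "down"): e[1.5], ("down", "up"): e[1.5]}
        m = epwtd.SemiMarkovModel(states=states, p=p, wtd=wtd, order=2,
                                  reversal={"up": "down", "down": "up"})
        R = np.array([0.5, 0.5])  # symmetric jump chain
        tau = np.array([0.6 * 1.0 + 0.4 / 1.5, 0.6 * 0.5 + 0.4 / 1.5])
        T = float(R @ tau)
        d_uu = np.log(1.0 / 2.0) + 2.0 / 1.0 - 1.0   # D[Exp(1)||Exp(2)]
        d_dd = np.log(2.0 / 1.0) + 1.0 / 2.0 - 1.0   # D[Exp(2)||Exp(1)]
        expected = (0.5 * 0.6 * d_uu + 0.5 * 0.6 * d_dd) / T
        assert epwtd.wtd_entropy_rate(m) == pytest.approx(expected, rel=1e-5)

    def test_missing_reverse_density_raises(self):
        grid = epwtd.log_time_grid(1.0)
        e1 = epwtd.exponential_density(1.0, grid).normalized()
        states = [("a", "b"), ("b", "a")]
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = epwtd.SemiMarkovModel(states=states, p=p, order=2,
                                  wtd={(states[0], states[1]): e1,
                                       (states[1], states[0]): e1})
        del m.wtd[(states[1], states[0])]
        with pytest.raises(ValueError, match="missing reverse-path"):
            epwtd.wtd_entropy_rate(m)


class TestKldDecomposition:
    def test_equilibrium_network_produces_nothing(self):
        """A detailed-balanced Poissonian network has S_kld = 0."""
        omega = np.array([[0.0, 2.0, 1.0],
                          [2.0, 0.0, 3.0],
                          [1.0, 3.0, 0.0]])
        net = epwtd.RateNetwork(states=("a", "b", "c"), omega=omega)
        rep = epwtd.kld_entropy_rate(epwtd.markov_semimarkov_model(net))
        assert rep.S_kld == pytest.approx(0.0, abs=1e-12)
        assert rep.S_wtd == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_fully_observed_matches_schnakenberg(self, seed):
        """With every state visible, the trajectory KLD rate is the exact
        Schnakenberg entropy production rate."""
        net = epwtd.random_network(seed)
        rep = epwtd.kld_entropy_rate(epwtd.markov_semimarkov_model(net))
        S = epwtd.schnakenberg_entropy_rate(net)
        assert rep.S_kld == pytest.approx(S, rel=1e-4)

    def test_report_sum_identity(self, decimated_f0):
        rep = epwtd.kld_entropy_rate(decimated_f0)
        assert rep.S_kld == rep.S_aff + rep.S_wtd
        assert rep.S_wtd >= 0.0
        assert abs(sum(rep.R.values()) - 1.0) < 1e-10

    def test_stall_has_positive_rate_without_current(self, decimated_stall):
        rep = epwtd.kld_entropy_rate(decimated_stall)
        assert abs(rep.S_aff) < 1e-8
        assert rep.S_kld > 0.05

    def test_observed_exit_divergences_vanish_identically(self, decimated_f0):
        """Sojourns in directly observed states are exponential and
        history-free, so their divergence terms in the general pair sum are
        exactly zero; only hidden-sojourn terms carry the rate."""
        m = decimated_f0
        R = m.visit_distribution()
        T = epwtd.mean_step_time(R, m.tau)
        rev = {s: (s[1], s[0]) for s in m.states}
        hidden_total = 0.0
        for a, sa in enumerate(m.states):
            for b, sb in enumerate(m.states):
                if m.p[b, a] == 0:
                    continue
                d = epwtd.kld_between_densities(m.wtd[(sa, sb)],
                                                m.wtd[(rev[sb], rev[sa])])
                if sa[1] != "H":
                    assert d == 0.0
                else:
                    hidden_total += m.p[b, a] * R[a] * d / T
        assert hidden_total == pytest.approx(epwtd.wtd_entropy_rate(m), rel=1e-10)


class TestRingIdentities:
    def test_triplet_current_identity(self, decimated_f0):
        """On the single observed cycle, p(ijk) - p(kji) equals the per-step
        current for every contiguous triplet."""
        m = decimated_f0
        R = dict(zip(m.states, m.visit_distribution()))
        idx = m.index

        def pp(a, b):
            return m.p[idx[b], idx[a]]

        J = R[("1", "2")] - R[("2", "1")]
        for (i, j, k) in [("1", "2", "H"), ("2", "H", "1"), ("H", "1", "2")]:
            fwd = R[(i, j)] * pp((i, j), (j, k))
            bwd = R[(k, j)] * pp((k, j), (j, i))
            assert fwd - bwd == pytest.approx(J, abs=1e-10)

    def test_affinity_vanishes_quadratically_at_stall(self, four_state, link,
                                                      partition, stall_force):
        """S_aff(F) fits a parabola through zero in F - F_stall."""
        dF = np.linspace(-0.1, 0.1, 7)
        s = []
        for d in dF:
            net = epwtd.apply_force(four_state, stall_force + d, link)
            s.append(epwtd.affinity_entropy_rate(
                epwtd.decimated_pair_process(net, partition, n_grid=2048)))
        s = np.array(s)
        x2 = dF ** 2
        a = float(x2 @ s / (x2 @ x2))
        resid = np.max(np.abs(s - a * x2)) / np.max(s)
        assert resid < 0.05
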