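"""Continuous-time Markov kinetic networks and reference entropy estimators.

The ground-truth object is a rate network with generator entries
``omega[i, j]`` = transition rate from state j to state i (columns index the
source state; all I/O keeps this orientation).  Besides the exact
steady-state (Schnakenberg) entropy production rate, this module implements
the two single-link lower bounds the waiting-time estimator is compared
against: the passive partial rate (the observed link's term of the
Schnakenberg sum) and the informed partial rate (which uses the stalling
populations obtained by retuning only the observed link).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .semimarkov import exponential_density, log_time_grid, SemiMarkovModel

STEADY_STATE_TOL = 1e-12
#: default force bracket (in 1/(beta L) units) scanned for a stall root
DEFAULT_STALL_BRACKET = (-10.0, 10.0)
STALL_CURRENT_TOL = 1e-12


@dataclass(frozen=True)
class RateNetwork:
    """A continuous-time Markov jump network.

    ``omega[i, j]`` is the rate of jumps j -> i (1/s), with zero diagonal.
    ``beta`` is the inverse temperature and ``L`` the length scale of the
    force protocol; forces are quoted in units of 1/(beta L), so only the
    product beta*F*L ever enters.
    """

    states: tuple
    omega: np.ndarray
    beta: float = 1.0
    L: float = 1.0

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        n = len(self.states)
        if omega.shape != (n, n):
            raise ValueError("omega shape does not match the state list")
        if np.any(np.diag(omega) != 0):
            raise ValueError("omega must have zero diagonal")
        if np.any(omega < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(omega.sum(axis=0) <= 0):
            dead = [self.states[i] for i in np.flatnonzero(omega.sum(axis=0) <= 0)]
            raise ValueError(f"states with no outgoing rate (absorbing): {dead}")
        sym = csr_matrix((omega + omega.T) > 0)
        ncomp, _ = connected_components(sym, directed=False)
        if ncomp > 1:
            raise ValueError("the embedded graph of the network is disconnected")
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "omega", omega)

    @property
    def index(self) -> dict:
        return {s: i for i, s in enumerate(self.states)}

    def tau(self) -> np.ndarray:
        """Mean (exponential) waiting time per state: 1 / total outgoing rate."""
        return 1.0 / self.omega.sum(axis=0)

    def generator(self) -> np.ndarray:
        """Master-equation generator W (columns sum to zero)."""
        w = self.omega.copy()
        np.fill_diagonal(w, -w.sum(axis=0))
        return w

    def jump_matrix(self) -> np.ndarray:
        """Embedded jump-chain matrix p[b, a] = tau_a * omega[b, a]."""
        return self.omega * self.tau()[np.newaxis, :]

    def rate(self, dst, src) -> float:
        return float(self.omega[self.index[dst], self.index[src]])


@dataclass(frozen=True)
class ObservedLink:
    """The pair of observed states carrying the force-modulated transition."""

    state_1: object
    state_2: object

    def indices(self, net: RateNetwork) -> tuple[int, int]:
        idx = net.index
        if self.state_1 not in idx or self.state_2 not in idx:
            raise ValueError(f"link states {self.state_1}, {self.state_2} "
                             "not both present in the network")
        i1, i2 = idx[self.state_1], idx[self.state_2]
        if net.omega[i1, i2] == 0 and net.omega[i2, i1] == 0:
            raise ValueError("observed link carries no rate in either direction")
        return i1, i2


def markov_steady_state(net: RateNetwork) -> np.ndarray:
    """Stationary distribution pi of the master equation, W pi = 0."""
    w = net.generator()
    n = w.shape[0]
    a = np.vstack([w, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = float(np.max(np.abs(w @ pi)))
    scale = float(np.max(np.abs(w)))
    if resid > STEADY_STATE_TOL * max(scale, 1.0):
        raise RuntimeError(f"steady-state residual {resid:.3e} exceeds tolerance")
    return pi


def schnakenberg_entropy_rate(net: RateNetwork, pi: np.ndarray | None = None) -> float:
    """Total steady-state entropy production rate (1/s, k_B = 1).

    S = sum_{i<j} (w_ji pi_i - w_ij pi_j) ln[(w_ji pi_i)/(w_ij pi_j)];
    every summand is nonnegative.  An edge carrying stationary flow in only
    one direction makes the rate +inf (warned, not raised).
    """
    if pi is None:
        pi = markov_steady_state(net)
    w = net.omega
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            fwd = w[j, i] * pi[i]   # flow i -> j
            bwd = w[i, j] * pi[j]   # flow j -> i
            if fwd == 0.0 and bwd == 0.0:
                continue
            if fwd == 0.0 or bwd == 0.0:
                warnings.warn(
                    f"one-way edge between {net.states[i]} and {net.states[j]}: "
                    "entropy production rate is +inf", RuntimeWarning, stacklevel=2)
                return float("inf")
            total += (fwd - bwd) * np.log(fwd / bwd)
    return total


def apply_force(net: RateNetwork, F: float, link: ObservedLink) -> RateNetwork:
    """Tilt the observed link: w_12 -> w_12 e^{beta F L}, w_21 -> w_21 e^{-beta F L}.

    ``w_12`` is the rate state_2 -> state_1.  F is in 1/(beta L) units, so the
    exponent is beta*F*L with the network's beta and L.  All other rates are
    untouched.
    """
    i1, i2 = link.indices(net)
    x = net.beta * F * net.L
    omega = net.omega.copy()
    omega[i1, i2] *= np.exp(x)
    omega[i2, i1] *= np.exp(-x)
    return replace(net, omega=omega)


def link_current(net: RateNetwork, link: ObservedLink,
                 pi: np.ndarray | None = None) -> float:
    """Stationary probability current over the link in the 2 -> 1 direction."""
    if pi is None:
        pi = markov_steady_state(net)
    i1, i2 = link.indices(net)
    return float(net.omega[i1, i2] * pi[i2] - net.omega[i2, i1] * pi[i1])


def find_stall_force(net: RateNetwork, link: ObservedLink,
                     bracket: tuple[float, float] = DEFAULT_STALL_BRACKET) -> float:
    """Force at which the observed-link current vanishes.

    The current is continuous in F; a sign change on the bracket is required
    and located by Brent's method to |current| < 1e-12.
    """
    def current(F: float) -> float:
        return link_current(apply_force(net, F, link), link)

    lo, hi = bracket
    clo, chi = current(lo), current(hi)
    if clo == 0.0:
        return lo
    if chi == 0.0:
        return hi
    if np.sign(clo) == np.sign(chi):
        raise ValueError(
            f"link current does not change sign on F in [{lo}, {hi}]: "
            f"current({lo}) = {clo:.6e}, current({hi}) = {chi:.6e}")
    F = brentq(current, lo, hi, xtol=1e-15, rtol=4 * np.finfo(float).eps)
    c = current(F)
    if abs(c) > STALL_CURRENT_TOL:
        raise RuntimeError(f"stall current {c:.3e} above tolerance at F = {F}")
    return float(F)


def passive_partial(net: RateNetwork, pi: np.ndarray | None = None,
                    link: ObservedLink | None = None) -> float:
    """Passive partial entropy production: the observed link's Schnakenberg term."""
    if link is None:
        raise ValueError("an observed link is required")
    if pi is None:
        pi = markov_steady_state(net)
    i1, i2 = link.indices(net)
    fwd = net.omega[i1, i2] * pi[i2]
    bwd = net.omega[i2, i1] * pi[i1]
    if fwd == 0.0 or bwd == 0.0:
        warnings.warn("one-way observed link: passive partial rate is +inf",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return float((fwd - bwd) * np.log(fwd / bwd))


def informed_partial(net: RateNetwork, link: ObservedLink,
                     bracket: tuple[float, float] = DEFAULT_STALL_BRACKET) -> float:
    """Informed partial entropy production.

    (w_12 pi_2 - w_21 pi_1) ln[(w_12 pi_2^stall)/(w_21 pi_1^stall)], where the
    stalling populations come from the network with only the link rates
    retuned to the stall force.
    """
    pi = markov_steady_state(net)
    F_stall = find_stall_force(net, link, bracket)
    pi_stall = markov_steady_state(apply_force(net, F_stall, link))
    i1, i2 = link.indices(net)
    j = net.omega[i1, i2] * pi[i2] - net.omega[i2, i1] * pi[i1]
    arg = (net.omega[i1, i2] * pi_stall[i2]) / (net.omega[i2, i1] * pi_stall[i1])
    return float(j * np.log(arg))


def markov_semimarkov_model(net: RateNetwork,
                            grid: np.ndarray | None = None) -> SemiMarkovModel:
    """The fully observed network as a first-order semi-Markov model.

    Exits from each state are exponential with the state's total rate and do
    not depend on the destination, so the waiting-time part of the entropy
    production vanishes and S_kld reduces to the Schnakenberg rate.
    """
    tau = net.tau()
    p = net.jump_matrix()
    if grid is None:
        grid = log_time_grid(float(np.max(tau)),
                             lo_rel=1e-7 * float(np.min(tau) / np.max(tau)))
    wtd = {}
    for a, sa in enumerate(net.states):
        dens = exponential_density(1.0 / tau[a], grid).normalized()
        for b, sb in enumerate(net.states):
            if p[b, a] > 0:
                wtd[(sa, sb)] = dens
    return SemiMarkovModel(states=list(net.states), p=p, wtd=wtd, order=1, tau=tau)


# ---------------------------------------------------------------------------
# bundled example networks
# ---------------------------------------------------------------------------

#: rates (1/s) of the four-state hidden-network example; entry [i, j] is the
#: rate j -> i, states ("1", "2", "3", "4"), states 3 and 4 hidden.
FOUR_STATE_RATES = np.array([
    [0.0,  2.0,  0.0,  1.0],
    [3.0,  0.0,  2.0, 35.0],
    [0.0, 50.0,  0.0,  0.7],
    [8.0,  0.2, 75.0,  0.0],
])

FOUR_STATE_LINK = ObservedLink("1", "2")


def four_state_network() -> RateNetwork:
    """The four-state kinetic network with hidden states 3 and 4."""
    return RateNetwork(states=("1", "2", "3", "4"), omega=FOUR_STATE_RATES.copy())


def random_network(seed: int, n_states: int = 4,
                   low: float = 0.5, high: float = 10.0) -> RateNetwork:
    """A seeded random fully connected n-state network (uniform rates)."""
    rng = np.random.default_rng(seed)
    omega = rng.uniform(low, high, size=(n_states, n_states))
    np.fill_diagonal(omega, 0.0)
    return RateNetwork(states=tuple(str(i + 1) for i in range(n_states)), omega=omega)
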