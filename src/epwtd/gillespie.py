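"""Exact stochastic simulation of rate-network trajectories.

The Gillespie algorithm for a time-homogeneous jump network: the dwell in
state a is exponential with mean tau_a = 1/sum_b omega[b, a] and the
successor is drawn with probability tau_a * omega[b, a].  Dwells are stored
per event (not as absolute times) so that lumping hidden sojourns later is
exact.  All randomness comes from a single numpy Generator seeded from the
``seed`` argument, which makes runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import RateNetwork, markov_steady_state

#: uniform/exponential variates are drawn in blocks of this size
_BLOCK = 262144

_CORE = None


def _core_python(idx, dwells, pos, u, e, cum, tau, state):
    """Inner jump loop; consumes one pre-drawn variate pair per step."""
    from bisect import bisect_right
    cum_lists = [list(row) for row in cum]
    tau_list = [float(t) for t in tau]
    ul = u.tolist()
    el = e.tolist()
    for k in range(len(ul)):
        idx[pos + k] = state
        dwells[pos + k] = el[k] * tau_list[state]
        state = bisect_right(cum_lists[state], ul[k])
    return state


def _compiled_core():
    """Numba-compiled jump loop when numba is importable, else None."""
    global _CORE
    if _CORE is None:
        try:
            from numba import njit

            @njit(cache=False)
            def core(idx, dwells, pos, u, e, cum, tau, state):
                n = cum.shape[1]
                for k in range(u.shape[0]):
                    idx[pos + k] = state
                    dwells[pos + k] = e[k] * tau[state]
                    uu = u[k]
                    s = 0
                    while s < n - 1 and cum[state, s] <= uu:
                        s += 1
                    state = s
                return state

            _CORE = core
        except ImportError:
            _CORE = False
    return _CORE or None


@dataclass
class Trajectory:
    """An ordered list of (state, dwell) events produced by one network."""

    states: list
    dwells: np.ndarray
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dwells = np.asarray(self.dwells, dtype=float)
        if len(self.states) != len(self.dwells):
            raise ValueError("states and dwells must have equal length")
        if np.any(self.dwells <= 0):
            raise ValueError("dwell times must be positive")
        arr = np.asarray(self.states, dtype=object)
        if len(arr) > 1 and np.any(arr[1:] == arr[:-1]):
            raise ValueError("consecutive states must differ")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def total_time(self) -> float:
        return float(self.dwells.sum())


def simulate(net: RateNetwork, n_steps: int, seed: int,
             initial: object = "stationary") -> Trajectory:
    """Sample a trajectory of ``n_steps`` events (visited states with dwells).

    ``initial`` is either a state label or ``"stationary"`` (the default),
    which draws the first state from the stationary occupancy to avoid
    transient bias in step statistics.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    rng = np.random.default_rng(seed)
    n = len(net.states)
    tau = net.tau()
    p = net.jump_matrix()          # p[b, a]
    cum = np.cumsum(p, axis=0).T   # cum[a, b] for searchsorted per source
    cum[:, -1] = 1.0

    if initial == "stationary":
        pi = markov_steady_state(net)
        state = int(rng.choice(n, p=pi))
    else:
        if initial not in net.index:
            raise ValueError(f"unknown initial state {initial!r}")
        state = net.index[initial]

    # all variates are pre-drawn from one Generator so the trajectory is
    # bit-identical whether the compiled or the pure-python core runs
    idx = np.empty(n_steps, dtype=np.int64)
    dwells = np.empty(n_steps, dtype=float)
    pos = 0
    core = _compiled_core()
    while pos < n_steps:
        m = min(_BLOCK, n_steps - pos)
        u = rng.random(m)
        e = rng.exponential(1.0, m)
        if core is not None:
            state = int(core(idx, dwells, pos, u, e, cum, tau, state))
        else:
            state = _core_python(idx, dwells, pos, u, e, cum, tau, state)
        pos += m

    labels = [net.states[i] for i in idx]
    return Trajectory(states=labels, dwells=dwells,
                      origin={"seed": seed, "n_steps": n_steps,
                              "initial": initial,
                              "states": list(net.states)})
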