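"""Two-internal-state molecular motor on a periodic track.

Each lattice site carries a passive state ``i`` and an active state ``i'``
(the latter able to hydrolyze fuel).  Internal flips run at rate ``k_s`` in
both directions.  Spatial transitions are attempted at rate ``k_0`` and obey
local detailed balance: the passive channel ``i <-> i+1`` is tilted by the
mechanical force, ratio down/up = e^{beta F L}, and the active channel
``i' <-> i+1`` additionally consumes the chemical drive, ratio
down/up = e^{beta(FL - dmu)}.  Each ratio is split symmetrically between the
two directions (rates k_0 e^{+-Delta/2}), the mid-point load-sharing
convention.

An observer sees only the position.  Both upward channels land in the
passive state while a downward jump lands in passive or active depending on
the channel, so the internal state after a step depends only on the step's
direction and the observed stepping process is second-order semi-Markov over
the two directions ``up`` and ``down``.  Its conditional step-time densities
are phase-type laws of the two-state internal block of the current site.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .coarse_grain import _phase_type_densities
from .markov import RateNetwork
from .semimarkov import DEFAULT_GRID_SIZE, SemiMarkovModel, visit_distribution

STALL_VISIT_TOL = 1e-10


@dataclass(frozen=True)
class MotorSpec:
    """Parameters of the motor: rates in 1/s, F in 1/(beta L), dmu in 1/beta."""

    k_s: float = 1.0
    k_0: float = 0.01
    F: float = 0.0
    dmu: float = 0.0
    n_cells: int = 4
    beta: float = 1.0
    L: float = 1.0

    def __post_init__(self) -> None:
        if self.k_s <= 0 or self.k_0 <= 0:
            raise ValueError("k_s and k_0 must be positive")
        if self.n_cells < 3:
            raise ValueError("the periodic embedding needs n_cells >= 3")

    def channel_rates(self) -> dict:
        """Up/down rates of the two spatial channels under the mid-point split."""
        x = self.beta * self.F * self.L          # mechanical tilt
        y = x - self.beta * self.dmu             # active-channel exponent
        return {
            "up_passive": self.k_0 * np.exp(-x / 2.0),
            "down_passive": self.k_0 * np.exp(+x / 2.0),
            "up_active": self.k_0 * np.exp(-y / 2.0),
            "down_active": self.k_0 * np.exp(+y / 2.0),
        }


def build_motor_network(spec: MotorSpec) -> RateNetwork:
    """The motor as a rate network on a ring of ``n_cells`` sites.

    States are ``p{i}`` (passive) and ``a{i}`` (active) per cell.  The
    passive channel connects p{i} and p{i+1}; the active channel connects
    a{i} and p{i+1}; internal flips connect p{i} and a{i} at ``k_s``.
    Translational symmetry makes every reported steady-state rate independent
    of ``n_cells``.
    """
    n = spec.n_cells
    ch = spec.channel_rates()
    states = [f"p{i}" for i in range(n)] + [f"a{i}" for i in range(n)]
    idx = {s: k for k, s in enumerate(states)}
    omega = np.zeros((2 * n, 2 * n))

    def add(dst, src, rate):
        omega[idx[dst], idx[src]] += rate

    for i in range(n):
        j = (i + 1) % n
        add(f"a{i}", f"p{i}", spec.k_s)
        add(f"p{i}", f"a{i}", spec.k_s)
        add(f"p{j}", f"p{i}", ch["up_passive"])
        add(f"p{i}", f"p{j}", ch["down_passive"])
        add(f"p{j}", f"a{i}", ch["up_active"])
        add(f"a{i}", f"p{j}", ch["down_active"])
    return RateNetwork(states=tuple(states), omega=omega,
                       beta=spec.beta, L=spec.L)


def _internal_block(spec: MotorSpec):
    """Sub-generator, exit-rate vectors and entry distributions of one site.

    Hidden states ordered [passive, active].  Exit channels are the step
    directions.  Entry after an up step puts all mass on passive (both up
    channels land there); after a down step the landing state is passive or
    active with weights given by the two downward channel rates.
    """
    ch = spec.channel_rates()
    ks = spec.k_s
    up_p, dn_p = ch["up_passive"], ch["down_passive"]
    up_a, dn_a = ch["up_active"], ch["down_active"]
    M = np.array([
        [-(ks + up_p + dn_p + dn_a), ks],
        [ks, -(ks + up_a)],
    ])
    exit_rates = {"up": np.array([up_p, up_a]),
                  "down": np.array([dn_p + dn_a, 0.0])}
    entries = {"up": np.array([1.0, 0.0]),
               "down": np.array([dn_p, dn_a]) / (dn_p + dn_a)}
    return M, exit_rates, entries


def motor_observed_process(spec: MotorSpec,
                           n_grid: int = DEFAULT_GRID_SIZE) -> SemiMarkovModel:
    """Second-order semi-Markov model of the observed stepping process.

    States are the last step's direction, ``up`` or ``down``; time reversal
    swaps them.  The four conditional step-time densities share one grid so
    identical laws (up-up vs down-down at dmu = 0) compare exactly.
    """
    M, exit_rates, entries = _internal_block(spec)
    # shared grid across both entry contexts
    means = [float(-np.linalg.solve(M, mu).sum()) for mu in entries.values()]
    lam = np.linalg.eigvals(M)
    from .semimarkov import log_time_grid
    grid = log_time_grid(max(max(means), 1.0 / abs(np.max(lam.real))), n=n_grid)

    while True:
        ok = True
        blocks = {}
        for d, mu in entries.items():
            splits, dens, _, mean_abs, grid2 = _phase_type_densities(
                M, exit_rates, mu, grid)
            if len(grid2) != len(grid) or grid2[-1] != grid[-1]:
                grid, ok = grid2, False
                break
            blocks[d] = (splits, dens, mean_abs)
        if ok:
            break

    states = ["up", "down"]
    p = np.zeros((2, 2))
    wtd = {}
    tau = np.zeros(2)
    for a, d in enumerate(states):
        splits, dens, mean_abs = blocks[d]
        tau[a] = mean_abs
        for b, d2 in enumerate(states):
            p[b, a] = splits[d2]
            wtd[(d, d2)] = dens[d2]
    return SemiMarkovModel(states=states, p=p, wtd=wtd, order=2,
                           reversal={"up": "down", "down": "up"}, tau=tau)


def observed_step_current(spec: MotorSpec) -> float:
    """Per-step current J = R_up - R_down of the observed stepping process."""
    M, exit_rates, entries = _internal_block(spec)
    minv = np.linalg.inv(M)
    p = np.zeros((2, 2))
    for a, d in enumerate(("up", "down")):
        for b, d2 in enumerate(("up", "down")):
            p[b, a] = float(-exit_rates[d2] @ minv @ entries[d])
    R = visit_distribution(p)
    return float(R[0] - R[1])


def motor_stall_force(spec: MotorSpec,
                      bracket: tuple[float, float] | None = None) -> float:
    """Force at which the observed step current vanishes (R_up = R_down).

    For dmu > 0 the chemical drive pushes the motor up, so the stalling force
    is positive (the force tilt favors down steps).
    """
    if bracket is None:
        span = abs(spec.dmu) + 5.0
        bracket = (-span, span)

    def current(F: float) -> float:
        return observed_step_current(replace(spec, F=F))

    lo, hi = bracket
    clo, chi = current(lo), current(hi)
    if np.sign(clo) == np.sign(chi) and clo != 0.0 and chi != 0.0:
        raise ValueError(f"step current does not change sign on [{lo}, {hi}]: "
                         f"{clo:.3e} vs {chi:.3e}")
    F = brentq(current, lo, hi, xtol=1e-14, rtol=4 * np.finfo(float).eps)
    c = current(F)
    if abs(c) > STALL_VISIT_TOL:
        raise RuntimeError(f"residual step current {c:.3e} at F = {F}")
    return float(F)
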