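"""End-to-end experiments: simulate -> lump -> estimate vs exact decimation.

These convenience drivers reproduce the hidden-network convergence
experiments: a trajectory of the four-state network is simulated at a given
force, coarse-grained to {1, 2, H}, fed to the plug-in estimator, and
compared against the analytic entropy production rate of the decimated
second-order process.
"""

from __future__ import annotations

import numpy as np

from .coarse_grain import PairTrajectory, Partition, decimated_pair_process, \
    lump_trajectory
from .estimation import empirical_second_order_estimate
from .gillespie import simulate
from .markov import ObservedLink, RateNetwork, apply_force, find_stall_force, \
    four_state_network, FOUR_STATE_LINK


def simulate_lumped(net: RateNetwork, part: Partition, n_pairs: int,
                    seed: int) -> PairTrajectory:
    """Simulate until the coarse-grained trajectory holds ``n_pairs`` sojourns.

    The raw run is extended as needed and the lumped trajectory truncated to
    exactly ``n_pairs`` events, so the pair-level sample size is controlled.
    """
    n_raw = n_pairs * 3
    while True:
        traj = simulate(net, n_raw, seed)
        ptraj = lump_trajectory(traj, part)
        if len(ptraj) >= n_pairs:
            return PairTrajectory(pairs=ptraj.pairs[:n_pairs],
                                  dwells=ptraj.dwells[:n_pairs],
                                  origin=ptraj.origin)
        n_raw = int(n_raw * 1.5)


def convergence_experiment(F: float, n_pairs: int, seed: int,
                           net: RateNetwork | None = None,
                           link: ObservedLink | None = None,
                           part: Partition | None = None,
                           at_stall: bool = False) -> dict:
    """One convergence measurement of the plug-in estimator.

    Returns the analytic rate, the trajectory estimate and their relative
    error |estimate/analytic - 1| (as used in the convergence study), all on
    the four-state hidden-network example unless another network is given.
    """
    net = net if net is not None else four_state_network()
    link = link if link is not None else FOUR_STATE_LINK
    part = part if part is not None else Partition(observed=("1", "2"),
                                                   hidden=("3", "4"))
    if at_stall:
        F = find_stall_force(net, link)
    tilted = apply_force(net, F, link)
    from .semimarkov import kld_entropy_rate
    analytic = kld_entropy_rate(decimated_pair_process(tilted, part))
    ptraj = simulate_lumped(tilted, part, n_pairs, seed)
    estimate = empirical_second_order_estimate(ptraj)
    rel = abs(estimate.S_kld / analytic.S_kld - 1.0)
    return {"force": float(F), "n_pairs": n_pairs, "seed": seed,
            "analytic_S_kld": analytic.S_kld,
            "estimated_S_kld": estimate.S_kld,
            "relative_error": float(rel),
            "relative_error_pct": float(100.0 * rel),
            "analytic": analytic, "estimate": estimate}
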