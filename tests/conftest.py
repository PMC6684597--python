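"""Shared fixtures: the four-state hidden network and reusable simulations."""

import numpy as np
import pytest

import epwtd


@pytest.fixture(scope="session")
def four_state():
    return epwtd.four_state_network()


@pytest.fixture(scope="session")
def link():
    return epwtd.FOUR_STATE_LINK


@pytest.fixture(scope="session")
def partition():
    return epwtd.Partition(observed=("1", "2"), hidden=("3", "4"))


@pytest.fixture(scope="session")
def stall_force(four_state, link):
    return epwtd.find_stall_force(four_state, link)


@pytest.fixture(scope="session")
def decimated_f0(four_state, partition):
    """Analytic pair process of the four-state network at zero force."""
    return epwtd.decimated_pair_process(four_state, partition)


@pytest.fixture(scope="session")
def decimated_stall(four_state, link, partition, stall_force):
    net = epwtd.apply_force(four_state, stall_force, link)
    return epwtd.decimated_pair_process(net, partition)


@pytest.fixture(scope="session")
def long_trajectory(four_state):
    """A 3e5-step stationary trajectory of the unforced network (seed 2024)."""
    return epwtd.simulate(four_state, 300_000, seed=2024)


def simulate_lumped(net, part, n_pairs, seed):
    """Simulate until the lumped pair trajectory has ``n_pairs`` sojourns."""
    n_raw = n_pairs * 3
    while True:
        traj = epwtd.simulate(net, n_raw, seed)
        ptraj = epwtd.lump_trajectory(traj, part)
        if len(ptraj) >= n_pairs:
            return epwtd.PairTrajectory(pairs=ptraj.pairs[:n_pairs],
                                        dwells=ptraj.dwells[:n_pairs])
        n_raw = int(n_raw * 1.5)


@pytest.fixture(scope="session")
def lumped_f0(four_state, partition, long_trajectory):
    return epwtd.lump_trajectory(long_trajectory, partition)


def random_jump_chain(seed, n=4):
    """A random irreducible column-stochastic jump matrix with zero diagonal."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 1.0, size=(n, n))
    np.fill_diagonal(p, 0.0)
    return p / p.sum(axis=0, keepdims=True)
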