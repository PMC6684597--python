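"""Lumping hidden states and the exact decimated second-order description.

When an observer resolves only a subset of a Markov network's states, all
unresolved states appear as one super-state H.  Sojourns in H are then
phase-type distributed (the absorption time of the hidden sub-generator) and
depend on how H was entered, so the observed dynamics is a second-order
semi-Markov process over pair states [prev, curr].

Two routes produce that description here:

* empirically, by merging consecutive hidden sojourns of a simulated or
  measured trajectory (``lump_trajectory``);
* analytically, by building the pair-state jump chain and the conditional
  sojourn densities from the rate matrix (``decimated_pair_process``).  The
  path sum over hidden routes is evaluated in the time domain as a
  phase-type density via the eigendecomposition of the hidden sub-generator,
  which is equivalent to the geometric sum over paths in Laplace space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .gillespie import Trajectory
from .markov import RateNetwork
from .semimarkov import (DEFAULT_GRID_SIZE, DensityOnGrid, SemiMarkovModel,
                         exponential_density, log_time_grid)

#: grid mass missing beyond the truncation point triggers automatic extension
GRID_MASS_DEFICIT_TOL = 1e-8
SPLIT_SUM_TOL = 1e-10


@dataclass(frozen=True)
class Partition:
    """Split of the state set into observed states and a lumped hidden block."""

    observed: tuple
    hidden: tuple
    hidden_label: str = "H"

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed", tuple(self.observed))
        object.__setattr__(self, "hidden", tuple(self.hidden))
        if set(self.observed) & set(self.hidden):
            raise ValueError("observed and hidden state sets must be disjoint")
        if not self.observed:
            raise ValueError("at least one state must be observed")
        if self.hidden_label in self.observed:
            raise ValueError(f"hidden label {self.hidden_label!r} clashes with "
                             "an observed state")

    def project(self, state) -> object:
        return self.hidden_label if state in self.hidden else state


@dataclass
class PairTrajectory:
    """A trajectory lifted to [prev, curr] pair states after lumping.

    ``pairs[k]`` is the pair state occupied during ``dwells[k]`` seconds;
    consecutive pairs chain ([i,j] is followed by some [j,k]).
    """

    pairs: list
    dwells: np.ndarray
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dwells = np.asarray(self.dwells, dtype=float)
        if len(self.pairs) != len(self.dwells):
            raise ValueError("pairs and dwells must have equal length")
        if np.any(self.dwells <= 0):
            raise ValueError("dwell times must be positive")
        for a, b in zip(self.pairs, self.pairs[1:]):
            if a[1] != b[0]:
                raise ValueError(f"pair states do not chain: {a} -> {b}")

    def __len__(self) -> int:
        return len(self.pairs)


def lump_trajectory(traj: Trajectory, part: Partition) -> PairTrajectory:
    """Coarse-grain a trajectory and lift it to pair states.

    Consecutive sojourns in hidden states merge into a single H sojourn with
    the summed dwell; hidden-internal jumps are erased.  The first sojourn is
    dropped because it has no predecessor.
    """
    known = set(part.observed) | set(part.hidden)
    unknown = sorted({s for s in traj.states if s not in known}, key=repr)
    if unknown:
        raise ValueError(f"trajectory states not covered by the partition: {unknown}")

    hidden = set(part.hidden)
    labels = np.array([part.hidden_label if s in hidden else s
                       for s in traj.states], dtype=object)
    # merge runs of identical labels (these are exactly the hidden-internal jumps)
    new_run = np.empty(len(labels), dtype=bool)
    new_run[0] = True
    new_run[1:] = labels[1:] != labels[:-1]
    starts = np.flatnonzero(new_run)
    merged_labels = labels[starts]
    merged_dwells = np.add.reduceat(traj.dwells, starts)
    if len(merged_labels) < 2:
        raise ValueError("trajectory is entirely hidden after lumping")

    pairs = [(merged_labels[k - 1], merged_labels[k])
             for k in range(1, len(merged_labels))]
    return PairTrajectory(pairs=pairs, dwells=merged_dwells[1:],
                          origin={**traj.origin, "partition": {
                              "observed": list(part.observed),
                              "hidden": list(part.hidden),
                              "hidden_label": part.hidden_label}})


# ---------------------------------------------------------------------------
# phase-type sojourn densities of the hidden block
# ---------------------------------------------------------------------------

def _phase_type_densities(M: np.ndarray, exit_rates: dict, entry: np.ndarray,
                          grid: np.ndarray | None = None,
                          n_grid: int = DEFAULT_GRID_SIZE,
                          check_total: bool = True):
    """Splitting probabilities, conditional exit densities and means.

    ``M`` is the hidden-block sub-generator (hidden-to-hidden rates off the
    diagonal, minus the total outflow on the diagonal), ``exit_rates[k]`` the
    vector of rates from each hidden state into exit channel k, and ``entry``
    the distribution over hidden states at entry.  The density of leaving
    through channel k at time t is sum_j [exp(tM) entry]_j exit_rates[k][j];
    splitting probabilities and conditional means come from -M^-1 and M^-2
    exactly.
    """
    M = np.asarray(M, dtype=float)
    entry = np.asarray(entry, dtype=float)
    if abs(entry.sum() - 1.0) > 1e-12 or np.any(entry < 0):
        raise ValueError("entry distribution must be a probability vector")
    eigvals = np.linalg.eigvals(M)
    if np.max(eigvals.real) >= 0:
        raise ValueError("hidden block is not escapable (sub-generator not "
                         f"strictly stable; eigenvalues {eigvals})")

    minv_entry = np.linalg.solve(M, entry)            # M^-1 entry  (<= 0)
    m2_entry = np.linalg.solve(M, minv_entry)         # M^-2 entry
    splits = {k: float(-r @ minv_entry) for k, r in exit_rates.items()}
    ssum = sum(splits.values())
    if check_total and abs(ssum - 1.0) > SPLIT_SUM_TOL:
        raise RuntimeError(f"splitting probabilities sum to {ssum}, not 1")
    cond_means = {k: float(r @ m2_entry) / splits[k] if splits[k] > 0 else np.nan
                  for k, r in exit_rates.items()}
    mean_abs = float(-minv_entry.sum())

    if grid is None:
        slowest = 1.0 / abs(np.max(eigvals.real))
        grid = log_time_grid(max(mean_abs, slowest), n=n_grid)

    occ = _occupancy_on_grid(M, entry, grid)
    while True:
        # truncation deficit = survival probability in the block at the grid end
        deficit = float(occ[-1].sum())
        if deficit <= GRID_MASS_DEFICIT_TOL:
            break
        grid = log_time_grid(grid[-1] / GRID_HI_EXTEND, n=len(grid))
        occ = _occupancy_on_grid(M, entry, grid)

    dens = {}
    for k, r in exit_rates.items():
        if splits[k] <= 0:
            continue
        # renormalize away the residual grid-truncation mass (< 1e-8)
        dens[k] = DensityOnGrid(grid, (occ @ r) / splits[k]).normalized()
    return splits, dens, cond_means, mean_abs, grid


GRID_HI_EXTEND = 0.25   # each extension multiplies the grid end by 1/this


def _occupancy_on_grid(M: np.ndarray, entry: np.ndarray,
                       grid: np.ndarray) -> np.ndarray:
    """occ[t_i, j] = [exp(t_i M) entry]_j, via eigendecomposition when sound."""
    n = M.shape[0]
    lam, V = np.linalg.eig(M)
    try:
        c = np.linalg.solve(V, entry)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        occ = (np.exp(np.outer(grid, lam)) * c) @ V.T
        occ = occ.real
    else:
        # defective or ill-conditioned sub-generator: fall back to expm
        occ = np.empty((len(grid), n))
        for i, t in enumerate(grid):
            occ[i] = scipy.linalg.expm(M * t) @ entry
    return np.clip(occ, 0.0, None)


def phase_type_wtd(net: RateNetwork, hidden, entry_dist,
                   exits=None, grid: np.ndarray | None = None,
                   n_grid: int = DEFAULT_GRID_SIZE):
    """Exit statistics of one sojourn in a lumped hidden block.

    Parameters
    ----------
    net
        The full rate network.
    hidden
        Labels of the hidden states.
    entry_dist
        Probability of starting the sojourn in each hidden state, in the
        order given by ``hidden``.
    exits
        Optional subset of observed labels to treat as absorbing exits;
        defaults to every observed state the hidden block can reach.
    grid, n_grid
        Optional shared time grid / grid size for the returned densities.

    Returns
    -------
    (splits, densities, means)
        Dicts keyed by the observed exit state: the probability of leaving
        through that state, the normalized conditional sojourn density, and
        its exact mean.
    """
    hidden = list(hidden)
    hidx = [net.index[h] for h in hidden]
    observed = [s for s in net.states if s not in set(hidden)]
    if exits is not None:
        observed = [o for o in observed if o in set(exits)]
    oidx = [net.index[o] for o in observed]
    M = net.generator()[np.ix_(hidx, hidx)]
    exit_rates = {}
    for o, oi in zip(observed, oidx):
        r = net.omega[oi, hidx]
        if np.any(r > 0):
            exit_rates[o] = r
    splits, dens, means, _, _ = _phase_type_densities(
        M, exit_rates, np.asarray(entry_dist, dtype=float), grid, n_grid,
        check_total=exits is None)
    return splits, dens, means


# ---------------------------------------------------------------------------
# the analytic decimated pair process
# ---------------------------------------------------------------------------

def decimated_pair_process(net: RateNetwork, part: Partition,
                           n_grid: int = DEFAULT_GRID_SIZE) -> SemiMarkovModel:
    """Exact second-order semi-Markov model of the partially observed network.

    Pair states run over [prev, curr] with curr in the observed alphabet plus
    H.  Exits from observed states keep their exponential waiting times
    (independent of history); exits from H use the phase-type sojourn law
    with the entry distribution fixed by the previous observed state's rates
    into the hidden block.  All densities share one time grid so that
    identical conditional laws compare exactly.
    """
    for s in part.observed + part.hidden:
        if s not in net.index:
            raise ValueError(f"partition state {s!r} not in the network")
    if set(part.observed) | set(part.hidden) != set(net.states):
        raise ValueError("partition must cover the network's state set")

    H = part.hidden_label
    hidden = list(part.hidden)
    observed = list(part.observed)
    tau_full = net.tau()
    entries: dict = {}
    ht: dict = {}

    if hidden:
        hidx = [net.index[h] for h in hidden]
        M = net.generator()[np.ix_(hidx, hidx)]
        eigvals = np.linalg.eigvals(M)
        if np.max(eigvals.real) >= 0:
            raise ValueError("hidden block is not escapable")

        exit_rates = {}
        for o in observed:
            r = net.omega[net.index[o], hidx]
            if np.any(r > 0):
                exit_rates[o] = r

        # entry distribution into H for each observed predecessor
        for o in observed:
            r_in = net.omega[hidx, net.index[o]]
            if np.any(r_in > 0):
                entries[o] = r_in / r_in.sum()

        # one shared grid for every density in the model
        means_abs = [float(-np.linalg.solve(M, mu).sum())
                     for mu in entries.values()]
        slowest = 1.0 / abs(np.max(eigvals.real))
        t_scale = max(max(means_abs), slowest, float(np.max(tau_full)))
        grid = log_time_grid(t_scale, n=n_grid)

        # H-exit statistics per entry context, extending the grid until
        # every density is mass-complete
        while True:
            ok = True
            ht = {}
            for o, mu in entries.items():
                splits, dens, means, mean_abs, grid2 = _phase_type_densities(
                    M, exit_rates, mu, grid)
                if len(grid2) != len(grid) or grid2[-1] != grid[-1]:
                    grid, ok = grid2, False
                    break
                ht[o] = (splits, dens, means, mean_abs)
            if ok:
                break
    else:
        # no hidden states: the pair process is the fully observed network
        # lifted to pairs, with exponential sojourns (the Markov limit)
        exit_rates = {}
        grid = log_time_grid(float(np.max(tau_full)), n=n_grid)

    # assemble the pair alphabet
    pair_states = []
    for x in observed:
        for y in observed:
            if x != y and net.rate(y, x) > 0:
                pair_states.append((x, y))
        if x in entries:
            pair_states.append((x, H))
    for y in observed:
        if y in exit_rates:
            for x in observed:
                if x in entries:
                    pair_states.append((H, y)) if (H, y) not in pair_states else None
    pair_states = list(dict.fromkeys(pair_states))

    n = len(pair_states)
    pidx = {s: i for i, s in enumerate(pair_states)}
    p = np.zeros((n, n))
    wtd = {}
    tau = np.zeros(n)

    exp_dens = {o: exponential_density(1.0 / tau_full[net.index[o]], grid).normalized()
                for o in observed}

    for a, (x, y) in enumerate(pair_states):
        if y != H:
            yi = net.index[y]
            tau[a] = tau_full[yi]
            for (yy, z) in pair_states:
                if yy != y:
                    continue
                b = pidx[(yy, z)]
                if z == H:
                    rate = float(net.omega[hidx, yi].sum())
                else:
                    rate = net.rate(z, y)
                if rate > 0:
                    p[b, a] = tau_full[yi] * rate
                    wtd[((x, y), (yy, z))] = exp_dens[y]
        else:
            splits, dens, means, mean_abs = ht[x]
            tau[a] = mean_abs
            for z, q in splits.items():
                if q <= 0:
                    continue
                b = pidx[(H, z)]
                p[b, a] = q
                wtd[((x, H), (H, z))] = dens[z]

    return SemiMarkovModel(states=pair_states, p=p, wtd=wtd, order=2, tau=tau)
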