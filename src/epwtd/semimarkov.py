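"""Semi-Markov processes and the KLD decomposition of entropy production.

A (first-order) semi-Markov process is a renewal jump process on a discrete
state set: the sequence of visited states is a Markov chain with transition
matrix ``p[beta, alpha]`` (probability that the next jump is alpha -> beta),
and the dwell in ``alpha`` preceding a jump to ``beta`` is drawn from the
conditional waiting-time density ``psi(t | alpha -> beta)``.  A second-order
process is the same object built over pair states ``[prev, curr]``.

The entropy production rate inferred from the irreversibility of stationary
trajectories splits exactly into two parts,

    S_kld = S_aff + S_wtd,

where ``S_aff`` is carried by the sequence of states alone (it is
proportional to the stationary current and vanishes at stall) and ``S_wtd``
is carried by the asymmetry between forward and time-reversed conditional
waiting-time densities, which can remain positive at zero current.
All rates use k_B = 1 and are reported per second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

# numerical tolerances: linear-algebra identities are demanded to near machine
# precision, density normalization only to quadrature accuracy
STOCHASTIC_TOL = 1e-12
EIGVEC_RESIDUAL_TOL = 1e-10
DENSITY_MASS_TOL = 1e-6

#: points in the default time grid used for analytically constructed densities;
#: sized so trapezoid mass and KLD quadrature errors sit below 1e-6
DEFAULT_GRID_SIZE = 8192
#: default span of the log-spaced time grid, relative to the density mean
GRID_LO_REL = 1e-6
GRID_HI_REL = 50.0


class ReducibleChainError(ValueError):
    """Raised when a jump chain has no unique stationary visit distribution."""


def log_time_grid(t_scale: float, n: int = DEFAULT_GRID_SIZE,
                  lo_rel: float = GRID_LO_REL, hi_rel: float = GRID_HI_REL) -> np.ndarray:
    """Log-spaced time grid covering [lo_rel, hi_rel] * t_scale, with t=0 prepended.

    Including t=0 keeps the trapezoid mass of densities with a finite value at
    the origin (exponential, phase-type) accurate near zero.
    """
    if t_scale <= 0:
        raise ValueError(f"time scale must be positive, got {t_scale}")
    return np.concatenate(([0.0], np.geomspace(lo_rel * t_scale, hi_rel * t_scale, n - 1)))


@dataclass
class DensityOnGrid:
    """A probability density on t >= 0 represented by values on a time grid.

    This is the common numerical currency for analytic (phase-type,
    exponential) and kernel-estimated waiting-time densities.  ``mass`` is the
    trapezoid integral over the grid; a valid conditional waiting-time density
    has mass 1 up to quadrature/truncation error.
    """

    t: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.f.shape:
            raise ValueError("t and f must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.t[0] < 0:
            raise ValueError("time grid must be nonnegative")
        if np.any(self.f < 0):
            fmin = float(self.f.min())
            if fmin < -1e-12:
                raise ValueError(f"density has negative values (min {fmin:.3e})")
            self.f = np.clip(self.f, 0.0, None)

    @property
    def mass(self) -> float:
        return float(np.trapezoid(self.f, self.t))

    def mean(self) -> float:
        return float(np.trapezoid(self.t * self.f, self.t)) / self.mass

    def normalized(self) -> "DensityOnGrid":
        return DensityOnGrid(self.t, self.f / self.mass)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero outside the grid support."""
        return np.interp(t, self.t, self.f, left=0.0, right=0.0)


def exponential_density(rate: float, grid: np.ndarray | None = None) -> DensityOnGrid:
    """Exp(rate) waiting-time density on ``grid`` (default: grid scaled to the mean)."""
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if grid is None:
        grid = log_time_grid(1.0 / rate)
    return DensityOnGrid(grid, rate * np.exp(-rate * grid))


def kld_between_densities(f: DensityOnGrid, g: DensityOnGrid,
                          support_rel: float = 1e-12, floor: float = 1e-300,
                          t_max: float | None = None) -> float:
    """Kullback-Leibler divergence D[f||g] = int f ln(f/g) dt by trapezoid quadrature.

    The integral is restricted to the part of f's grid where f exceeds
    ``support_rel`` times its maximum, which controls tail noise in estimated
    densities; g is interpolated onto that grid.  ``t_max`` optionally caps
    the integration domain (used by the plug-in estimator to avoid comparing
    an estimated density against the unsampled tail of its reverse).
    Returns +inf (with a warning) when g carries no mass on f's support.
    """
    if f is g or (f.t.shape == g.t.shape and np.array_equal(f.t, g.t)
                  and np.array_equal(f.f, g.f)):
        return 0.0
    keep = f.f > support_rel * f.f.max()
    if t_max is not None:
        keep &= f.t <= t_max
    t = f.t[keep]
    fv = f.f[keep]
    gv = g(t)
    if np.trapezoid(gv, t) <= 0:
        warnings.warn("densities have non-overlapping supports; KLD is +inf",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    fv = np.maximum(fv, floor)
    gv = np.maximum(gv, floor)
    val = float(np.trapezoid(fv * np.log(fv / gv), t))
    # quadrature can go microscopically negative for nearly equal densities
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# jump-chain linear algebra
# ---------------------------------------------------------------------------

def visit_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary distribution R of the embedded jump chain: p R = R, sum R = 1.

    R is the long-run fraction of visits to each state.  Raises
    ReducibleChainError, naming the disconnected blocks, when the chain is not
    irreducible on its support.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    if p.shape != (n, n):
        raise ValueError("p must be square")
    colsums = p.sum(axis=0)
    if np.max(np.abs(colsums - 1.0)) > 1e-9:
        raise ValueError(f"p is not column-stochastic (column sums {colsums})")
    ncomp, labels = connected_components(csr_matrix(p > 0), directed=True,
                                         connection="strong")
    if ncomp > 1:
        blocks = [[int(i) for i in np.flatnonzero(labels == k)]
                  for k in range(ncomp)]
        raise ReducibleChainError(
            f"jump chain is reducible; strongly connected blocks (state indices): {blocks}")
    # solve (p - I) R = 0 with the normalization row appended
    a = np.vstack([p - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    r, *_ = np.linalg.lstsq(a, b, rcond=None)
    r = np.clip(r, 0.0, None)
    r /= r.sum()
    resid = float(np.max(np.abs(p @ r - r)))
    if resid > EIGVEC_RESIDUAL_TOL:
        raise RuntimeError(f"visit distribution residual {resid:.3e} exceeds tolerance")
    return r


def mean_step_time(R: np.ndarray, tau: np.ndarray) -> float:
    """Mean duration of a step, T = sum_a R_a tau_a, in seconds."""
    R = np.asarray(R, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if R.shape != tau.shape:
        raise ValueError("R and tau must share the state set")
    if np.any(tau <= 0):
        raise ValueError(f"all mean waiting times must be positive, got {tau}")
    return float(R @ tau)


def stationary_distribution(R: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Time-weighted stationary occupancy pi_a = tau_a R_a / T."""
    T = mean_step_time(R, tau)
    return np.asarray(R) * np.asarray(tau) / T


def steady_current(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Antisymmetric per-step current table J[b,a] = p[b,a] R[a] - p[a,b] R[b]."""
    p = np.asarray(p, dtype=float)
    R = np.asarray(R, dtype=float)
    m = p * R[np.newaxis, :]
    return m - m.T


# ---------------------------------------------------------------------------
# the semi-Markov model
# ---------------------------------------------------------------------------

@dataclass
class SemiMarkovModel:
    """First- or second-order semi-Markov model.

    Parameters
    ----------
    states
        State labels.  For second-order models built by decimation these are
        ``(prev, curr)`` tuples; any hashable labels are accepted.
    p
        Jump-chain matrix, ``p[b, a]`` = probability that the next jump is
        ``states[a] -> states[b]``.  Columns sum to 1, diagonal is 0.
    wtd
        Mapping ``(state_a, state_b) -> DensityOnGrid`` holding the normalized
        conditional waiting-time density psi(t | a -> b).  Only transitions
        with ``p[b, a] > 0`` need an entry.
    order
        1 or 2.  The order selects the time-reversal bookkeeping used by the
        entropy decomposition.
    reversal
        Time-reversal map on labels.  Defaults to the identity for order 1
        and to the pair swap ``(i, j) -> (j, i)`` for order 2 (supplied
        explicitly for non-tuple second-order alphabets, e.g. up/down step
        directions).
    tau
        Mean waiting time per state; computed from p and the densities when
        omitted.
    """

    states: list
    p: np.ndarray
    wtd: dict
    order: int = 1
    reversal: Mapping[Hashable, Hashable] | None = None
    tau: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        n = len(self.states)
        if self.p.shape != (n, n):
            raise ValueError("p shape does not match the state list")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        self.index = {s: i for i, s in enumerate(self.states)}
        if np.max(np.abs(self.p.sum(axis=0) - 1.0)) > STOCHASTIC_TOL:
            raise ValueError("columns of p must sum to 1 within "
                             f"{STOCHASTIC_TOL} (sums {self.p.sum(axis=0)})")
        # a state cannot jump to itself (psi_aa = 0) -- except in collapsed
        # second-order alphabets (e.g. up/down step directions), where equal
        # labels stand for distinct translated pair states
        collapsed = self.order == 2 and not all(
            isinstance(s, tuple) and len(s) == 2 for s in self.states)
        if not collapsed and np.any(np.abs(np.diag(self.p)) > 0):
            raise ValueError("diagonal of p must be zero (psi_aa = 0)")
        if np.any(self.p < 0):
            raise ValueError("p must be nonnegative")
        if self.order == 2:
            self._check_pair_chaining()
        if self.reversal is None:
            if self.order == 2 and all(isinstance(s, tuple) and len(s) == 2
                                       for s in self.states):
                self.reversal = {s: (s[1], s[0]) for s in self.states}
            else:
                self.reversal = {s: s for s in self.states}
        missing = [s for s in self.states if self.reversal.get(s) not in self.index]
        if missing:
            raise ValueError(f"reversal map must send states to states; bad: {missing}")
        self._check_densities()
        if self.tau is None:
            self.tau = self._tau_from_densities()
        else:
            self.tau = np.asarray(self.tau, dtype=float)
            implied = self._tau_from_densities()
            if np.max(np.abs(self.tau - implied)) > 1e-4 * np.max(self.tau):
                raise ValueError("tau inconsistent with the mean of the stored "
                                 f"densities: given {self.tau}, implied {implied}")

    def _check_pair_chaining(self) -> None:
        # transitions [ij] -> [jk] only: middle labels must match
        if not all(isinstance(s, tuple) and len(s) == 2 for s in self.states):
            return  # non-tuple alphabet (e.g. step directions): chaining implicit
        for a, sa in enumerate(self.states):
            for b, sb in enumerate(self.states):
                if self.p[b, a] > 0 and sa[1] != sb[0]:
                    raise ValueError(
                        f"second-order transition {sa} -> {sb} breaks pair chaining")

    def _check_densities(self) -> None:
        for (sa, sb), dens in self.wtd.items():
            if sa not in self.index or sb not in self.index:
                raise ValueError(f"wtd key ({sa}, {sb}) not in the state set")
            if abs(dens.mass - 1.0) > DENSITY_MASS_TOL:
                raise ValueError(
                    f"psi(t|{sa} -> {sb}) has mass {dens.mass:.8f}, expected 1")
        for a, sa in enumerate(self.states):
            for b, sb in enumerate(self.states):
                if self.p[b, a] > 0 and (sa, sb) not in self.wtd:
                    raise ValueError(f"missing waiting-time density for {sa} -> {sb}")

    def _tau_from_densities(self) -> np.ndarray:
        tau = np.zeros(len(self.states))
        for a, sa in enumerate(self.states):
            for b, sb in enumerate(self.states):
                if self.p[b, a] > 0:
                    tau[a] += self.p[b, a] * self.wtd[(sa, sb)].mean()
        return tau

    # -- derived stationary quantities ------------------------------------

    def visit_distribution(self) -> np.ndarray:
        return visit_distribution(self.p)

    def reversal_index(self) -> np.ndarray:
        return np.array([self.index[self.reversal[s]] for s in self.states])


@dataclass
class EPReport:
    """Entropy-production decomposition of a (semi-)Markov model or trajectory.

    All rates are in units of 1/s with k_B = 1; per-step values are obtained
    by multiplying with the mean step time ``T_step``.
    """

    S_aff: float
    S_wtd: float
    T_step: float
    R: dict
    J_per_step: dict
    wtd_terms: dict = field(default_factory=dict)
    aff_terms: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def S_kld(self) -> float:
        return self.S_aff + self.S_wtd


def _affinity_from_arrays(p: np.ndarray, R: np.ndarray, T: float,
                          rev: np.ndarray, labels: list,
                          warn_sink: list | None = None) -> tuple[float, dict]:
    """Per-time affinity rate (1/T) sum_ab p_ba R_a ln(p_ba / p_rev(a),rev(b))."""
    total = 0.0
    terms: dict = {}
    n = p.shape[0]
    for a in range(n):
        for b in range(n):
            w = p[b, a] * R[a]
            if w == 0.0:
                continue
            prev = p[rev[a], rev[b]]
            if prev == 0.0:
                msg = (f"forward transition {labels[a]} -> {labels[b]} has zero "
                       "reverse probability; affinity rate is +inf")
                warnings.warn(msg, RuntimeWarning, stacklevel=3)
                if warn_sink is not None:
                    warn_sink.append(msg)
                terms[(labels[a], labels[b])] = float("inf")
                total = float("inf")
                continue
            term = w * np.log(p[b, a] / prev) / T
            terms[(labels[a], labels[b])] = term
            total += term
    return total, terms


def affinity_entropy_rate(model: SemiMarkovModel) -> float:
    """Affinity part of the entropy production rate, in 1/s.

    First order: (1/T) sum_ab p_ba R_a ln(p_ba / p_rev(a)rev(b)); with the
    identity reversal this is the familiar current-times-log-ratio form.
    Second order the same expression runs over pair states with the pair-swap
    reversal.  Zero-probability forward terms contribute 0; a positive forward
    weight with zero reverse probability yields +inf with a warning.
    """
    R = model.visit_distribution()
    T = mean_step_time(R, model.tau)
    rev = model.reversal_index()
    total, _ = _affinity_from_arrays(model.p, R, T, rev, model.states)
    return total


def wtd_entropy_rate(model: SemiMarkovModel,
                     kld: Callable[[DensityOnGrid, DensityOnGrid], float]
                     = kld_between_densities) -> float:
    """Waiting-time part of the entropy production rate, in 1/s.

    First order: (1/T) sum_{a,b,m} p_mb p_ba R_a D[psi(t|b->m) || psi(t|~b->~a)].
    Second order (pair states already carry the history):
    (1/T) sum_{a,b} p_ba R_a D[psi(t|a->b) || psi(t|~b->~a)].
    Triplets/pairs with zero path weight contribute 0.  Raises if a needed
    reverse-path density is missing from the model.
    """
    R = model.visit_distribution()
    T = mean_step_time(R, model.tau)
    rev = model.reversal_index()
    states = model.states
    p = model.p
    n = len(states)
    cache: dict = {}
    missing: list = []

    def div(fkey, gkey) -> float:
        key = (fkey, gkey)
        if key not in cache:
            fwd = model.wtd.get(fkey)
            back = model.wtd.get(gkey)
            if fwd is None or back is None:
                missing.append(key)
                cache[key] = float("nan")
            else:
                cache[key] = kld(fwd, back)
        return cache[key]

    total = 0.0
    if model.order == 1:
        for a in range(n):
            for b in range(n):
                if p[b, a] * R[a] == 0.0:
                    continue
                for m in range(n):
                    w = p[m, b] * p[b, a] * R[a]
                    if w == 0.0:
                        continue
                    d = div((states[b], states[m]),
                            (states[rev[b]], states[rev[a]]))
                    total += w * d / T
    else:
        for a in range(n):
            for b in range(n):
                w = p[b, a] * R[a]
                if w == 0.0:
                    continue
                d = div((states[a], states[b]),
                        (states[rev[b]], states[rev[a]]))
                total += w * d / T
    if missing:
        raise ValueError("missing reverse-path waiting-time densities for: "
                         f"{sorted(set(missing), key=repr)}")
    return max(total, 0.0) if np.isfinite(total) else total


def kld_entropy_rate(model: SemiMarkovModel) -> EPReport:
    """Full KLD entropy-production report: S_kld = S_aff + S_wtd, with R, T, J."""
    R = model.visit_distribution()
    T = mean_step_time(R, model.tau)
    rev = model.reversal_index()
    warn_sink: list = []
    s_aff, aff_terms = _affinity_from_arrays(model.p, R, T, rev, model.states,
                                             warn_sink)
    s_wtd = wtd_entropy_rate(model)
    J = steady_current(model.p, R)
    jdict = {(model.states[a], model.states[b]): J[b, a]
             for a in range(len(model.states)) for b in range(len(model.states))
             if model.p[b, a] > 0 or model.p[a, b] > 0}
    return EPReport(S_aff=s_aff, S_wtd=s_wtd, T_step=T,
                    R=dict(zip(model.states, R)), J_per_step=jdict,
                    aff_terms=aff_terms, warnings=warn_sink)
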