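# Methods

## Model and decomposition

A semi-Markov (continuous-time random walk) process on discrete states is
specified by the joint densities `ψ_βα(t)` of making the jump α → β after a
dwell of length t.  Integrating out time gives the embedded jump chain
`p_βα = ∫ ψ_βα dt` (column-stochastic); normalizing gives the conditional
waiting-time density `ψ(t|α→β) = ψ_βα(t)/p_βα`.  The stationary quantities
are the visit distribution `R` (fixed point of `p`), the mean waits
`τ_α = Σ_β p_βα · mean ψ(·|α→β)`, the mean time per step `𝒯 = Σ R_α τ_α`,
the occupancy `π_α = τ_α R_α / 𝒯`, and the per-step current
`J_βα = p_βα R_α − p_αβ R_β`.

The Kullback–Leibler rate between the ensemble of stationary trajectories
and its time reverse separates exactly into a state-sequence (affinity)
part and a waiting-time part:

* order 1: `Ṡ_aff = (1/𝒯) Σ_αβ p_βα R_α ln(p_βα/p_α̃β̃)` and
  `Ṡ_WTD = (1/𝒯) Σ_αβμ p_μβ p_βα R_α D[ψ(t|β→μ) ‖ ψ(t|β̃→α̃)]`;
* order 2 (pair states `[prev, curr]`, reversal = pair swap; the time
  shift of the reversed dwell sequence turns the triplet sum into a pair
  sum): `Ṡ_WTD = (1/𝒯) Σ_αβ p_βα R_α D[ψ(t|α→β) ‖ ψ(t|β̃→α̃)]`.

`Ṡ_WTD ≥ 0` term by term; `Ṡ_aff ≥ 0` for identity/pair-swap reversals by
the log-sum inequality.  `Ṡ_KLD = Ṡ_aff + Ṡ_WTD` is a lower bound on the
physical entropy production rate, with equality for a fully observed
Markov network, where the conditional waits are exponential and
destination-independent so `Ṡ_WTD = 0` and `Ṡ_KLD` reduces to the
Schnakenberg sum `Σ_{i<j} (ω_ji π_i − ω_ij π_j) ln[(ω_ji π_i)/(ω_ij π_j)]`.

Conventions: `ω_ij` is the rate j → i (columns index the source); k_B = 1;
rates in 1/s; the force protocol tilts one observed link by
`ω_12 → ω_12 e^{βFL}`, `ω_21 → ω_21 e^{−βFL}` with F quoted in 1/(βL), so
only the product βFL matters (β = L = 1 by default).  Zero-probability
forward terms contribute 0 (`0·ln 0 = 0`); a positive forward weight whose
reverse has zero probability yields `+inf` with a warning rather than an
exception, so stalled or one-way topologies remain diagnosable.

## Exact decimation of hidden states

Lumping a connected hidden block into one label H makes the observed
dynamics second-order semi-Markov.  With `M` the hidden sub-generator
(hidden↔hidden rates, total outflow on the diagonal) and `μ` the entry
distribution fixed by the previous observed state's rates into the block,
one sojourn in H exits to observed state k at time t with density
`Σ_j [e^{tM} μ]_j ω_kj`.  Splitting probabilities `−r_k·M⁻¹μ` and
conditional means `r_k·M⁻²μ / split` are evaluated in closed form; the
density itself via the eigendecomposition of `M` (per-point matrix
exponentials as a fallback for defective blocks).  This time-domain
phase-type route is analytically identical to summing the Laplace-domain
geometric series over hidden paths.  Exits from directly observed states
stay exponential and history-free, which makes their divergence terms in
the general pair sum exactly zero — asserted numerically in the tests, not
hard-coded.

Numerics: all densities of one model share a single time grid
(8192 points: t = 0 plus a log-spaced range from 1e-6 to 50 times the
slowest scale).  At this size the trapezoid mass error is < 1e-6 and the
divergence quadrature reproduces `D[Exp(a)‖Exp(b)] = ln(a/b) + b/a − 1` to
~2e-7.  The grid auto-extends until the survival probability of the hidden
block beyond the grid end is < 1e-8.  Stored conditional densities are
renormalized to unit trapezoid mass.  Tolerances are tiered deliberately:
1e-12 for stochasticity of constructed matrices, 1e-10 for stationary
residuals, 1e-6 for density mass (quadrature-limited).

## Simulation

Trajectories are sampled with the exact Gillespie algorithm: exponential
dwell with the state's total rate, successor proportional to its rate.  All
variates are pre-drawn from one seeded numpy Generator, so runs are
bit-reproducible; an optional numba-compiled inner loop consumes the same
variate stream and yields identical output.  The initial state is drawn
from the stationary occupancy by default to avoid transient bias in step
statistics.  Dwells are stored per event so that lumping (merging
consecutive hidden sojourns, dropping the predecessor-less first pair) is
exact.

## The plug-in trajectory estimator

From a lumped pair trajectory: `R̂` from visit counts, `p̂` from transition
counts, `𝒯̂` from the mean dwell, and KDE-based divergence terms.  Three
structural choices matter:

1. **Observed-exit pooling.**  Transition probabilities out of directly
   observed states are estimated from counts pooled over the previous state
   (their exits are Poissonian and memory-free; only H carries history).
   This removes spurious `+inf` affinity estimates when a rare
   context-specific count is zero and substantially reduces the variance of
   the rare-count logarithms that dominate the affinity error under strong
   driving.
2. **Hidden-only divergence terms by default.**  The true divergence terms
   of observed-state sojourns vanish identically (see above), so their
   plug-in estimates are pure upward bias; the default estimator sums
   divergences over H-sojourns only.  The full pair sum is available with
   `wtd_terms="all"`.
3. **Reverse-support truncation.**  Each divergence quadrature is cut at
   the largest dwell observed for the reverse transition.  Beyond that
   point the reverse density estimate is pure kernel-tail extrapolation,
   and the integrand `f ln(f/ĝ)` otherwise diverges; the true contribution
   of the discarded tail is of order 1/n_reverse.

**Positive-support KDE.**  Default: Gaussian kernels in linear time,
reflected at t = 0, with Abramson square-root adaptive bandwidths
`h_i = c·h0·sqrt(ḡ/f_pilot(x_i))` (`h0` Silverman, pilot on a 512-point
grid, `c = 0.3`).  The adaptive bandwidth resolves the short-time region —
where entry-dependent sojourn laws differ most (density ratios of order
100 at t → 0 occur in the bundled network) — while keeping smooth tails.
The factor c was calibrated against exact phase-type divergences: at
2.5e4 samples the dominant divergence is recovered with ≈ −10% bias, and
the null divergence between two same-law samples is ≈ 8e-4 (well under the
0.005 self-consistency bound the tests enforce).  Sensitivity: fixed-
bandwidth reflection at c = 0.5 biases the dominant divergence ≈ −18%;
log-transform KDE (available as `method="log"`) is accurate for broad
densities but its Gaussian log-space tails collapse under the forward bulk
when forward/reverse samples are imbalanced, inflating divergences several-
fold — which is why it is not the default.  No debiasing is applied; the
plug-in divergence is biased for finite samples and the estimator is
consistent as the trajectory grows.

**Finite-sample behaviour** (measured on the bundled network at its study
conditions): at the stall force with 1e5 coarse-grained steps the relative
error of `Ṡ_KLD` is typically below 10% (limited by the ~1.3e3 samples per
rare cycle context); away from stall at F = 3 with 1e4 steps typically a
few percent (limited by the ~40 counter-current transitions whose log
enters the affinity).  At equilibrium the estimate does not vanish but sits
at a small positive bias floor (≈ 4e-3 1/s at 2e4 steps, shrinking with
length) because every term is a nonnegative plug-in divergence; replicate
estimates should be compared against this floor, not against zero noise.

## Molecular motor

Two internal states per lattice site: passive `i` and active `i'` (able to
consume chemical energy Δμ).  Internal flips at `k_s` both ways; spatial
channels attempted at `k_0` with local detailed balance, mid-point split:
passive `i ↔ i+1` rates `k_0 e^{∓βFL/2}` and active `i' ↔ i+1` rates
`k_0 e^{∓β(FL−Δμ)/2}` (upper sign up; positive F favours down-steps, Δμ
favours up-steps through the active channel).  The split of each ratio
between forward and backward rates is a load-sharing convention; any split
respecting the ratios is admissible and the choice is config-exposed.  The
lattice is embedded on a periodic ring (default 4 cells; all reported
rates are provably independent of the ring size, and the tests check 3/4/6
agree to 1e-10).

An observer sees only position.  Both up-channels land in the passive
state; a down-step lands passive or active according to the channel rates;
hence the internal state after a step depends only on the step's direction
and the observed stepping process is second-order over {up, down} with
phase-type step-time densities from the 2×2 internal block.  At Δμ = 0 the
up-up and down-down laws coincide pointwise (machine precision) for any
force, so `Ṡ_WTD = 0`: force alone cannot be detected in dwell asymmetry.
With Δμ > 0 the laws separate and `Ṡ_KLD > 0` even at the stall force,
where the affinity term is zero — dissipation without motion.

## Synthetic data and what the tests show

All test inputs are generated in-process: the four-state network with its
published rate table, seeded random 4-state networks (uniform rates
0.5–10 1/s), and Gillespie trajectories at the study conditions (1e4–1e5
coarse-grained steps for convergence checks, up to 8e6 raw jumps for the
million-sojourn phase-type law check).  The generator reproduces exactly
the renewal structure the estimator assumes: Markov dynamics, perfect
state assignment, stationary start.  Real recordings add measurement
noise, finite sampling rates (missed fast sojourns), drifting rates and
state-assignment errors, none of which are modelled; passing tests
demonstrate correctness of the estimator under the model, not robustness
to instrument effects.

## Known limitations

* The plug-in divergence is biased (typically downward after truncation,
  upward near equilibrium); no nearest-neighbour or debiased alternative is
  provided.
* One hidden block only; multiple disjoint hidden super-states are not
  supported.
* The affinity under strong driving is Poisson-limited by counter-current
  counts; errors at 1e4 steps can exceed several percent for unlucky
  trajectories.
* Odd-parity states (reversal map different from identity/pair swap) are
  supported through an explicit map but exercised only by the identity and
  swap cases.
* Time-dependent driving and multiple simultaneously tilted links are out
  of scope.
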