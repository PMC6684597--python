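# epwtd — entropy production from waiting-time distributions

`epwtd` detects and quantifies irreversibility in discrete-state time series
— even when no net current, drift or flux is visible.  It is aimed at
experiments that record a coarse state trajectory of a dissipative system
(kinetic networks with unresolved states, molecular motors whose chemistry
is hidden behind their stepping) and want a lower bound on the total entropy
production rate from that trajectory alone.

## The estimator

A partially observed Markov jump network becomes a **second-order
semi-Markov process**: the sequence of observed states `[prev, curr]` is a
Markov chain with jump matrix `p_βα`, and each transition carries a
conditional waiting-time density `ψ(t | α → β)` that remembers how the
current state was entered.  The Kullback–Leibler rate between stationary
trajectories and their time reverses then splits exactly as

```
Ṡ_KLD = Ṡ_aff + Ṡ_WTD ≤ Ṡ
Ṡ_aff = (1/𝒯) Σ_αβ p_βα R_α ln( p_βα / p_α̃β̃ )
Ṡ_WTD = (1/𝒯) Σ_αβ p_βα R_α D[ ψ(t|α→β) ‖ ψ(t|β̃→α̃) ]
```

with `R` the visit distribution of the jump chain, `𝒯 = Σ R_α τ_α` the mean
time per step, and `~` the time-reversal map (pair swap).  `Ṡ_aff` is
carried by the state sequence alone and vanishes at stall; `Ṡ_WTD` is
carried by the asymmetry of conditional waiting-time densities and can stay
positive at zero current — this is the term that reveals hidden
dissipation.  Units are 1/s with k_B = 1.

The package provides

* the semi-Markov data model and the decomposition above (`semimarkov`),
* exact reference quantities for rate networks: the Schnakenberg total rate
  and the passive / informed partial single-link bounds (`markov`),
* exact decimation of hidden states into phase-type sojourn laws
  (`coarse_grain`), a Gillespie simulator (`gillespie`),
* the trajectory (plug-in) estimator with positive-support kernel density
  estimation of waiting-time densities (`estimation`),
* a two-internal-state molecular-motor model on a periodic track (`motor`),
* plain-text file formats and an `epwtd` command line (`io`, `cli`).

## Worked example

The bundled four-state kinetic network (states 3 and 4 hidden behind a
single label `H`, force applied on the observed 1–2 link):

```python
import epwtd

net = epwtd.four_state_network()
link = epwtd.ObservedLink("1", "2")
part = epwtd.Partition(observed=("1", "2"), hidden=("3", "4"))

F_stall = epwtd.find_stall_force(net, link)
print(f"stall force: {F_stall:.6f} (1/beta L)")

for F in (F_stall, 3.0):
    tilted = epwtd.apply_force(net, F, link)
    total = epwtd.schnakenberg_entropy_rate(tilted)
    s_pp = epwtd.passive_partial(tilted, epwtd.markov_steady_state(tilted), link)
    s_ip = epwtd.informed_partial(tilted, link)
    rep = epwtd.kld_entropy_rate(epwtd.decimated_pair_process(tilted, part))
    print(f"F = {F:+.3f}:  S_PP = {s_pp:.4f}  S_IP = {s_ip:.4f}  "
          f"S_aff = {rep.S_aff:.4f}  S_KLD = {rep.S_kld:.4f}  S = {total:.4f}")

from epwtd.pipeline import convergence_experiment
res = convergence_experiment(F=0.0, n_pairs=100_000, seed=0, at_stall=True)
print(f"plug-in estimate at stall: {res['estimated_S_kld']:.4f} 1/s "
      f"(analytic {res['analytic_S_kld']:.4f}, "
      f"error {res['relative_error_pct']:.1f}%)")
```

prints

```
stall force: -0.670020 (1/beta L)
F = -0.670:  S_PP = 0.0000  S_IP = -0.0000  S_aff = -0.0000  S_KLD = 0.1902  S = 196.5946
F = +3.000:  S_PP = 16.4468  S_IP = 30.6516  S_aff = 30.6516  S_KLD = 31.8717  S = 120.9715
plug-in estimate at stall: 0.1865 1/s (analytic 0.1902, error 1.9%)
```

Reading this: at the stall force the observed current is zero, so both
single-link bounds and the affinity term vanish — yet `Ṡ_KLD = 0.19 1/s`
stays strictly positive, exposing the hidden dissipation (the true total is
196.6 1/s; all of these are lower bounds).  Away from stall the hierarchy
`Ṡ_PP ≤ Ṡ_IP = Ṡ_aff ≤ Ṡ_KLD ≤ Ṡ` is visible directly.  The last line runs
the full simulate → lump → estimate pipeline on 10⁵ coarse-grained steps
and recovers the analytic rate to a few percent.

The same pipeline is available from the shell:

```sh
epwtd fixture fig3 -o net.yaml
epwtd simulate net.yaml -n 300000 --seed 1 --force -0.67002 -o traj.tsv
epwtd lump traj.tsv --observed 1,2 --hidden 3,4 -o pairs.tsv
epwtd estimate pairs.tsv -o report.json
epwtd motor-sweep --dmus 0,5,10 --at-stall -o motor.tsv
```

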