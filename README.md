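# fflnoise

Noise reduction and signal transduction in isolated and coupled
feed-forward loop (FFL) motifs, modeled as post-translational
activation/inactivation reaction networks.

## The problem

Signaling pathways must filter stochastic fluctuations out of their inputs
while still responding to genuine changes.  Feed-forward loops — three-node
motifs in which X regulates the output Z both directly and through an
intermediate Y — are classic candidates for this job, and in real pathways
they rarely act alone: two FFLs often couple at the input layer (one signal
driving two X nodes, *minp*) or at the intermediate layer (one X driving two
Y nodes, *mint*).  `fflnoise` systematically compares every sign assignment
(coherent types c1–c4, incoherent i1–i4), every admissible AND/OR gate
combination, both one-step and two-step (multisite-like) modification
schemes, and all pairwise couplings — 84 models in the default catalog —
on a common footing:

* each protein node is a conserved pool of 60 molecules converted between
  inactive and active forms by mass-action catalysis (activators drive the
  forward conversion, inhibitors the reverse; default rates
  k1 = k2 = k3 = 1, kp = 10, kpp = 40, ka = 5);
* the input S is a super-Poissonian birth/autocatalysis/death process with
  Fano factor d/(d−b) = 1.83 at every mean, stepped through a five-plateau
  staircase (1→2→…→6→…→1) of 20 time units per plateau;
* noise is quantified by the output's coefficient of variation,
  %CV = 100·σ/μ, and signal transduction by the least-squares slope of
  mean output against mean input across the five ascending plateaus.

Moments come from the linear noise approximation (LNA) — the macroscopic
rate equation dμ/dt = S·a(μ) coupled to the covariance equation
dΣ/dt = JΣ + ΣJᵀ + D with D = S·diag(a)·Sᵀ — validated by exact Gillespie
simulation and, on shrunken instances, by direct solution of the chemical
master equation.

## Worked example

```python
from fflnoise import build_model, integrate, staircase

crn = build_model("c1-OR")            # all-activating isolated FFL
result = integrate(crn, staircase())  # LNA through the full staircase
```

Printing the end-of-plateau output statistics
(`examples/staircase_timecourse.py`) gives

```
 t_end  phase      S   Z mean   Z sd   Z %CV
    20     up   1.00    38.88   5.66   14.55
    60     up   3.00    42.45   4.21    9.92
   120     up   6.00    44.20   3.64    8.23
   180   down   3.00    42.45   4.21    9.92
   220   down   1.00    38.88   5.66   14.55
```

The output tracks the staircase without visible delay, its noise falls as
the input rises, and its %CV (8–15%) sits far below the input's
(55% at level 6): the c1-OR loop is a noise filter.  Sweeping the whole
catalog (`examples/rank_catalog.py`) ranks the coupled, all-activating
`c1c1-minp-OR` as the best noise reducer (output %CV 6.5 at input 6) and
shows a negative %CV–slope correlation (−0.63): good noise reducers tend
to be good signal transducers.

More narrative scripts live in `examples/`: motif enumeration, input
calibration, engine cross-validation (CME/SSA/LNA) and the gate/coupling/
scheme comparisons.  A thin CLI wraps the same functions:

```bash
fflnoise enumerate --family minp        # catalog as JSON lines
fflnoise build --model c1c1-minp-OR     # compiled reaction network
fflnoise run --family isolated          # LNA sweep with ranking table
fflnoise reproduce fig6                 # AND-vs-OR gate comparison
fflnoise selftest                       # built-in oracle checks
```

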