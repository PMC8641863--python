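"""Drive one motif through the full staircase and follow its moments.

The LNA propagates the mean vector and covariance matrix jointly through
the piecewise-constant protocol (five plateau levels up, then mirrored
down); the output table shows how the active output pool Z_a tracks the
input while compressing its relative noise.
"""

import numpy as np

from fflnoise import build_model, integrate, staircase

crn = build_model("c1-OR")
result = integrate(crn, staircase())
iz = result.species_names.index("Z_a")
i_s = result.species_names.index("S")

print(f"model {crn.model_id}: {crn.n_species} species, {crn.n_reactions} reactions")
print(f"\n{'t_end':>6} {'phase':>6} {'S':>6} {'Z mean':>8} {'Z sd':>6} {'Z %CV':>7}")
for level, phase, state in result.plateau_end_states():
    sd = np.sqrt(state.sigma[iz, iz])
    cv = 100 * sd / state.mu[iz]
    print(f"{state.t:6.0f} {phase:>6} {state.mu[i_s]:6.2f} "
          f"{state.mu[iz]:8.2f} {sd:6.2f} {cv:7.2f}")
print(
    "\nThe output mean rises and falls with the staircase without visible\n"
    "delay, and its %CV (single digits) sits far below the input's ~55-96%:\n"
    "the all-activating FFL acts as a noise filter."
)
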