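"""Exact stochastic simulation (Gillespie direct method) of compiled models.

The SSA samples the chemical master equation's jump process exactly, so its
ensemble statistics are the ground truth against which the linear noise
approximation is validated.  The staircase protocol enters as a
piecewise-constant basal production rate of the input species: when the next
tentative jump would cross a plateau boundary the clock advances to the
boundary and the waiting time is redrawn under the new rates, which is exact
for time-inhomogeneous chains with piecewise-constant propensities.

The inner loop is compiled with numba (a pure-python fallback keeps the
module importable without it); trajectories are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crn import CRNModel, monomial_matrix, stoichiometry
from .input_signal import InputProtocol

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class Trajectory:
    """States of one SSA realization sampled on a fixed time grid."""

    model_id: str
    seed: int
    species_names: list[str]
    sample_times: np.ndarray  # (nt,)
    states: np.ndarray  # (nt, n_species), integer counts


@dataclass(frozen=True)
class EnsembleStats:
    """Per-plateau moments of an SSA ensemble.

    Statistics are computed inside the final fraction of each plateau
    (equilibrated window); standard errors come from the spread of the
    per-replicate window statistics, replicates being independent.
    """

    model_id: str
    species_names: list[str]
    plateau_levels: np.ndarray  # (n_plateau,)
    plateau_phase: list[str]
    mean: np.ndarray  # (n_plateau, n_species)
    var: np.ndarray
    se_mean: np.ndarray
    se_var: np.ndarray
    n_trajectories: int
    base_seed: int


@njit(cache=False)
def _ssa_kernel(x0, stoich_t, expo, rates, birth_idx, seg_end, seg_basal, sample_times, seed):
    """Direct-method SSA through piecewise-constant segments.

    stoich_t: (n_r, n_s) per-reaction state updates; expo: (n_r, n_s) 0/1
    exponents of the propensity monomials; seg_end/seg_basal: segment right
    edges and the birth rate that applies up to each edge.
    """
    np.random.seed(seed)
    n_r, n_s = stoich_t.shape
    x = x0.copy()
    out = np.empty((sample_times.shape[0], n_s), dtype=np.int64)
    t = 0.0
    i_seg = 0
    i_samp = 0
    t_final = seg_end[-1]
    while True:
        # propensities at current state
        total = 0.0
        props = np.empty(n_r)
        for j in range(n_r):
            a = rates[j] if j != birth_idx else seg_basal[i_seg]
            for s in range(n_s):
                if expo[j, s] == 1:
                    a *= x[s]
            props[j] = a
            total += a
        if total <= 0.0:
            # absorbing until the next boundary
            t_next = seg_end[i_seg]
        else:
            t_next = t + (-np.log(np.random.random()) / total)
        boundary = seg_end[i_seg]
        if t_next >= boundary:
            # record samples inside (t, boundary], then cross the boundary
            while i_samp < sample_times.shape[0] and sample_times[i_samp] <= boundary:
                for s in range(n_s):
                    out[i_samp, s] = x[s]
                i_samp += 1
            t = boundary
            i_seg += 1
            if t >= t_final or i_seg >= seg_end.shape[0]:
                break
            continue
        # record samples strictly before the jump
        while i_samp < sample_times.shape[0] and sample_times[i_samp] < t_next:
            for s in range(n_s):
                out[i_samp, s] = x[s]
            i_samp += 1
        # choose reaction
        r = np.random.random() * total
        acc = 0.0
        j_fire = n_r - 1
        for j in range(n_r):
            acc += props[j]
            if r < acc:
                j_fire = j
                break
        for s in range(n_s):
            x[s] += stoich_t[j_fire, s]
        t = t_next
    # any remaining samples (at exactly t_final)
    while i_samp < sample_times.shape[0]:
        for s in range(n_s):
            out[i_samp, s] = x[s]
        i_samp += 1
    return out


def _segments_arrays(crn: CRNModel, protocol: InputProtocol):
    relax = crn.input_mech.decay_rate - crn.input_mech.autocatalytic_rate
    segs = protocol.segments()
    seg_end = np.array([s[1] for s in segs])
    seg_basal = np.array([s[2] * relax for s in segs])
    return seg_end, seg_basal


def simulate(
    crn: CRNModel,
    protocol: InputProtocol,
    seed: int,
    sample_times: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """One exact SSA realization sampled at ``sample_times``.

    The initial state defaults to fully inactive pools with S at the first
    plateau's mean (rounded); the leading baseline plateau serves as the
    equilibration period.
    """
    if sample_times is None:
        sample_times = np.linspace(0.0, protocol.total_time, 2201)
    if x0 is None:
        x0 = np.rint(
            crn.default_initial_state(s0=protocol.plateaus[0])
        ).astype(np.int64)
    else:
        x0 = np.asarray(x0, dtype=np.int64)
    _validate_initial(crn, x0)
    seg_end, seg_basal = _segments_arrays(crn, protocol)
    states = _ssa_kernel(
        x0,
        np.ascontiguousarray(stoichiometry(crn).T),
        np.ascontiguousarray(monomial_matrix(crn)),
        crn.rate_vector(),
        crn.birth_index,
        seg_end,
        seg_basal,
        np.asarray(sample_times, dtype=float),
        seed,
    )
    return Trajectory(
        model_id=crn.model_id,
        seed=seed,
        species_names=crn.species_names,
        sample_times=np.asarray(sample_times, dtype=float),
        states=states,
    )


def _validate_initial(crn: CRNModel, x0: np.ndarray) -> None:
    if (x0 < 0).any():
        raise ValueError("initial state must be nonnegative")
    for forms, total in _pool_indices(crn):
        if x0[list(forms)].sum() != int(round(total)):
            raise ValueError("initial state violates a conservation total")


def _pool_indices(crn: CRNModel):
    idx = {n: i for i, n in enumerate(crn.species_names)}
    for node in crn.protein_nodes:
        yield tuple(idx[f] for f in crn.node_forms(node)), crn.params.total


def window_sample_times(protocol: InputProtocol, fraction: float = 0.1, per_window: int = 10):
    """Sample times inside the final ``fraction`` of every plateau."""
    times, owners = [], []
    for i, (t0, t1, _) in enumerate(protocol.segments()):
        w = np.linspace(t1 - fraction * (t1 - t0), t1, per_window)
        times.extend(w)
        owners.extend([i] * per_window)
    return np.array(times), np.array(owners)


def ensemble(
    crn: CRNModel,
    protocol: InputProtocol,
    n: int,
    base_seed: int,
    window_fraction: float = 0.1,
    samples_per_window: int = 10,
) -> EnsembleStats:
    """Moments of ``n`` independent replicates (seeds ``base_seed + i``)."""
    if n < 2:
        raise ValueError("need at least two replicates for standard errors")
    times, owners = window_sample_times(protocol, window_fraction, samples_per_window)
    n_seg = len(protocol.plateaus)
    n_sp = crn.n_species
    rep_mean = np.empty((n, n_seg, n_sp))
    rep_var = np.empty((n, n_seg, n_sp))
    for r in range(n):
        traj = simulate(crn, protocol, seed=base_seed + r, sample_times=times)
        for seg in range(n_seg):
            w = traj.states[owners == seg].astype(float)
            rep_mean[r, seg] = w.mean(axis=0)
            rep_var[r, seg] = w.var(axis=0, ddof=0)
    peak = int(np.argmax(protocol.plateaus))
    # total variance across the ensemble: within-replicate + between-replicate
    grand_mean = rep_mean.mean(axis=0)
    total_var = rep_var.mean(axis=0) + rep_mean.var(axis=0, ddof=0)
    # per-replicate linearized contribution to the total-variance estimator,
    # so its standard error covers the between-replicate component too
    contrib = rep_var + (rep_mean - grand_mean) ** 2
    return EnsembleStats(
        model_id=crn.model_id,
        species_names=crn.species_names,
        plateau_levels=np.array(protocol.plateaus),
        plateau_phase=["up" if i <= peak else "down" for i in range(n_seg)],
        mean=grand_mean,
        var=total_var,
        se_mean=rep_mean.std(axis=0, ddof=1) / np.sqrt(n),
        se_var=contrib.std(axis=0, ddof=1) / np.sqrt(n),
        n_trajectories=n,
        base_seed=base_seed,
    )
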