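"""Exact stationary solutions of the chemical master equation on small,
truncated state spaces.

Only shrunken instances (tiny pool totals, capped input copy number) are
tractable, but on those the CME is the exact oracle that anchors the whole
agreement chain: CME = SSA (statistically) >= LNA (approximately).  The
state space is reduced by the conservation laws — one inactive form per
protein pool is implied — and the input species is truncated at a cap whose
boundary probability mass is reported so truncation error is auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .crn import CRNModel, monomial_matrix, stoichiometry

MAX_STATES = 200_000


@dataclass(frozen=True)
class CMEResult:
    """Stationary distribution over the truncated, conservation-reduced lattice."""

    species_names: list[str]
    states: np.ndarray  # (n_states, n_species) full species counts
    probabilities: np.ndarray  # (n_states,)
    boundary_mass: float  # stationary probability of capped-species saturation

    def mean(self) -> np.ndarray:
        return self.probabilities @ self.states

    def cov(self) -> np.ndarray:
        mu = self.mean()
        centered = self.states - mu
        return (centered * self.probabilities[:, None]).T @ centered

    def marginal(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.species_names.index(species)
        vals = np.arange(self.states[:, j].max() + 1)
        pmf = np.zeros(vals.size)
        np.add.at(pmf, self.states[:, j], self.probabilities)
        return vals, pmf


def cme_stationary_small(
    crn: CRNModel,
    caps: dict[str, int],
    input_mean: float | None = None,
    boundary_tol: float = 1e-8,
) -> CMEResult:
    """Stationary CME solution on a truncated lattice.

    ``caps`` gives the maximum copy number per unconserved species (the
    input S must be capped); conserved pools are bounded by their totals
    automatically.  Transitions that would leave the box are dropped
    (reflecting truncation); the resulting stationary mass sitting on the
    S = cap boundary must stay below ``boundary_tol``.
    """
    names = crn.species_names
    idx = {n: i for i, n in enumerate(names)}
    total = int(round(crn.params.total))

    # free coordinates: capped species + all-but-one form per pool
    free: list[str] = []
    ranges: list[range] = []
    for n in names:
        if n == "S" or n in caps:
            if n not in caps:
                raise ValueError(f"unconserved species {n} needs a cap")
            free.append(n)
            ranges.append(range(caps[n] + 1))
    pool_forms = {node: crn.node_forms(node) for node in crn.protein_nodes}
    for node, forms in pool_forms.items():
        for f in forms[1:]:  # first form (inactive) is implied
            free.append(f)
            ranges.append(range(total + 1))

    rates = crn.rate_vector(
        basal_rate=None
        if input_mean is None
        else input_mean
        * (crn.input_mech.decay_rate - crn.input_mech.autocatalytic_rate)
    )

    # enumerate admissible states
    states = []
    for combo in itertools.product(*ranges):
        x = np.zeros(len(names), dtype=np.int64)
        for f, v in zip(free, combo):
            x[idx[f]] = v
        ok = True
        for node, forms in pool_forms.items():
            used = sum(x[idx[f]] for f in forms[1:])
            if used > total:
                ok = False
                break
            x[idx[forms[0]]] = total - used
        if ok:
            states.append(x)
    states = np.array(states)
    if states.shape[0] > MAX_STATES:
        raise ValueError(f"truncated state space too large ({states.shape[0]} states)")

    key_cols = [idx[f] for f in free]
    index_of = {tuple(s[key_cols]): i for i, s in enumerate(states)}

    S = stoichiometry(crn)
    E = monomial_matrix(crn)
    cap_vec = np.full(len(names), np.iinfo(np.int64).max, dtype=np.int64)
    for n, c in caps.items():
        cap_vec[idx[n]] = c

    rows, cols, vals = [], [], []
    diag = np.zeros(states.shape[0])
    for i, x in enumerate(states):
        for j in range(crn.n_reactions):
            a = rates[j]
            for s_i in np.nonzero(E[j])[0]:
                a *= x[s_i]
            if a <= 0.0:
                continue
            target = x + S[:, j]
            if (target < 0).any() or (target > cap_vec).any():
                continue  # reflecting truncation at the cap
            k = index_of.get(tuple(target[key_cols]))
            if k is None:  # pragma: no cover - pool bound, cannot happen
                continue
            rows.append(k)
            cols.append(i)
            vals.append(a)
            diag[i] += a
    n_states = states.shape[0]
    Q = sparse.coo_matrix(
        (vals + list(-diag), (rows + list(range(n_states)), cols + list(range(n_states)))),
        shape=(n_states, n_states),
    ).tocsr()

    # stationary distribution: Q p = 0, sum p = 1 (replace one balance row)
    A = Q.tolil()
    A[0, :] = 1.0
    b = np.zeros(n_states)
    b[0] = 1.0
    p = spsolve(A.tocsr(), b)
    p = np.maximum(p, 0.0)
    p /= p.sum()

    boundary = 0.0
    for n, c in caps.items():
        boundary += p[states[:, idx[n]] == c].sum()
    if boundary > boundary_tol:
        raise ValueError(
            f"truncation too tight: boundary mass {boundary:.2e} exceeds {boundary_tol:.0e}"
        )
    return CMEResult(
        species_names=list(names),
        states=states,
        probabilities=p,
        boundary_mass=float(boundary),
    )
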