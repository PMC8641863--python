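"""Linear noise approximation: time-dependent means and covariances.

The LNA propagates the macroscopic rate equation for the mean vector mu
jointly with a Lyapunov-type equation for the covariance Sigma,

    d mu   / dt = S a(mu)
    d Sigma/ dt = J Sigma + Sigma J^T + D,

where S is the stoichiometry matrix, a the propensity vector, J the drift
Jacobian and D = S diag(a) S^T the diffusion matrix.  For the linear
submodels used here as oracles (the input species; an unregulated two-state
pool) these moments are exact.

Conserved pools make J singular, so stationary covariances are solved on
the stoichiometric subspace: one inactive form per protein node is
eliminated through its conservation law and the Lyapunov equation is solved
in the reduced coordinates, which pins the conserved directions to exactly
zero variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_lyapunov

from .crn import CRNModel, monomial_matrix, stoichiometry
from .input_signal import InputProtocol

#: Variance tolerance for conserved combinations and PSD checks.
PSD_TOL = 1e-7


@dataclass(frozen=True)
class MomentState:
    """Mean vector and covariance matrix at one time point."""

    t: float
    mu: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class LNAResult:
    """Moments of one model along the full staircase protocol."""

    model_id: str
    species_names: list[str]
    protocol: InputProtocol
    times: np.ndarray  # (nt,)
    mu: np.ndarray  # (nt, n)
    sigma: np.ndarray  # (nt, n, n)

    def at(self, t: float) -> MomentState:
        i = int(np.argmin(np.abs(self.times - t)))
        return MomentState(self.times[i], self.mu[i], self.sigma[i])

    def plateau_end_states(self) -> list[tuple[float, str, MomentState]]:
        """(plateau mean, phase up/down, end-of-plateau moments) per segment."""
        out = []
        peak = int(np.argmax(self.protocol.plateaus))
        for i, (_, t_end, level) in enumerate(self.protocol.segments()):
            out.append((level, "up" if i <= peak else "down", self.at(t_end)))
        return out


# ---------------------------------------------------------------------------
# local LNA ingredients
# ---------------------------------------------------------------------------


def drift(crn: CRNModel, x: np.ndarray, rates: np.ndarray | None = None) -> np.ndarray:
    """Macroscopic rate of change S a(x) (propensities evaluated at real x)."""
    a = _propensity_fast(crn, np.asarray(x, dtype=float), rates)
    return stoichiometry(crn) @ a


def jacobian(crn: CRNModel, x: np.ndarray, rates: np.ndarray | None = None) -> np.ndarray:
    """Analytic Jacobian of the drift (exact for multilinear propensities)."""
    x = np.asarray(x, dtype=float)
    S = stoichiometry(crn)
    E = monomial_matrix(crn)
    r = crn.rate_vector() if rates is None else rates
    n_r, n_s = E.shape
    dA = np.zeros((n_r, n_s))
    for j in range(n_r):
        support = np.nonzero(E[j])[0]
        for i in support:
            prod = r[j]
            for k in support:
                if k != i:
                    prod *= x[k]
            dA[j, i] = prod
    return S @ dA


def diffusion(crn: CRNModel, x: np.ndarray, rates: np.ndarray | None = None) -> np.ndarray:
    """LNA diffusion matrix S diag(a) S^T."""
    a = _propensity_fast(crn, np.asarray(x, dtype=float), rates)
    S = stoichiometry(crn)
    return (S * a) @ S.T


def _propensity_fast(crn, x, rates):
    E = monomial_matrix(crn)
    r = crn.rate_vector() if rates is None else rates.copy()
    a = r.astype(float).copy()
    for j in range(E.shape[0]):
        for i in np.nonzero(E[j])[0]:
            a[j] *= x[i]
    return a


class _CompiledLNA:
    """Pre-extracted arrays so the RHS avoids python-object overhead."""

    def __init__(self, crn: CRNModel):
        self.crn = crn
        self.S = stoichiometry(crn).astype(float)
        self.E = monomial_matrix(crn)
        self.base_rates = crn.rate_vector()
        self.birth = crn.birth_index
        self.n = crn.n_species
        # list of species-index tuples per reaction
        self.supports = [tuple(np.nonzero(row)[0]) for row in self.E]

    def rates_at(self, basal: float) -> np.ndarray:
        r = self.base_rates.copy()
        r[self.birth] = basal
        return r

    def prop(self, x: np.ndarray, rates: np.ndarray) -> np.ndarray:
        a = rates.copy()
        for j, sup in enumerate(self.supports):
            for i in sup:
                a[j] *= x[i]
        return a

    def jac(self, x: np.ndarray, rates: np.ndarray) -> np.ndarray:
        dA = np.zeros((len(self.supports), self.n))
        for j, sup in enumerate(self.supports):
            for i in sup:
                prod = rates[j]
                for k in sup:
                    if k != i:
                        prod *= x[k]
                dA[j, i] = prod
        return self.S @ dA

    def moment_rhs(self, x: np.ndarray, sigma: np.ndarray, rates: np.ndarray):
        a = self.prop(x, rates)
        f = self.S @ a
        J = self.jac(x, rates)
        D = (self.S * a) @ self.S.T
        dS = J @ sigma + sigma @ J.T + D
        return f, dS


# ---------------------------------------------------------------------------
# conservation-reduced coordinates
# ---------------------------------------------------------------------------


def _reduction(crn: CRNModel):
    """Embedding x = E y + c eliminating one inactive form per node.

    Returns (independent indices, E, c): P x = y with P the row selection of
    the independent species, and P E = I.
    """
    names = crn.species_names
    drop = {f"{node}_i" for node in crn.protein_nodes}
    indep = [i for i, n in enumerate(names) if n not in drop]
    n, m = len(names), len(indep)
    E = np.zeros((n, m))
    c = np.zeros(n)
    col_of = {i: j for j, i in enumerate(indep)}
    for i, name in enumerate(names):
        if name not in drop:
            E[i, col_of[i]] = 1.0
        else:
            node = name[:-2]
            c[i] = crn.params.total
            for form in crn.node_forms(node):
                if form != name:
                    E[i, col_of[names.index(form)]] = -1.0
    return indep, E, c


# ---------------------------------------------------------------------------
# stationary moments (fast path for per-plateau statistics)
# ---------------------------------------------------------------------------


def stationary(
    crn: CRNModel, input_mean: float, relax_time: float = 400.0
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary mean and covariance at a fixed input plateau.

    The deterministic fixed point is found by relaxing the rate equation and
    polishing with a root finder in conservation-reduced coordinates; the
    covariance solves the continuous Lyapunov equation on the stoichiometric
    subspace, so conserved combinations carry exactly zero variance.
    """
    comp = _CompiledLNA(crn)
    basal = input_mean * (crn.input_mech.decay_rate - crn.input_mech.autocatalytic_rate)
    rates = comp.rates_at(basal)
    indep, E, c = _reduction(crn)
    P = np.zeros((len(indep), crn.n_species))
    for j, i in enumerate(indep):
        P[j, i] = 1.0

    x0 = crn.default_initial_state(s0=input_mean)
    sol = solve_ivp(
        lambda t, x: comp.S @ comp.prop(np.maximum(x, 0.0), rates),
        (0.0, relax_time),
        x0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-10,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"relaxation failed for {crn.model_id}")
    x_relaxed = sol.y[:, -1]

    def f_red(y):
        return P @ (comp.S @ comp.prop(E @ y + c, rates))

    root = optimize.root(f_red, P @ x_relaxed, method="hybr", tol=1e-12)
    if not root.success:  # pragma: no cover
        raise RuntimeError(f"fixed-point search failed for {crn.model_id}")
    mu = E @ root.x + c
    if (mu < -1e-9).any():  # pragma: no cover
        raise RuntimeError(f"negative stationary mean for {crn.model_id}")

    J = comp.jac(mu, rates)
    a = comp.prop(mu, rates)
    D = (comp.S * a) @ comp.S.T
    J_red = P @ J @ E
    D_red = P @ D @ P.T
    sigma_red = solve_continuous_lyapunov(J_red, -D_red)
    sigma_red = 0.5 * (sigma_red + sigma_red.T)
    sigma = E @ sigma_red @ E.T
    _check_psd(sigma, crn.model_id)
    return mu, sigma


def _check_psd(sigma: np.ndarray, model_id: str) -> None:
    eigs = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
    if eigs.min() < -PSD_TOL * max(1.0, eigs.max()):
        raise RuntimeError(
            f"covariance of {model_id} lost positive semidefiniteness "
            f"(min eigenvalue {eigs.min():.3e})"
        )


# ---------------------------------------------------------------------------
# time-dependent integration through the staircase
# ---------------------------------------------------------------------------


def integrate(
    crn: CRNModel,
    protocol: InputProtocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    points_per_segment: int = 21,
) -> LNAResult:
    """Propagate (mu, Sigma) through the piecewise-constant staircase.

    The state carries over across plateau boundaries (the solver restarts,
    the moments do not reset); the initial condition is the stationary state
    of the first plateau, so the first segment is already equilibrated.
    """
    comp = _CompiledLNA(crn)
    n = crn.n_species
    iu = np.triu_indices(n)

    def pack(mu, sigma):
        return np.concatenate([mu, sigma[iu]])

    def unpack(y):
        mu = y[:n]
        sigma = np.zeros((n, n))
        sigma[iu] = y[n:]
        sigma = sigma + np.triu(sigma, 1).T
        return mu, sigma

    mech = crn.input_mech
    relax = mech.decay_rate - mech.autocatalytic_rate
    mu0, sigma0 = stationary(crn, protocol.plateaus[0])
    y = pack(mu0, sigma0)

    times, mus, sigmas = [], [], []
    for t0, t1, level in protocol.segments():
        rates = comp.rates_at(level * relax)

        def rhs(t, yv):
            mu, sigma = unpack(yv)
            f, dS = comp.moment_rhs(mu, sigma, rates)
            return pack(f, dS)

        t_eval = np.linspace(t0, t1, points_per_segment)
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval
        )
        if not sol.success:
            raise RuntimeError(
                f"LNA integration failed for {crn.model_id} on segment {t0}-{t1}"
            )
        for k in range(sol.t.size):
            mu_k, sigma_k = unpack(sol.y[:, k])
            times.append(sol.t[k])
            mus.append(mu_k)
            sigmas.append(0.5 * (sigma_k + sigma_k.T))
        y = sol.y[:, -1]

    mu_arr = np.array(mus)
    if (mu_arr < -1e-6).any():
        raise RuntimeError(f"negative means along the trajectory of {crn.model_id}")
    result = LNAResult(
        model_id=crn.model_id,
        species_names=crn.species_names,
        protocol=protocol,
        times=np.array(times),
        mu=mu_arr,
        sigma=np.array(sigmas),
    )
    _check_psd(result.sigma[-1], crn.model_id)
    return result
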