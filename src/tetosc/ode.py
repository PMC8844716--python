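"""Deterministic (mean-field) counterpart of the Goodwin network.

The seven rate equations mirror the stochastic reaction set term by term:
transcription of both ORFs enters as k1*h(tetO) with the same operator
gate the SSA uses, dimerisation keeps the combinatorial form
k3*X*(X-1)/2 (rather than the continuum X^2/2) so the two models are
structurally identical, and the monomer balance carries the -2/+2
stoichiometry of dimerisation and dissociation.  The free and bound
operator equations are exact negatives of one another, so the operator
total is a conserved quantity of any solution.

This model serves as the high-copy oracle for the stochastic simulator and
for closed-form limit checks; it is integrated with an adaptive
stiff-capable solver (LSODA) at tight tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import RATE_SYMBOLS, RateParameters, SPECIES, SpeciesState

_I = {name: i for i, name in enumerate(SPECIES)}


def ode_rhs(state: np.ndarray, params: RateParameters) -> np.ndarray:
    """Time derivative (molecules/min) of the seven concentrations."""
    m_t, T, T2, O, C, m_g, G = state
    k1, k2, k3, k4, o1, o2, d1, d2, d3, d4, d5 = params.as_array()
    h = params.gate(O)
    # continuum extension of the combinatorial propensity; clamped at zero
    # because X*(X-1)/2 would turn (unphysically) negative for 0 < X < 1
    dim = k3 * T * max(T - 1.0, 0.0) / 2.0
    bind = o1 * T2 * O
    unbind = o2 * C
    return np.array([
        k1 * h - d1 * m_t,                                   # mRNA_tetR
        k2 * m_t - 2.0 * dim + 2.0 * k4 * T2 - d2 * T,       # TetR
        dim - k4 * T2 - d3 * T2 - bind + unbind,             # TetR2
        -bind + unbind + d4 * C,                             # tetO
        bind - unbind - d4 * C,                              # tetO_TetR2
        k1 * h - d1 * m_g,                                   # mRNA_eGFP
        k2 * m_g - d5 * G,                                   # eGFP
    ])


@dataclass(frozen=True)
class ContinuousTrajectory:
    """Real-valued species abundances on the same grid the SSA records on."""

    times: np.ndarray
    values: np.ndarray           # (G, 7) float, columns in SPECIES order
    params: RateParameters
    species: tuple[str, ...] = SPECIES

    def of(self, species: str) -> np.ndarray:
        return self.values[:, self.species.index(species)]


class IntegrationError(RuntimeError):
    pass


def simulate_ode(params: RateParameters, init: SpeciesState | np.ndarray,
                 t_final: float, record_interval: float = 0.5,
                 t0: float = 0.0, rtol: float = 1e-8, atol: float = 1e-10,
                 method: str = "LSODA") -> ContinuousTrajectory:
    """Integrate the rate equations and sample them on the recording grid."""
    y0 = init.as_array().astype(float) if isinstance(init, SpeciesState) else np.asarray(init, float)
    n = int(np.floor((t_final - t0) / record_interval)) + 1
    grid = t0 + record_interval * np.arange(n)
    sol = solve_ivp(
        lambda t, y: ode_rhs(y, params), (t0, t_final), y0,
        t_eval=grid, method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return ContinuousTrajectory(times=grid, values=sol.y.T.copy(), params=params)
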