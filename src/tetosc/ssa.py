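"""Gillespie Direct Method simulation of the Goodwin network.

The Direct Method is exact for the chemical master equation: at each step
one uniform pair (r1, r2) is drawn; the waiting time to the next reaction
is tau = (1/a0) * ln(1/r1) where a0 is the summed propensity, and the
reaction index k is the smallest k with sum_{j<=k} a_j >= r2*a0.  States
are recorded on a fixed grid: the value at a grid time is the state
immediately before the first reaction after that time (the right-continuous
step function sampled on the grid).  When every propensity vanishes the
state is absorbing and the remaining grid is filled with it.

The stepping loop is JIT-compiled with numba; randomness comes from
numba's per-thread NumPy legacy generator seeded once per trajectory, so a
trajectory is bit-reproducible from (network, params, config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .network import (
    ConfigurationError,
    ParameterPrior,
    RateParameters,
    ReactionNetwork,
    SPECIES,
    SpeciesState,
    build_goodwin_network,
    sample_parameters,
)

SCENARIOS = ("default_zero", "random_1_20", "all_50", "bound_start")


@dataclass(frozen=True)
class SimulationConfig:
    """Time span, recording grid, seed and starting state of one run."""

    t0: float = 0.0
    t_final: float = 1000.0
    record_interval: float = 0.5
    seed: int = 0
    initial_condition: SpeciesState | str = "default_zero"

    def __post_init__(self):
        if self.t_final <= self.t0:
            raise ConfigurationError("t_final must exceed t0")
        if self.record_interval <= 0:
            raise ConfigurationError("record_interval must be > 0")

    def grid(self) -> np.ndarray:
        n = int(math.floor((self.t_final - self.t0) / self.record_interval)) + 1
        return self.t0 + self.record_interval * np.arange(n)

    def resolve_initial(self) -> SpeciesState:
        if isinstance(self.initial_condition, SpeciesState):
            return self.initial_condition
        return initial_condition_scenarios(self.initial_condition, self.seed)


@dataclass(frozen=True)
class Trajectory:
    """Species counts on a fixed time grid, with the rates that produced them."""

    times: np.ndarray            # (G,) minutes
    counts: np.ndarray           # (G, 7) int64, columns in SPECIES order
    params: RateParameters
    species: tuple[str, ...] = SPECIES

    def of(self, species: str) -> np.ndarray:
        return self.counts[:, self.species.index(species)]


@dataclass(frozen=True)
class EnsembleResult:
    """A set of trajectories with their (independently sampled) rate sets."""

    trajectories: tuple[Trajectory, ...]
    parameters: tuple[RateParameters, ...]

    def __post_init__(self):
        if len(self.trajectories) != len(self.parameters):
            raise ConfigurationError("trajectories/parameters length mismatch")

    @property
    def n(self) -> int:
        return len(self.trajectories)


def initial_condition_scenarios(tag: str, seed: int = 0) -> SpeciesState:
    """Named starting states used in the ensemble studies.

    ``default_zero``: everything 0 except one vacant operator.
    ``random_1_20``: vacant operator; the five expressed species uniform
    integers in [1, 20].  ``all_50``: vacant operator; others 50.
    ``bound_start``: a single operator starting bound, all else 0.
    """
    if tag == "default_zero":
        return SpeciesState()
    if tag == "random_1_20":
        rng = np.random.default_rng(seed)
        vals = rng.integers(1, 21, size=5)
        return SpeciesState(
            mRNA_tetR=int(vals[0]), TetR=int(vals[1]), TetR2=int(vals[2]),
            tetO=1, tetO_TetR2=0, mRNA_eGFP=int(vals[3]), eGFP=int(vals[4]),
        )
    if tag == "all_50":
        return SpeciesState(
            mRNA_tetR=50, TetR=50, TetR2=50, tetO=1, tetO_TetR2=0,
            mRNA_eGFP=50, eGFP=50,
        )
    if tag == "bound_start":
        return SpeciesState(tetO=0, tetO_TetR2=1)
    raise ConfigurationError(
        f"unknown scenario {tag!r}; expected one of {SCENARIOS}"
    )


@njit(cache=True)
def _ssa_core(x0, stoich, kinds, rate_idx, sp_i, sp_j, rates, S, grid, seed):
    np.random.seed(seed)
    n_grid = grid.shape[0]
    n_rxn = stoich.shape[0]
    n_sp = stoich.shape[1]
    out = np.empty((n_grid, n_sp), dtype=np.int64)
    x = x0.copy()
    a = np.empty(n_rxn, dtype=np.float64)
    t = grid[0]
    gi = 0
    while gi < n_grid:
        a0 = 0.0
        for j in range(n_rxn):
            r = rates[rate_idx[j]]
            if kinds[j] == 0:  # gated source
                xo = float(x[sp_i[j]])
                if S == 0.0:
                    a[j] = r if xo >= 1.0 else 0.0
                else:
                    a[j] = r * xo / (S + xo)
            elif kinds[j] == 1:  # first order
                a[j] = r * x[sp_i[j]]
            elif kinds[j] == 2:  # homodimerisation
                xi = float(x[sp_i[j]])
                a[j] = r * xi * (xi - 1.0) / 2.0
            else:  # bimolecular
                a[j] = r * x[sp_i[j]] * x[sp_j[j]]
            a0 += a[j]
        if a0 <= 0.0:
            # absorbing state: freeze the remaining grid
            while gi < n_grid:
                for i in range(n_sp):
                    out[gi, i] = x[i]
                gi += 1
            break
        r1 = np.random.random()
        while r1 == 0.0:  # ln(1/0) undefined; probability-zero event
            r1 = np.random.random()
        r2 = np.random.random()
        while r2 == 0.0:
            r2 = np.random.random()
        tau = (1.0 / a0) * math.log(1.0 / r1)
        t_next = t + tau
        while gi < n_grid and grid[gi] < t_next:
            for i in range(n_sp):
                out[gi, i] = x[i]
            gi += 1
        if gi >= n_grid:
            break
        target = r2 * a0
        cum = 0.0
        k = n_rxn - 1
        for j in range(n_rxn):
            cum += a[j]
            if target <= cum:
                k = j
                break
        for i in range(n_sp):
            x[i] += stoich[k, i]
        t = t_next
    return out


def simulate_ssa(network: ReactionNetwork, params: RateParameters,
                 config: SimulationConfig) -> Trajectory:
    """One exact Direct Method trajectory recorded on the configured grid."""
    init = config.resolve_initial()
    init.validate()
    grid = config.grid()
    kinds, rate_idx, sp_i, sp_j = network.propensity_tables()
    counts = _ssa_core(
        init.as_array(), network.stoichiometry(), kinds, rate_idx, sp_i, sp_j,
        params.as_array(), params.S, grid.astype(float), config.seed,
    )
    return Trajectory(times=grid, counts=counts, params=params)


def run_ensemble(network: ReactionNetwork, prior: ParameterPrior,
                 config: SimulationConfig, n: int) -> EnsembleResult:
    """n trajectories, each with its own independently sampled rate set.

    Per-trajectory randomness is derived as base seed + trajectory index
    (one stream for parameter sampling, one for the SSA steps), so no two
    simulations share a parameter set and the whole ensemble is
    reproducible from the base seed.
    """
    if n < 0:
        raise ConfigurationError("ensemble size must be >= 0")
    trajectories, parameters = [], []
    for i in range(n):
        params = sample_parameters(prior, config.seed + i)
        cfg_i = SimulationConfig(
            t0=config.t0, t_final=config.t_final,
            record_interval=config.record_interval, seed=config.seed + i,
            initial_condition=config.initial_condition,
        )
        trajectories.append(simulate_ssa(network, params, cfg_i))
        parameters.append(params)
    return EnsembleResult(tuple(trajectories), tuple(parameters))


def run_replicates(network: ReactionNetwork, params: RateParameters,
                   config: SimulationConfig, n: int) -> EnsembleResult:
    """n trajectories sharing one fixed rate set (seeds base + index)."""
    if n < 0:
        raise ConfigurationError("replicate count must be >= 0")
    trajectories = []
    for i in range(n):
        cfg_i = SimulationConfig(
            t0=config.t0, t_final=config.t_final,
            record_interval=config.record_interval, seed=config.seed + i,
            initial_condition=config.initial_condition,
        )
        trajectories.append(simulate_ssa(network, params, cfg_i))
    return EnsembleResult(tuple(trajectories), tuple([params] * n))


def ensemble_mean(ensemble: EnsembleResult, species: str) -> np.ndarray:
    """Pointwise mean count of one species across all trajectories."""
    if ensemble.n == 0:
        raise ValueError("cannot average an empty ensemble")
    stack = np.stack([traj.of(species) for traj in ensemble.trajectories])
    return stack.mean(axis=0)
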