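"""Core definition of the TetR/tetO Goodwin auto-repression network.

The network is the minimal genetic oscillator: a constitutive promoter
transcribes both a repressor (TetR) and a short half-life reporter
(Ub-eGFP); TetR homodimerises and the dimer binds a single tetO operator
site immediately downstream of the promoter, shutting off transcription of
both open reading frames until the bound dimer is degraded or unbinds.
Delayed negative feedback of this kind can sustain periodic expression.

Seven molecular species are tracked (molecule counts per cell):

========  =====================================================
symbol    meaning
========  =====================================================
mRNA_tetR transcript of the tetR ORF
TetR      repressor monomer
TetR2     repressor homodimer
tetO      vacant operator site(s)
tetO_TetR2 operator bound by a TetR homodimer
mRNA_eGFP transcript of the Ub-eGFP reporter ORF
eGFP      destabilised reporter protein
========  =====================================================

Fourteen reactions (R1..R14) connect them; all are mass-action except
transcription (R1/R11), which is gated by operator occupancy, and
dimerisation (R3), which uses the combinatorial propensity k3*X*(X-1)/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: canonical species order used by every array in the package
SPECIES: tuple[str, ...] = (
    "mRNA_tetR",
    "TetR",
    "TetR2",
    "tetO",
    "tetO_TetR2",
    "mRNA_eGFP",
    "eGFP",
)
SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: canonical rate-parameter order (the order the priors table lists them in)
RATE_SYMBOLS: tuple[str, ...] = (
    "k1", "k2", "k3", "k4", "o1", "o2", "d1", "d2", "d3", "d4", "d5",
)

# propensity kinds
GATED_SOURCE = 0   # a = rate * h(tetO)      (transcription)
FIRST_ORDER = 1    # a = rate * X_i
DIMERISATION = 2   # a = rate * X_i * (X_i - 1) / 2
BIMOLECULAR = 3    # a = rate * X_i * X_j


class InvalidStateError(ValueError):
    """A species count is negative or violates operator conservation."""


class ConfigurationError(ValueError):
    """A prior, scenario tag or option is malformed."""


@dataclass(frozen=True)
class SpeciesState:
    """Molecule counts of the seven species (non-negative integers)."""

    mRNA_tetR: int = 0
    TetR: int = 0
    TetR2: int = 0
    tetO: int = 1
    tetO_TetR2: int = 0
    mRNA_eGFP: int = 0
    eGFP: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=np.int64)

    @classmethod
    def from_array(cls, x) -> "SpeciesState":
        return cls(**{s: int(x[i]) for i, s in enumerate(SPECIES)})

    @property
    def operator_copies(self) -> int:
        """Total operator sites, free plus bound; conserved by the network."""
        return self.tetO + self.tetO_TetR2

    def validate(self, operator_copies: int | None = None) -> None:
        x = self.as_array()
        if (x < 0).any():
            bad = SPECIES[int(np.argmin(x))]
            raise InvalidStateError(f"negative count for species {bad!r}")
        if operator_copies is not None and self.operator_copies != operator_copies:
            raise InvalidStateError(
                f"tetO + tetO_TetR2 = {self.operator_copies}, "
                f"expected {operator_copies}"
            )


@dataclass(frozen=True)
class RateParameters:
    """The eleven reaction rates plus the optional Hill constant S.

    Units: first-order rates in 1/min; the bimolecular rates k3 and o1 in
    1/(molecule*min); S in molecules.  With ``S == 0`` transcription uses the
    switch gate h(tetO) = 1 if tetO >= 1 else 0; with ``S > 0`` the literal
    Hill form h(tetO) = tetO / (S + tetO).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    o1: float
    o2: float
    d1: float
    d2: float
    d3: float
    d4: float
    d5: float
    S: float = 0.0

    def __post_init__(self):
        for sym in RATE_SYMBOLS:
            if getattr(self, sym) < 0:
                raise ConfigurationError(f"rate {sym} must be >= 0")
        if self.S < 0:
            raise ConfigurationError("Hill constant S must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in RATE_SYMBOLS], dtype=float)

    def gate(self, tetO: float) -> float:
        """Transcription gate h(tetO): switch limit, or Hill when S > 0."""
        if self.S == 0.0:
            return 1.0 if tetO >= 1 else 0.0
        return tetO / (self.S + tetO)


# The priors table prints the k1 range as "U(0.18 min^-1, .054 mol^-1 min^-1)"
# - bounds inverted and units inconsistent.  Normalised reading: both bounds
# in min^-1 with a dropped leading zero, i.e. U(0.018, 0.054).
_K1_PRINTED = (0.18, 0.054)
_K1_NORMALISED = (0.018, 0.054)

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k1": _K1_NORMALISED,
    "k2": (0.01, 0.03),
    "k3": (0.007, 0.02),
    "k4": (0.0005, 0.0015),
    "o1": (0.009, 0.027),
    "o2": (0.00005, 0.00015),
    "d1": (0.008, 0.026),
    "d2": (0.011, 0.035),
    "d3": (0.011, 0.035),
    "d4": (0.011, 0.035),
}

#: eGFP decay measured directly; alternate faster-decay scenario 0.020 1/min
D5_DEFAULT = 0.004
D5_FAST = 0.020


@dataclass(frozen=True)
class ParameterPrior:
    """Independent uniform priors for the ten sampled rates plus fixed d5.

    ``bounds`` maps each sampled rate symbol to its (lower, upper) range;
    ``fixed`` holds non-sampled rates (by default only d5).  ``S`` is the
    Hill constant passed through to the sampled :class:`RateParameters`.
    """

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    fixed: Mapping[str, float] = field(default_factory=lambda: {"d5": D5_DEFAULT})
    S: float = 0.0

    def __post_init__(self):
        seen = set(self.bounds) | set(self.fixed)
        if seen != set(RATE_SYMBOLS):
            missing = set(RATE_SYMBOLS) - seen
            extra = seen - set(RATE_SYMBOLS)
            raise ConfigurationError(
                f"prior must cover exactly the 11 rates; missing={sorted(missing)}"
                f" extra={sorted(extra)}"
            )
        for sym, (lo, hi) in self.bounds.items():
            if not (0 < lo <= hi):
                raise ConfigurationError(
                    f"prior bounds for {sym} inverted or non-positive: ({lo}, {hi})"
                )

    def midpoint(self) -> RateParameters:
        """Mid-range value of every sampled rate; handy as a fixed reference set."""
        vals = {sym: 0.5 * (lo + hi) for sym, (lo, hi) in self.bounds.items()}
        vals.update(self.fixed)
        return RateParameters(S=self.S, **vals)


def default_prior(d5: float = D5_DEFAULT, S: float = 0.0) -> ParameterPrior:
    """The published sampling ranges, with the k1 range normalised.

    The printed k1 range is self-contradictory (inverted bounds, mixed
    units); it is normalised here to U(0.018, 0.054) 1/min and a warning is
    logged recording that normalisation.
    """
    logger.warning(
        "k1 prior printed as U(%g, %g) with inconsistent units; "
        "normalised to U(%g, %g) 1/min",
        *_K1_PRINTED, *_K1_NORMALISED,
    )
    return ParameterPrior(fixed={"d5": d5}, S=S)


def sample_parameters(prior: ParameterPrior, seed: int) -> RateParameters:
    """Draw one rate set from the prior (uniform, independent per rate).

    Deterministic given ``seed``; rates are drawn in the canonical
    :data:`RATE_SYMBOLS` order so the stream is reproducible.
    """
    rng = np.random.default_rng(seed)
    vals: dict[str, float] = {}
    for sym in RATE_SYMBOLS:
        if sym in prior.bounds:
            lo, hi = prior.bounds[sym]
            vals[sym] = float(rng.uniform(lo, hi))
        else:
            vals[sym] = float(prior.fixed[sym])
    return RateParameters(S=prior.S, **vals)


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: stoichiometry plus a propensity rule."""

    rid: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    kind: int
    rate_symbol: str

    def net_change(self, species: str) -> int:
        return self.products.get(species, 0) - self.reactants.get(species, 0)


@dataclass(frozen=True)
class ReactionNetwork:
    """The fixed 14-reaction network with array views for the simulators."""

    reactions: tuple[Reaction, ...]

    def __post_init__(self):
        if len(self.reactions) != 14:
            raise ConfigurationError("the Goodwin network has exactly 14 reactions")

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometry matrix, shape (14, 7), int64."""
        S = np.zeros((len(self.reactions), len(SPECIES)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for sp, n in rxn.reactants.items():
                S[j, SPECIES_INDEX[sp]] -= n
            for sp, n in rxn.products.items():
                S[j, SPECIES_INDEX[sp]] += n
        return S

    def propensity_tables(self):
        """(kinds, rate_idx, sp_i, sp_j) int64 arrays driving propensity evaluation.

        ``sp_i`` is the governing species (the operator for gated sources);
        ``sp_j`` is the second species of a bimolecular reaction, else -1.
        """
        kinds = np.empty(len(self.reactions), dtype=np.int64)
        rate_idx = np.empty_like(kinds)
        sp_i = np.full_like(kinds, -1)
        sp_j = np.full_like(kinds, -1)
        for j, rxn in enumerate(self.reactions):
            kinds[j] = rxn.kind
            rate_idx[j] = RATE_SYMBOLS.index(rxn.rate_symbol)
            if rxn.kind == GATED_SOURCE:
                sp_i[j] = SPECIES_INDEX["tetO"]
            elif rxn.kind in (FIRST_ORDER, DIMERISATION):
                (sp,) = rxn.reactants.keys()
                sp_i[j] = SPECIES_INDEX[sp]
            elif rxn.kind == BIMOLECULAR:
                a, b = rxn.reactants.keys()
                sp_i[j], sp_j[j] = SPECIES_INDEX[a], SPECIES_INDEX[b]
            else:  # pragma: no cover - construction guards this
                raise ConfigurationError(f"unknown propensity kind {rxn.kind}")
        return kinds, rate_idx, sp_i, sp_j


def build_goodwin_network() -> ReactionNetwork:
    """The fixed 14-reaction TetR/tetO Goodwin network."""
    R = Reaction
    reactions = (
        R("R1", {}, {"mRNA_tetR": 1}, GATED_SOURCE, "k1"),
        R("R2", {"mRNA_tetR": 1}, {"mRNA_tetR": 1, "TetR": 1}, FIRST_ORDER, "k2"),
        R("R3", {"TetR": 2}, {"TetR2": 1}, DIMERISATION, "k3"),
        R("R4", {"TetR2": 1}, {"TetR": 2}, FIRST_ORDER, "k4"),
        R("R5", {"tetO": 1, "TetR2": 1}, {"tetO_TetR2": 1}, BIMOLECULAR, "o1"),
        R("R6", {"tetO_TetR2": 1}, {"tetO": 1, "TetR2": 1}, FIRST_ORDER, "o2"),
        R("R7", {"mRNA_tetR": 1}, {}, FIRST_ORDER, "d1"),
        R("R8", {"TetR": 1}, {}, FIRST_ORDER, "d2"),
        R("R9", {"TetR2": 1}, {}, FIRST_ORDER, "d3"),
        R("R10", {"tetO_TetR2": 1}, {"tetO": 1}, FIRST_ORDER, "d4"),
        R("R11", {}, {"mRNA_eGFP": 1}, GATED_SOURCE, "k1"),
        R("R12", {"mRNA_eGFP": 1}, {"mRNA_eGFP": 1, "eGFP": 1}, FIRST_ORDER, "k2"),
        R("R13", {"mRNA_eGFP": 1}, {}, FIRST_ORDER, "d1"),
        R("R14", {"eGFP": 1}, {}, FIRST_ORDER, "d5"),
    )
    return ReactionNetwork(reactions)


def propensities(state: SpeciesState, params: RateParameters,
                 network: ReactionNetwork | None = None) -> np.ndarray:
    """Propensity a_j of each reaction (1/min) at the given state.

    Transcription (R1/R11) fires at k1*h(tetO); dimerisation at
    k3*X*(X-1)/2; operator binding at o1*tetO*TetR2; everything else is
    first-order rate*count.
    """
    state.validate()
    if network is None:
        network = build_goodwin_network()
    x = state.as_array().astype(float)
    rates = params.as_array()
    kinds, rate_idx, sp_i, sp_j = network.propensity_tables()
    a = np.empty(network.n_reactions, dtype=float)
    for j in range(network.n_reactions):
        r = rates[rate_idx[j]]
        if kinds[j] == GATED_SOURCE:
            a[j] = r * params.gate(x[sp_i[j]])
        elif kinds[j] == FIRST_ORDER:
            a[j] = r * x[sp_i[j]]
        elif kinds[j] == DIMERISATION:
            xi = x[sp_i[j]]
            a[j] = r * xi * (xi - 1.0) / 2.0
        else:
            a[j] = r * x[sp_i[j]] * x[sp_j[j]]
    return a
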