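"""Synthetic single-cell fluorescence traces.

Emulates the derived form of the live-cell imaging data: per-cell intensity
series of 60 frames at 2-min spacing (120 min), in four phenotypes —
no signal ('absent'), gradual loss ('decreasing', modelled as exponential
photobleaching-like decay), steady signal ('constant'), and 'oscillating':
a sinusoid with ~50-min period riding on a linear growth trend with a
linearly growing amplitude envelope.  Noise is additive Gaussian clipped at
zero (intensities are non-negative); frames can be masked to emulate a cell
drifting out of focus.

The default population is the 88-cell field: 40 absent, 37 decreasing,
3 constant, 8 oscillating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import ConfigurationError
from .traces import CATEGORIES, FluorescenceTrace


@dataclass(frozen=True)
class TraceSpec:
    """Recipe for one synthetic trace.

    Units: times in minutes, intensities in arbitrary fluorescence units.
    ``decay_rate`` (1/min) only affects the decreasing phenotype.
    """

    category: str
    n_samples: int = 60
    dt: float = 2.0
    baseline: float = 100.0
    trend_slope: float = 0.2          # units/min
    period: float = 50.0              # minutes
    amplitude0: float = 20.0          # units
    amplitude_growth: float = 0.1     # units/min
    phase: float = 0.0                # radians
    noise_sd: float = 5.0             # units
    decay_rate: float = 0.01          # 1/min
    missing_indices: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.n_samples < 4:
            raise ConfigurationError("n_samples must be >= 4")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.period <= 2 * self.dt:
            raise ConfigurationError(
                f"period {self.period} must exceed twice the sampling "
                f"interval ({2 * self.dt}) to be resolvable"
            )
        for i in self.missing_indices:
            if not 0 <= i < self.n_samples:
                raise ConfigurationError(f"missing index {i} out of range")


def generate_trace(spec: TraceSpec, cell_id: str = "cell") -> FluorescenceTrace:
    """Deterministically generate one trace from its spec and seed."""
    rng = np.random.default_rng(spec.seed)
    t = spec.dt * np.arange(spec.n_samples)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_samples) if spec.noise_sd > 0 \
        else np.zeros(spec.n_samples)
    if spec.category == "oscillating":
        envelope = spec.amplitude0 + spec.amplitude_growth * t
        signal = (spec.baseline + spec.trend_slope * t
                  + envelope * np.sin(2 * np.pi * t / spec.period + spec.phase))
        values = signal + noise
    elif spec.category == "decreasing":
        values = spec.baseline * np.exp(-spec.decay_rate * t) + noise
    elif spec.category == "constant":
        values = spec.baseline + noise
    else:  # absent: only folded background noise
        values = np.abs(noise)
    values = np.clip(values, 0.0, None)
    mask = np.zeros(spec.n_samples, dtype=bool)
    if spec.missing_indices:
        mask[list(spec.missing_indices)] = True
    return FluorescenceTrace(
        cell_id=cell_id, times=t, intensities=values, missing=mask,
        category=spec.category,
    )


#: the default field of view: category -> cell count
DEFAULT_POPULATION_COUNTS = {
    "absent": 40,
    "decreasing": 37,
    "constant": 3,
    "oscillating": 8,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a whole field of cells with known (planted) phenotypes."""

    counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_COUNTS)
    )
    base: TraceSpec = field(default_factory=lambda: TraceSpec("constant"))
    seed: int = 0
    randomize_phase: bool = True

    def __post_init__(self):
        for cat, n in self.counts.items():
            if cat not in CATEGORIES:
                raise ConfigurationError(f"unknown category {cat!r}")
            if n < 0:
                raise ConfigurationError("cell counts must be >= 0")
        if sum(self.counts.values()) <= 0:
            raise ConfigurationError("population must contain at least one cell")


def generate_population(spec: PopulationSpec) -> list[FluorescenceTrace]:
    """One trace per cell, with per-cell derived seeds and true labels.

    Oscillating cells get independent uniform phases (unless disabled) to
    emulate the observed lack of synchrony between cells.  Each trace's
    true category is stored on the trace itself.
    """
    master = np.random.default_rng(spec.seed)
    traces: list[FluorescenceTrace] = []
    cell = 0
    for cat in CATEGORIES:
        for _ in range(spec.counts.get(cat, 0)):
            cell += 1
            child_seed = int(master.integers(0, 2**31 - 1))
            phase = float(master.uniform(0, 2 * np.pi)) \
                if (spec.randomize_phase and cat == "oscillating") else spec.base.phase
            cell_spec = replace(spec.base, category=cat, seed=child_seed,
                                phase=phase)
            traces.append(generate_trace(cell_spec, cell_id=f"cell{cell:02d}"))
    return traces


def plant_missing(trace: FluorescenceTrace, index: int) -> FluorescenceTrace:
    """Mask a single interior frame (at least three observed on each side).

    Emulates one frame lost to the cell falling out of focus, in the exact
    context the neighbour-mean imputation rule assumes.
    """
    n = trace.n_samples
    if not 3 <= index <= n - 4:
        raise ValueError(
            f"index {index} must lie in [3, {n - 4}] so three neighbours "
            "exist on each side"
        )
    mask = trace.missing.copy()
    mask[index] = True
    vals = trace.intensities.copy()
    return FluorescenceTrace(
        cell_id=trace.cell_id, times=trace.times, intensities=vals,
        missing=mask, category=trace.category,
    )
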