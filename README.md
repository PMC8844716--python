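# tetosc

Simulation and detection of Goodwin oscillation in a TetR/tetO
auto-repression gene network, as implemented in *Trypanosoma brucei
brucei*: a stochastic (Gillespie) and deterministic (ODE) simulator of the
network, a synthetic-data generator emulating single-cell fluorescence
imaging, and the time-series pipeline that pulls an oscillation period and
a phase-space limit cycle out of noisy per-cell intensity traces.

## The system

The Goodwin oscillator is the minimal genetic oscillator: a constitutive
promoter drives a repressor that shuts off its own transcription, giving
delayed negative feedback. Here the repressor is TetR, which homodimerises
and binds a single tetO operator downstream of the promoter; a
destabilised reporter (Ub-eGFP, half-life set by its degradation rate
d5 = 0.004 min⁻¹) sits in the same transcription unit so fluorescence
tracks promoter activity. Seven species are modelled — mRNA_tetR, TetR,
TetR₂, tetO, tetO:TetR₂, mRNA_eGFP, eGFP — connected by 14 reactions
(R1–R14) with rates k1–k4 (expression and dimer kinetics), o1/o2
(operator binding/unbinding) and d1–d5 (decay).

All reactions are mass action except:

* transcription, gated by operator occupancy: a(R1) = a(R11) = k1·h(tetO),
  with h the switch gate 𝟙[tetO ≥ 1] (or the literal Hill form
  tetO/(S+tetO) when a Hill constant S > 0 is configured);
* homodimerisation, with the combinatorial propensity
  a(R3) = k3·X(X−1)/2.

The stochastic simulator is the exact Gillespie Direct Method
(τ = ln(1/r1)/a0; reaction k chosen by the cumulative-sum rule), recorded
on a fixed grid (default 0.5 min over 1000 min). Ensembles draw each
trajectory's rates independently from uniform priors; the deterministic
counterpart integrates the matching rate equations and serves as the
high-copy oracle.

The analysis half processes per-cell fluorescence traces (60 frames at
2-min spacing): impute missing frames → moving-average filter (half-width
8) → cubic spline → subtract mean and OLS linear growth trend → period
from the tapered autocorrelation → Takens delay embedding (x_t vs x_{t+k},
k ≈ quarter period) → classify each cell as absent / decreasing /
constant / oscillating and tally the population.

## Worked example

```python
import numpy as np
import tetosc as T

# a synthetic 88-cell field of view with planted phenotypes
pop = T.generate_population(T.PopulationSpec(seed=7))
results = [T.analyze_trace(t) for t in pop]

summary = T.summarize_population([r.category for r in results])
print(summary.percentages)

periods = [r.period for r in results if r.category == "oscillating"]
print("mean period %.1f min (n=%d)" % (np.mean(periods), len(periods)))
```

prints

```
{'absent': 45.5, 'decreasing': 42.0, 'constant': 3.4, 'oscillating': 9.1}
mean period 50.6 min (n=8)
```

i.e. the four phenotypes are recovered at their planted frequencies
(40/37/3/8 of 88 cells) and the oscillating cells return the planted
50-min period. Each `AnalysisResult` also carries the fitted trend
(`trend_slope`, units/min), the embedding delay `delay_k` (samples) and
the `phase_pairs` array whose closed loop indicates a periodic limit
cycle.

The same functionality is exposed on the command line:

```sh
tetosc synth --seed 7 --out traces.csv --labels labels.csv
tetosc analyze --traces traces.csv --out analysis/
tetosc simulate --n 500 --seed 1 --out sim/          # Gillespie ensemble
tetosc export-sbml --seed 1 --out model.xml          # SBML L3 model
```

`simulate` writes a tidy `trajectories.csv` plus flat-text
`particles.txt` (the 11 sampled rates per simulation) and
`trajectories.txt` (species counts at every recorded time).

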