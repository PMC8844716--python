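# Methods

## Model

The network couples seven species through fourteen reactions. Writing
counts as [·], the deterministic rate equations are

    d[mRNA_tetR]/dt = k1·h([tetO]) − d1·[mRNA_tetR]
    d[TetR]/dt      = k2·[mRNA_tetR] − 2·k3·[TetR]([TetR]−1)/2
                      + 2·k4·[TetR2] − d2·[TetR]
    d[TetR2]/dt     = k3·[TetR]([TetR]−1)/2 − k4·[TetR2] − d3·[TetR2]
                      − o1·[TetR2][tetO] + o2·[tetO:TetR2]
    d[tetO]/dt      = −o1·[TetR2][tetO] + o2·[tetO:TetR2] + d4·[tetO:TetR2]
    d[tetO:TetR2]/dt =  o1·[TetR2][tetO] − o2·[tetO:TetR2] − d4·[tetO:TetR2]
    d[mRNA_eGFP]/dt = k1·h([tetO]) − d1·[mRNA_eGFP]
    d[eGFP]/dt      = k2·[mRNA_eGFP] − d5·[eGFP]

and the stochastic model uses the corresponding propensities. Free plus
bound operator is conserved by construction (the tetO and complex
equations are exact negatives), which the simulators verify row-wise.

**Transcription gate h.** Transcription is tied directly to whether the
operator is bound, not to repressor abundance. With a single operator
copy the default gate is the switch h = 𝟙[tetO ≥ 1]; a literal Hill form
tetO/(S+tetO) is available whenever a Hill constant S > 0 is configured.
No value of S is adopted by default because none is established for this
system; the switch is the S → 0 limit and, for tetO ∈ {0, 1}, is also
exactly linear in operator count.

**Dimerisation.** The propensity is the combinatorial k3·X(X−1)/2 with
−2/+2 monomer stoichiometry. The ODE carries the same X(X−1)/2 factor
rather than the continuum X²/2 so the two models are structurally
identical (the difference is O(1/X) and irrelevant at high copy); the
continuum factor is clamped at zero for 0 < X < 1, where X(X−1) would
otherwise turn negative and leak probability-less flux.

**Degron.** The reporter's destabilising degron has no reaction of its
own; its effect is folded into the dimer and reporter degradation rates.
Tetracycline is not a model species; dose modulation is outside the
model's scope.

## Parameters

Rates are per minute (bimolecular rates per molecule per minute). The
sampling priors are independent uniforms:

| rate | meaning                           | prior / value |
|------|-----------------------------------|---------------|
| k1   | transcription                     | U(0.018, 0.054) |
| k2   | translation                       | U(0.01, 0.03) |
| k3   | dimerisation                      | U(0.007, 0.02) |
| k4   | dimer dissociation                | U(0.0005, 0.0015) |
| o1   | operator binding                  | U(0.009, 0.027) |
| o2   | operator unbinding                | U(0.00005, 0.00015) |
| d1   | mRNA decay                        | U(0.008, 0.026) |
| d2   | monomer decay                     | U(0.011, 0.035) |
| d3   | dimer decay                       | U(0.011, 0.035) |
| d4   | bound-complex decay               | U(0.011, 0.035) |
| d5   | reporter decay                    | fixed 0.004 (alternate 0.020) |

The k1 range as published is self-contradictory (inverted bounds, mixed
units); this package normalises it to U(0.018, 0.054) min⁻¹ — reading the
upper figure as the intended magnitude and the lower as a dropped leading
zero — logs a warning saying so, and leaves the bounds configurable.

## Stochastic engine

Exact Direct Method: per step one uniform pair (r1, r2);
τ = ln(1/r1)/a0; reaction k is the smallest index with cumulative
propensity ≥ r2·a0. Zero draws of r1 or r2 are resampled (ln(1/0) and the
degenerate selection target are undefined; both are probability-zero).
Recording is right-continuous sampling: a grid time takes the state
immediately before the first reaction after it. When all propensities
vanish the state is absorbing and fills the remaining grid. A step
landing beyond the final time simply completes the grid; no partial step
is taken.

Ensembles derive per-trajectory randomness as base seed + trajectory
index — one stream for the parameter draw, one for the stepping — so no
two simulations share a rate set and every output is reproducible from
the base seed. The inner loop is numba-compiled; randomness inside it is
the per-thread NumPy legacy generator seeded once per trajectory, making
trajectories bit-reproducible.

Defaults: 1000 min span (the studied range is 500–1000 min), 0.5-min
recording (2001 points), single operator copy, start from the empty state
with one free operator. Alternative starting scenarios: expressed species
uniform in [1, 20]; all at 50; or a single bound operator.

## Deterministic integration

LSODA with rtol 1e-8, atol 1e-10, sampled on the same grid as the SSA.
Operator conservation holds along solutions to ≤1e-8 relative; linear
subsystems match their closed forms to ≤1e-6 relative. In the 100×
copy-number limit (100 operators, initial counts ×100) the SSA ensemble
mean of every species follows the ODE solution well within 5% of the
species' scale; a 20-replicate ensemble suffices because relative
fluctuations at ~5000 molecules are below 2%.

## Trace pipeline

* **Imputation.** A lone missing frame becomes the mean of up to three
  observed values on each side (the exact rule used on the real data,
  where one of 60 frames per analysed cell was lost to focus drift).
  Generalisations for synthetic stress-testing: runs of missing frames
  are linearly interpolated, ends take the nearest observed value, and
  more than 20% missing is rejected.
* **Filter.** Symmetric moving average, half-width n (default 8, i.e. the
  frame plus eight each side), with boundary truncation: out-of-range
  indices are dropped and the denominator shrinks accordingly. The
  published formula prints 1/(2k+1) for the interior denominator; it is
  implemented as 1/(2n+1) — a mean over the 2n+1 window points — since
  the printed index-dependent form is dimensionally not an average.
* **Spline.** A not-a-knot cubic interpolant of the filtered series
  provides continuous evaluation (the end condition matches the default
  of the numerical environment the original analysis used). It
  interpolates, it does not smooth further: smoothing is the filter's
  job.
* **De-trending.** Subtract the mean, then an OLS line fitted to the
  mean-free series. The result has zero mean and zero OLS slope to 1e-9
  of the data scale and the operation is idempotent.
* **Period.** The de-trended series is tapered with a Tukey window
  (cosine roll-off over the outer 25% of samples) and its sample
  autocorrelation scanned past the first non-positive lag; the maximising
  lag is refined by parabolic interpolation and converted to minutes.
  The taper is standard practice for short records and specifically
  down-weights the region the truncated filter window distorts most —
  without it the edge artifacts bias the 50-min recovery by ≈ +2 min,
  with it the planted 50-min period returns as 49.7 min. A peak below
  autocorrelation 0.2 (or a featureless series) yields "no period"
  rather than a number; if the autocorrelation never crosses zero the
  mean spacing of prominent peaks is used as a fallback.
* **Embedding.** Takens delay pairs (x_i, x_{i+k}); the default delay is
  a quarter of the estimated period (in samples), which opens the loop
  maximally — at quarter-period delay a sinusoid's pair coordinates are
  uncorrelated and trace a closed loop, the signature of a periodic limit
  cycle.
* **Classification.** The observed phenotypes were called by eye; this
  package operationalises them with explicit, configurable thresholds:
  absent if the imputed maximum is below θ_abs = 25 intensity units
  (chosen above the extreme of background noise at the generator's
  default noise level, and far below the ~100-unit signal baseline);
  oscillating if the de-trended filtered series contains three
  alternating extrema of either polarity (max–min–max or min–max–min —
  both witness a full cycle; requiring the max-first pattern misses
  records whose maxima fall at the ends) each with prominence
  ≥ θ_prom = 0.15 of the filtered range, and the de-trended range is at
  least θ_range = 0.1 of the mean signal (guards near-flat traces whose
  noise wiggles would pass a purely relative prominence test); otherwise
  decreasing if the filtered OLS decline over the record exceeds
  θ_slope = 0.5 of the filtered range; otherwise constant.
* **Tally.** Percentages are count/total rounded to one decimal place
  (the convention that reproduces 45.5 / 42.0 / 3.4 / 9.1 for the
  40/37/3/8 split of 88 cells).

## Synthetic data

The generator emulates the derived form of the live-cell imaging data —
per-cell intensity series, 60 frames at 2-min spacing — with the four
phenotypes: oscillating cells are a sinusoid of default period 50 min
with a linear growth trend (0.2 units/min) and a linearly growing
amplitude envelope (20 + 0.1·t units), matching the reported character of
the real oscillating cells; decreasing cells decay exponentially at
0.01 min⁻¹ (photobleaching-like; the observation is only "gradual
decrease"); constant cells are a flat baseline (100 units); absent cells
are folded Gaussian background. Noise is additive Gaussian (default
SD 5 units, putting the oscillation SNR at 4) clipped at zero. Phases are
randomised per cell, emulating the observed lack of synchrony.

These defaults make the pipeline testable, not the data real: the true
noise distribution, SNR and bleaching kinetics of the deposited images
are unknown, cells do not move or defocus here except through the
explicit missing-frame mask, and planted-label recovery (≥95% on the
default field) therefore bounds classifier behaviour only under this
noise model.

## Problem sizes

Test and acceptance runs use 500 replicates for the closed-form stochastic
oracles (binomial/Poisson standard errors of ~3%), 20 replicates for the
high-copy mean-field comparison, 50 trajectories for the qualitative
ensemble-mean oscillation check, and 100 traces for period-recovery
statistics — sizes at which the statistical tolerances quoted above are
comfortably resolved.

## Known limitations

* The switch gate makes transcription independent of operator copy number
  once any operator is free; the Hill form should be configured instead
  when modelling multi-copy operators with graded occupancy.
* Period estimation assumes at least ~2 cycles in the record and a
  near-uniform grid; 120-min records of periods much beyond ~55 min leave
  the autocorrelation peak poorly resolved after the wide default filter.
* The moving-average filter at half-width 8 (34-min window) strongly
  attenuates periods below ~45 min; period recovery through the full
  default pipeline is reliable in the 45–55 min band the system actually
  occupies, and the filter half-width should be reduced for faster
  oscillators.
* The ODE is a mean-field surrogate: at single-molecule copy numbers its
  solution is not the ensemble mean of the stochastic model (nonlinear
  binding and dimerisation correlate fluctuations); it is used as an
  oracle only in linear subsystems and the high-copy limit.
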