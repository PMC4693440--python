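# Methods

## Gating model

The Cav3.1 current is modeled as `I(V,t) = g_max · m(t)^p · h(t) · (V − E_rev)`
with Boltzmann steady states for the activation gate `m` (rising, parameters
`V_half_act`, `k_act`) and the availability gate `h` (falling, `V_half_inact`,
`k_inact`). Units are fixed throughout: mV, ms, nS, pA (1 nS × 1 mV = 1 pA).

Assumptions, and why they were made:

- **Activation exponent `p = 1` by default.** Peak-derived relative
  conductance is fitted with a single Boltzmann in the standard workflow, so
  the model's conductance–voltage relation is made identical to `m_inf`.
  Higher integer exponents are supported for users who want an `m^2` or
  `m^3` scheme, but they make the fitted `V_half`/`k` effective rather than
  structural parameters.
- **Linear (ohmic) driving force, no Goldman–Hodgkin–Katz rectification.**
  The reversal potential here is an *effective* `E_rev`, matching how it is
  measured: a line fit through the depolarized limb of the peak I–V. Default
  45 mV, typical for T-type currents in ~2 mM external Ca²⁺.
- **No temperature correction** (room-temperature recordings are emulated)
  and no Ca²⁺-dependent inactivation, ion accumulation, or Markov-state
  kinetics.
- **Time constants** follow a sigmoid of voltage with a floor,
  `τ(V) = τ_floor + τ_amp / (1 + exp((V − V_τ)/s_τ))`, monotonically
  non-increasing with depolarization. Defaults: `τ_m` floor 1 ms, amplitude
  9 ms; `τ_h` floor 12 ms, amplitude 50 ms; `V_τ = −60 mV`, `s_τ = 8 mV`.
  These reproduce the qualitative pattern of slower inactivation at small
  steps without asserting values that only exist in figure form; no numeric
  targets are derived from them.

Step responses are computed **analytically per segment**:
`x(t) = x_inf + (x0 − x_inf)·e^(−t/τ_x)` with the end-of-segment state (at
the full segment duration, not the last sample) carried into the next
segment, so gate trajectories are continuous across voltage transitions and
no ODE solver error enters. A forward-Euler integration serves as an
independent cross-check in the tests (< 0.1 % deviation).

## Protocols

- **Activation:** holding −60 mV (20 ms) → prepulse −100 mV (300 ms) → test
  step, one sweep per level, default −90…+30 mV in 10 mV increments, 150 ms,
  sampled at 20 kHz. The prepulse duration is configurable (300 ms default,
  500 ms equally supported — both durations circulate in protocol
  descriptions of this experiment family and the package asserts neither).
  The step range covers both the low-threshold steps used for group
  comparisons (−70/−60 mV) and the −10…+30 mV reversal-fit window; the full
  acquisition step list is a package choice.
- **Steady-state inactivation:** holding −60 mV → conditioning prepulse
  (default −120…−40 mV, 300 ms) → test step to −30 mV.
- Segment sample counts are `round(duration × rate)`; timestamps are
  left-aligned (the first sample of a segment sits at the new level).

## Synthetic data

The generator emulates the study conditions: two expression groups with
per-cell gating parameters drawn independently from normal distributions at
the published group means and SDs (wild-type n = 9: activation −57.5 ± 9.1 /
6.4 ± 2.2 mV, inactivation −79.1 ± 6.6 / 6.3 ± 1.4 mV; mutant n = 12:
−44.7 ± 6.0 / 6.2 ± 2.9 and −72.5 ± 5.5 / 7.7 ± 1.5 mV). Slope factors are
truncated at 0.5 mV and conductance at 0; no parameter covariance is
imposed (none is published). `g_max ~ N(5, 1.5) nS` and
`E_rev ~ N(45, 3) mV` are package choices in the physiological range for
whole-cell T-type currents of a few hundred pA. Recording noise is additive
white Gaussian, default SD 5 pA — a typical whole-cell baseline — optionally
low-passed with a 4th-order Butterworth at 3 kHz to mirror hardware
filtering. Capacitive transients are omitted by default.

Two synthesis modes:

- **kinetic** — full step-response simulation; peaks are then subject to
  kinetic distortion (the current peaks before `m` fully settles and after
  `h` has begun to decay).
- **idealized** — per-sweep peaks placed exactly at
  `g_max · m_inf(V)^p · h_inf(prepulse) · (V − E_rev)` under a stereotyped
  rise/decay envelope (rise 3 ms, decay 25 ms, normalized on the actual
  sample grid so the sampled extremum equals the analytic peak to machine
  precision). This mode isolates the analysis chain from kinetic bias and
  makes parameter-recovery checks deterministic.

What the generator does **not** emulate: series-resistance and space-clamp
errors, leak currents, seal instability, rundown, and liquid-junction
potentials. Passing recovery tests therefore validate the analysis chain and
the statistics, not robustness to these recording artifacts.

The family-variant generator emits an annotated variant table (database
flags, function class, per-sample zygosity, three prediction calls) for a
three-generation dominant pedigree, planting one fully segregating,
consensus-pathogenic variant; any randomly generated decoy that would
survive the full funnel is pushed into dbSNP so the planted variant is the
unique survivor by construction.

## Analysis chain

1. **Peak extraction:** signed extremum (minimum for inward current) in the
   test segment after a blanking window, default 2 ms, which excludes the
   region a capacitive transient would occupy.
2. **Reversal potential:** OLS line through the peak I–V points in
   −10…+30 mV, zero-crossing `V_rev = −intercept/slope`.
3. **Relative conductance:** `G(V) = I_peak/(V − V_rev)`, excluding points
   within 10 mV of `V_rev` (the quotient degenerates as the driving force
   vanishes), normalized by the maximum magnitude.
4. **Boltzmann fits:** nonlinear least squares with free amplitude; `k`
   bounded to [0.5, 30] mV; `V_half` initialized from the interpolated
   half-maximum crossing, `k` at 6.5 mV, amplitude at the observed maximum.
   Non-convergence or a slope landing on its bound flags the fit; flagged
   cells are excluded from group statistics and logged.
5. **Inactivation curve:** test-pulse peaks normalized to the most
   hyperpolarized prepulse (a deterministic reference; with the default
   −120 mV prepulse `h_inf ≈ 0.9985`, and the free fit amplitude absorbs the
   ~0.15 % residual).
6. **Kinetics:** single-exponential decay fit from the peak to the end of
   the step, and 10–90 % rise time with linear interpolation between
   samples; both computed only for steps carrying ≥ 5 % of the cell's
   maximal peak. If both rise-time crossings fall within one inter-sample
   interval the rise is reported as 0 (unresolvable at that sampling rate).
7. **Statistics:** two-sided Mann–Whitney U; exact null when the pooled
   sample is tie-free with n ≤ 25, otherwise the normal approximation with
   tie correction. No multiple-testing correction is applied. Group
   summaries are reported as mean ± SD (ddof = 1).

## Numerical behavior worth knowing

- **Reversal-estimation bias.** With the group-mean parameters the channel
  is > 99 % activated over −10…+30 mV and the estimated `V_rev` is within
  ~0.1 mV of truth; recovered `V_half`/`k` are then exact to < 0.05 mV.
  Cells drawn with shallow (k ≈ 10–13 mV) *and* depolarized activation leave
  the I–V measurably curved over the fit window, biasing `V_rev` by a few mV
  and the recovered activation `V_half` by up to ~3 mV. Given the true
  reversal potential (`analyze_cell(v_rev=...)`) recovery is < 0.5 mV for
  any valid parameter vector; both behaviors are pinned by tests.
- **Kinetic-mode bias.** With the default time constants the kinetic peak
  under-reports availability at strong steps, shifting recovered activation
  `V_half` by ≈ 2 mV (bounded < 3 mV in tests); the bias shrinks
  monotonically as `τ_m/τ_h` decreases and vanishes in the idealized mode.
- **Deterministic peak–amplitude ratios.** At a fixed step voltage the
  WT:mutant peak ratio equals `(m_inf·h_inf)_WT / (m_inf·h_inf)_mut`,
  independent of `g_max` and the driving force. With the published
  parameters the mutant current is ~86 % smaller at −70 mV, ~80 % at −60 mV,
  still ~27 % at −40 mV and ~7 % at −30 mV, converging below 1 % only from
  −20 mV upward. The experimental finding of "no significant difference" at
  higher depolarizations is a statement about group statistics under large
  inter-cell variability, not about equality of the deterministic means.

## Variant filtration

Funnel stages, applied in order (configurable): database exclusion
(dbSNP / 1000 Genomes / ESP6500 presence), function-class retention
(exonic nonsynonymous, stopgain, stoploss, frameshift and non-frameshift
indels, splicing; the class list is a package choice spelling out the usual
"position and function" criterion), zygosity (no affected individual
homozygous — the dominant expectation), sharing (all affected carry the
alternate allele), and in-house database exclusion. Counts after every stage
are reported; the funnel is idempotent and each stage only removes variants.
Prediction consensus requires ≥ 2 of 3 damaging calls; `unknown` counts as
not damaging. Segregation requires every affected to carry the variant and
every unaffected to lack it; individuals of unknown affection status (e.g.
below the expected onset age) are skipped and can never be discordant, while
a missing genotype on a scored sample fails conservatively and is listed.
Haplotype sharing is the maximal contiguous run of identical alleles
containing the index marker, with length measured marker-to-marker
(1-based positions, VCF convention); database membership is read from input
annotations — no live queries.

## Problem sizes

Unit and property tests run the protocols at 2 kHz sampling (idealized-mode
peaks are placed analytically, so peak-based results are rate-independent);
full-rate 20 kHz runs cover the simulator checks and the headline
parameter-recovery computation. The replicate power study uses 200 cohorts
of 9 + 12 idealized noiseless cells at 2 kHz with the exact Mann–Whitney
test. The haplotype detector is cross-checked against an exhaustive scan on
1,000 random marker panels.

## Known limitations

- The kinetics of real T-type currents include voltage-dependent activation
  delays (sigmoidal onset) that a first-order `m` gate only approximates.
- The funnel models database membership as boolean flags; allele-frequency
  thresholds are not implemented because the workflow it mirrors used
  presence/absence.
- Exome alignment, variant calling and annotation, parametric linkage
  analysis, and cell-biological assays are out of scope.
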