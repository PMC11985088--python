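# Methods

## Gating model

A channel variant is modelled as two independent two-state Markov gates in
series; the pore conducts iff both are open. The **slow gate** carries the
open probability: its stationary open fraction at a holding voltage V is
`p = k_open(V) / (k_open(V) + k_close(V))`, and the idealized `P_O` of a
long recording converges to it. The **fast (flicker) gate** switches on the
0.01–1 ms scale; its closures are (partly) faster than the recording filter,
so instead of resolved events it produces a reduced apparent open level. In
the fast-gating limit (switching rates ≫ filter cutoff) the apparent
amplitude is exactly `i_true · k_open / (k_open + k_close)`; the simulator
reproduces this limit to within 5 % and the test suite asserts it.

This is the *minimal* scheme that reproduces the two experimentally separable
phenomena — a voltage-dependent slow open probability and an apparent-
amplitude reduction at hyperpolarizing voltages — and nothing more. No
kinetic scheme beyond two states per gate, no substates, no cooperative or
stacked channels.

Rates follow a Boltzmann law `k(V) = k₀ · exp(z · V / V_T)` with
`V_T = RT/F ≈ 25.69 mV` at 25 °C. The factory `gate_rates_for(p_neg, p_pos,
k_close0)` inverts this parameterization: it returns gate parameters whose
stationary open fraction hits two prescribed values at −160 and +160 mV,
with the gating charge split symmetrically between opening and closing and
the kinetic timescale set by `k_close0` (mean open dwell at 0 mV =
`1/k_close0`). Channel variants are therefore specified by *observables*
(conductance, P_O at the voltage extremes), not by raw rate constants.

Defaults for the WT-like reference channel: `g = 174 pS`, slow-gate open
fraction 0.034 at −160 mV and 0.005 at +160 mV (a 6.8-fold inward
rectification), mean open dwell 20 ms at 0 mV — long enough that dwells are
well resolved at 5 kHz, short enough that a 30-s record holds tens of
events. The flicker gate is essentially open at positive voltages (≈ 0.995
at +160 mV) and drops to ≈ 0.55 at −160 mV on a sub-millisecond timescale,
yielding the characteristic shrinking open level under hyperpolarization.
Dwell-time constants are not constrained by published kinetics (none are
reported for this channel family at this level); they are package choices
that make the printed steady-state observables recoverable.

Conduction is Ohmic, `i_true(V) = g·(V − E_rev)` with `E_rev = 0` for
symmetric 100 mM KCl. The bilayer sign convention is kept end to end:
negative currents are inward; nothing in the pipeline flips signs.

## Acquisition physics

The conducting-level series is synthesized at `oversample_factor × fs`
(default 10 × 5 kHz), so flicker faster than the sampling rate shapes the
filtered amplitude as it would in an analog rig. Gaussian noise of sd
`noise_sd·√oversample` is added at the oversampled rate (giving ≈ `noise_sd`
in the recording bandwidth), a causal low-pass Bessel filter is applied
(default 4 poles, 1 kHz, designed with the −3 dB magnitude convention used
when specifying recording filters), and the result is decimated to `fs`.
Initial gate states are drawn from the stationary distribution, avoiding
burn-in bias; every random draw flows from a single master seed through
`numpy.random.SeedSequence.spawn`, so identical configurations give
byte-identical outputs and each voltage/genotype has an independent,
reproducible stream.

## Idealization

**Baseline.** The closed level is the dominant mode of the amplitude
histogram (these channels are mostly closed), sharpened by iterating a
±1 σ trimmed mean; for noiseless traces it is the most common exact value.
The noise sd is the median absolute deviation of first differences,
rescaled to a Gaussian sd. This diff-based estimator is robust against open
events but *underestimates* the sd of filter-correlated noise by roughly a
factor 1.5–2 at fs/cutoff = 5; in practice this only rescales the detection
threshold, and the recovery tests (below) show no resulting bias.

**Detector.** An order-p Hinkley (cumulative-sum) detector on
noise-standardized deviations toward the alternative level: the order-1
statistic is the classic cusum clipped at zero; each higher order
accumulates the one below, which concentrates evidence from brief events.
A jump fires when the order-p statistic crosses `threshold_lambda`
(default 6) and is *placed* at the most recent zero of the order-1
statistic, which removes the detection delay from the dwell boundaries;
the detector then re-arms toward the other level. Defaults `p = 4`,
`λ = 6`: order ~4 is the sweet spot for brief-event sensitivity, and 6 σ
keeps false positives far below one per minute at 5 kHz. With these
settings the recovered P_O tracks the per-realization generator truth to
< 1 % over P_O ∈ [0.005, 0.4] and SNR ∈ [5, 10] (see the recovery-grid
test).

**Open level.** Without a hint, the initial open level is the extreme
0.1 %-quantile deviation from baseline, then re-estimated from the accepted
open segments and the trace re-idealized (two-pass). Traces whose level
separation is below `λ·σ` yield an empty event table plus a warning flag —
never silently empty.

**Dead time.** Events shorter than `0.4/filter_cutoff` (0.4 ms at 1 kHz)
are unresolvable filter artefacts; they are merged into their neighbors
(shortest first), not reported. Raising the threshold on the raw detector
never increases the event count; the merge step can introduce ±2 wobbles,
which is why the monotonicity test runs with merging off.

**Amplitude.** `i_meas` is the duration-weighted mean of open-event sample
means, excluding `2·fs/cutoff` samples at each boundary (filter edges),
minus the closed level. Flicker is deliberately *not* deconvolved: `i_meas`
is the filtered, instrument-reported amplitude. Traces without a
qualifying open event report NaN (flagged), never zero — a missing
amplitude is not a zero current.

## Channel parameters

Per-voltage amplitudes and open probabilities aggregate into i/V and
P_O/V relations (mean, sample sd, n; missing amplitudes are excluded from
the i/V but their P_O kept). The conductance is the OLS slope over the
positive limb. The default fit range is 0…+100 mV; 0…+160 mV is equally
supported via `v_hi` because both conventions exist for this fit, and the
range used is recorded in every summary. The intercept is left free to
absorb baseline offsets; only the slope is `g`. `i_true` at negative
voltages is the fitted line evaluated there. Values "at −140 mV" are exact
protocol lookups — the relations are never interpolated. The global mean
P_O is the unweighted mean across protocol voltages (recording durations
vary in practice and no principled weighting exists).

## Growth model

Growth of the K⁺-uptake-deficient strain follows logistic kinetics
`OD(t) = K / (1 + (K/od₀ − 1)·e^(−rt))` from `od₀ = 0.1` toward
`K = 1.0`, with the rate saturating in the channel's time-averaged current:
`r = r_base + (r_max − r_base)·A/(A + A_half)`, where
`A = expression_factor · |activity|`. The hidden, per-genotype
`expression_factor` stands for the number of channels that actually reach
the plasma membrane — the quantity bilayer recordings cannot see.
Multiplicative log-normal noise (sd 0.05) acts per OD sample; OD values are
positive and their errors roughly proportional, which additive noise would
violate.

Defaults: `r_base = 0` (no channel, no growth — the empty-vector
phenotype), `r_max = 0.12 h⁻¹`, `A_half = 3 pA`. The half-saturation sits
near the top of the default panel's activity range (≈ 0.1–5.7 pA) so that
growth remains responsive to activity differences across the *whole*
panel; this is the regime in which a complementation assay is informative,
and the regime the decorrelation demonstration probes. The trade-off is
that the WT-like reference then reaches only ≈ 2-fold OD growth at 48 h
rather than saturating.

The decorrelation demonstration draws expression factors log-normally with
sd σ and measures the Pearson r between |activity| and the 48-h fold
change across the 20-genotype panel: at σ = 0 the median r (40 seeds) is
≈ 0.99, and it falls monotonically below 0.3 by σ = 4 — once the hidden
variable dominates, single-channel function no longer predicts growth,
which is precisely why growth assays alone cannot rank channel variants.

## Statistics

Mutant-vs-WT growth comparisons use the classical equal-variance two-sample
t-test (two-sided, p < 0.05), with Welch behind a flag; no multiple-testing
correction is applied by default (a Holm option exists) because the
screening convention for such panels is per-mutant testing. Correlations
are Pearson product-moment coefficients; zero-variance input is an error,
not r = 0. The quadrant classification compares each mutant's feature
(currents as absolute values) and growth against the WT point with strict
inequalities; exact ties are excluded with a warning, and the WT itself is
never classified. The multilinear model regresses growth on
(1, i, P_O, i·P_O) by OLS with an intercept (R² without an intercept is
not comparable across software); collinear regressors raise an error
naming the offender. All of these are cross-checked in the tests against
independent closed-form oracles (normal equations, product-moment formula,
Student-t tail probability).

## Problem sizes

Record lengths mirror bench practice scaled to a desktop: 30 s per voltage
for i/V work, 120 s single-voltage records for low-P_O open-probability
estimates, 300 s when P_O ≈ 0.005 (events are rare; the sd of a P_O
estimate scales as `P_O/√N_events`). The recovery experiments in
`singlechan.validation` use 10-seed medians. Flicker-free simulations in
the test suite drop the oversampling factor to 2, which changes nothing
when no sub-sample structure exists.

## What the generator does and does not emulate

Emulated: two-timescale gating with voltage dependence, Ohmic conduction,
band-limited Gaussian noise, the filter's amplitude attenuation of fast
gating, inward-negative sign convention, activity-driven growth with a
hidden expression variable. Not emulated: capacitive/leak artefacts,
baseline drift, 50/60-Hz pickup, multi-channel insertions, conductance
substates, lipid- or pH-dependent gating, and any mechanistic link between
a mutation's chemistry and its parameters — variants are defined purely by
their observable parameter values. Passing tests therefore demonstrate
that the *analysis chain* is unbiased under realistic recording physics,
not that real membranes hold no further surprises (drifting baselines and
multi-channel records are the usual ones).

## Known limitations

* No missed-event (dead-time) correction of dwell-time statistics; P_O is
  asymptotically unbiased but individual dwell-time distributions are
  truncated below the dead time.
* No hidden-Markov (likelihood-based) dwell analysis; the detector is a
  threshold method and needs level separation ≳ 6 estimated noise sd.
* The noise estimator assumes the dominant mode of the amplitude histogram
  is the closed level; channels with P_O > 0.5 would need the hint
  mechanism.
* The growth model is a one-dimensional caricature: real rescue depends on
  medium K⁺, pH regulation, and trafficking kinetics that a single
  expression factor only gestures at.
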