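# Methods

`tripdose` estimates what a commuter inhales during a multimodal trip, from
three ingredients: portable-monitor exposure time series collected inside
transport microenvironments, accelerometry-based inhalation rates, and
survey-derived travel-time distributions. This note documents the models,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions the results depend
on.

## Sensor processing

**Time base.** All channels are bin-averaged onto a common 10 s grid (bins
anchored at the stream's own t = 0; a bin with fewer than 50 % of its
expected native samples is reported missing). Portable photometers typically
log at 1 s and aethalometers at 10 s, so the 10 s base is the coarsest
native resolution.

**Synchronization.** Instrument clocks drift by seconds to minutes.
Per-stream integer lags are estimated by maximizing the magnitude of the
normalized cross-correlation against a reference channel (the photometer,
which has the highest signal continuity) over ±`max_lag_s` (default 120 s).
The magnitude is used because physically co-driven channels can be
anti-correlated — accelerometer counts peak while walking, exactly when
concentrations are lowest. A stream whose correlation peak falls below 0.2
is flagged "unsynchronizable" and kept at zero lag rather than shifted by a
spurious amount.

**Photometric correction.** Raw photometric PM2.5 is offset by the HEPA
zero reading and multiplied by a device-specific gravimetric calibration
factor (defaults 0.63/0.58 are typical values for the instruments emulated).

**Aethalometer loading correction.** As absorbing particles accumulate on
the filter spot, sensitivity drops. The multiplicative correction

    BC_c = BC_nc · (1 + k · ATN)

restores the signal using the logged attenuation ATN. The factor k is
estimated from two co-located devices run at different flow rates: both
filters load, but at different speeds, so the k minimizing the summed
squared difference between the two corrected series is identified by the
contrast in their ATN trajectories. The objective is quadratic in k; it is
solved by bounded one-dimensional minimization on [0, 0.1] (tolerance
1e-12), and a flat quadratic term (identical ATN trajectories) is reported
as a degeneracy with k = 0 rather than an arbitrary interior point. On
noiseless synthetic pairs the fit recovers the generating k to better than
1e-6; with 5 % independent device noise at n = 2000 it stays within a few
percent.

**Negative eBC readings.** Instantaneous micro-aethalometer readings are
noisy and can be negative. They are retained for averaging by default
because truncation at zero biases segment means upward; a floor is
configurable for consumers that require nonnegative series.

**Segmentation and summaries.** The field registry's boarding/alighting
events partition the series into half-open `[start, end)` segments; a sample
exactly on an event timestamp belongs to the later segment. Mode summaries
(n, mean, median, Q1, Q3) pool all samples of a mode; quartiles use linear
interpolation (type 7), which matters for box-plot-style outputs.

## Dose model

The inhaled dose rate of pollutant j in microenvironment i is
`D_ij = C_ij · IR_i` (µg/min; CO in mg/min). `C_ij` is the mean exposure
concentration; `IR_i` is the mean inhalation rate over that mode's samples,
because activity differs between walking and riding.

Counts→METs and METs→ventilation are both linear maps with configurable
coefficients. The defaults — METs = 1.439 + 0.000795 · counts/min, floored
at 1 MET, and IR = METs × 0.0083 m³/min — are plausible values consistent
with the published finding that accelerometer counts correlate well with
METs and ventilation; they are *not* measured constants of any specific
cohort, and the test suite pins them so a change is always deliberate.

CO is measured in ppm and dosed in mg, converted with the ideal gas law
(M = 28.01 g/mol; default 25 °C, 101.325 kPa). At a high-altitude city like
Bogotá (~74.7 kPa) the same ppm reading is ~26 % less mass per m³ — set
`co_pressure_kpa` accordingly when absolute CO doses matter; relative
comparisons are unaffected.

BRT cabins are not measured in this pipeline's sessions; their
concentrations and IR enter as an externally supplied profile (flagged
`external` in outputs). The demo's BRT profile is a synthetic stand-in with
plausible in-cabin values, not a measured record.

## Travel-time models

Stage times come from a small stage-level survey; totals come from a large
household survey. Per-stage densities are Gaussian KDEs (Silverman's rule,
0.9·min(sd, IQR/1.34)·n^(−1/5), configurable) sampled by drawing a support
point plus kernel noise and reflecting at zero — reflection preserves the
mean better than rejection for short stages. The model mean is computed in
closed form (folded-normal mixture), so expected totals can be matched
without simulation.

**Harmonization.** All stage models of a trip type are rescaled by one
common factor s_k = (survey mean total)/(sum of stage means), so the
expected total matches the household survey while the relative split of
time across stages is preserved. Matching the *mean* total (rather than the
full distribution) is a deliberate choice recorded in the catalog metadata;
the alternative (rejection sampling conditioned on the survey total's CI)
was rejected as inefficient with wide stage KDEs. `validate_totals`
checks the result: simulated totals against surveyed totals per trip type
with a two-sided Mann-Whitney test; under the null construction this test
passes (p > 0.05) in ≥ 90 % of seeds, and a +50 % shifted target is
rejected essentially always at n = 500 per arm.

## Monte Carlo trip simulation

A replication is a synthetic commuting day: N commuters (default 10,000,
configurable; the demo uses smaller N) are assigned trip types by multinomial
draw on the commuter shares, each samples its stage times and accumulates
`D_kj = Σ_i D_ij · Δt_i`. Replication means are i.i.d., so across-replication
confidence intervals use the Student t distribution. The stopping rule —
relative CI half-width ≤ 5 % for every trip-type × pollutant cell, minimum
30 and maximum 1000 replications — makes "a 95 % confidence interval is
guaranteed" operational; non-convergence at the cap is returned with a
warning flag, never silently. A trip type that receives zero commuters in a
replication is recorded as missing for that replication, not as zero dose.
Calibration: on stochastic scenarios with analytically known expected dose,
the nominal 95 % intervals cover in 93–97 % of 100 seeded runs.

Scenario comparisons (e.g. baseline Feeder–Bus vs follow-up Cable car–Bus)
are Welch t tests on the paired trip types' replication means, reporting
mean difference and percent change. Pairings are declared explicitly;
nothing is imputed for trip types absent from a campaign.

## Statistical tests

- **Mann-Whitney U** (mode comparisons): exact permutation p-value by full
  enumeration of group assignments for combined n ≤ 12 (midranks handle
  ties), tie-corrected normal approximation with continuity correction
  otherwise; two-sided by default. The exact mode matches independent
  enumeration for every partition up to combined n = 10, and the
  approximation's null rejection rate at α = 0.05 is 0.03–0.07. The test is
  documented as a test of stochastic ordering, not strictly of means.
- **Normality screen**: KS distance to a normal with the sample's own
  mean/SD. Because those parameters are estimated, the p-value uses the
  Lilliefors correction; the plain KS null would be badly conservative for
  exactly this case.
- **Welch t** for dose comparisons; degenerate zero-variance replicate sets
  are resolved explicitly (identical → t = 0, p = 1).
- Significance stars follow the * ≤ 0.05 / ** ≤ 0.01 / *** ≤ 0.001 /
  **** ≤ 0.0001 convention. No multiplicity correction by default (a Holm
  adjustment is available but off, matching the presentation style of
  single-comparison panels).

## Synthetic data: what it emulates, what it does not

The generator produces the three input families with known ground truth:

- **Sessions**: piecewise-constant true levels per microenvironment segment;
  multiplicative lognormal noise with unit mean per channel (concentrations
  are positive and right-skewed; unit mean keeps segment means unbiased);
  the photometric scale factor and HEPA offset applied inversely to the raw
  PM channel; ATN accumulated in proportion to the cumulative eBC mass drawn
  through the filter (linear accumulation from 0 — consistent with
  filter-deposit physics and sufficient to identify k) with the raw eBC
  channel attenuated by 1/(1 + k·ATN); CO quantized to its 1 ppm resolution;
  integer-sample clock offsets per instrument. The dual-device calibration
  pair shares one true aerosol series and differs in ATN accumulation rate
  (flow) and in independent device-level noise — co-located devices share
  the same inlet air, so the demo caps that independent noise at the
  instrument-precision scale (cv = 0.05) rather than the ambient cv.
- **Surveys**: the total-time survey draws trip types by share (lognormal
  totals around each type's target mean); the stage-level survey is
  allocated proportionally to share with a per-type respondent floor,
  mirroring a purposive small survey that oversamples rare trip types of
  interest.

Not emulated: device firmware formats, within-mode temporal autocorrelation
and spatial structure (each sample is conditionally independent given the
segment), ambient background drift between campaigns, GPS-derived mode
inference (the registry is authoritative), and respiratory-tract deposition
(doses are potential inhaled mass, an upper bound on deposited mass).
Passing tests therefore demonstrate correctness of the *computations* under
the stated generative assumptions, not field validity of any particular
concentration level.

The demo study (`make_demo`) sets the generator's true levels to the
magnitudes characteristic of a cable-car natural experiment — in-bus PM2.5
87.0 µg/m³ and eBC 28.2 µg/m³ versus 32.6 and 5.2 µg/m³ in cable-car cabins
(62 %/82 % lower), commuter shares dominated by feeder- or cable-to-BRT
trips, baseline two-stage totals near 125.5 min and three-stage near
137.9 min, follow-up cable-car trips near 98.4 min and others near
102.8 min — so the processed outputs land on the scales a reader of such a
study expects.

## Numerical conventions and edge cases

- Half-open segment intervals; boundary samples go to the later segment.
- Quartiles: linear interpolation (type 7) throughout.
- KDE bandwidth zero (point-mass samples) is valid for sampling and means;
  the density itself is undefined there and says so.
- The k fit refuses constant-zero streams and flags flat objectives.
- Zero-variance samples are rejected by the normality test and resolved
  explicitly by the Welch t.
- All randomness flows from one integer seed through named
  `SeedSequence`-derived substreams (sessions, surveys, validation,
  simulation), so identical configs reproduce bit-identical report bundles;
  every bundle records the config hash and seed.

## Problem sizes

Defaults are sized for interactive use: demo sessions of 2–4 segments at
10 s sampling (a few hundred samples per instrument), surveys of 400 stage
/ 3000 total respondents, and Monte Carlo runs of a few thousand commuters
× ≥30 replications, which resolve per-trip dose means to well under the 5 %
CI target. All sizes are configuration parameters and scale up linearly.

## Known limitations

- The counts→METs→ventilation coefficients are generic defaults; absolute
  dose levels inherit their uncertainty (relative comparisons across modes
  are much less sensitive).
- Harmonization matches mean totals only; if the two surveys disagree in
  distributional shape, simulated total-time *distributions* can differ
  from the household survey even after harmonization (the Mann-Whitney
  consistency check will say so).
- The lag search assumes a constant integer-sample offset per session;
  clock *drift* within a session is not modeled.
- Exact Mann-Whitney enumeration is combinatorial; above combined n = 12 the
  implementation switches to the corrected normal approximation.
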