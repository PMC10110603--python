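# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Reversal potential and intracellular chloride

### Circuit model and series-resistance correction

A voltage-clamped cell behind an access resistance R_s sees

    V_m = V_com − I_clamp · R_s,

so the membrane is progressively under-clamped as current grows. The
correction V_corr = V_com − I_clamp·R_s is applied with explicit unit
bookkeeping (pA × MΩ = 10⁻³ mV). `I_clamp` here is the **total** clamp
current at the moment of the response peak (holding + evoked), because that
is the current actually crossing R_s; using the baseline-subtracted evoked
peak instead leaves a residual error equal to the leak current's drop.
With the total current, the corrected potential equals V_m identically and
a straight-line fit of baseline-subtracted peak current against V_corr
crosses zero at the true reversal exactly — the package's noiseless
regression tests assert this to < 10⁻⁶ mV, and also assert that the
uncorrected fit is measurably biased whenever R_s > 0, which is the reason
the correction exists.

### Peak extraction

The peak GABA-evoked current is the signed extremum of (trace − baseline)
in a response window after the stimulus, with the baseline averaged over a
pre-stimulus window (default 100 ms; the measurement convention is a mean
over a quiet stretch, length not critical). Before the extremum search the
response is smoothed with a 1-ms edge-replicating boxcar (default,
switchable off): an extremum over ~10³ raw samples would otherwise ride the
upper tail of the noise. Edge replication matters — zero-padded smoothing
drags the window edges toward 0 pA and can fabricate an extremum at the
edge of a trace holding −160 pA of leak current.

### I–V fit

A straight line is fit by least squares and E_GABA = −intercept/slope. The
GABA_A I–V near reversal is approximately ohmic over the sampled range, so
a line is adequate; the fit diagnostics expose residual RMS and span so
curvature is visible. Guard rails: at least two distinct potentials; slope
(chord conductance) must be strictly positive; a zero crossing
extrapolating more than 10 mV beyond the sampled span is refused rather
than reported.

### Nernst conversion

For chloride (z = −1):

    E_Cl = (RT/F) · ln([Cl⁻]ᵢ/[Cl⁻]ₒ),   [Cl⁻]ᵢ = [Cl⁻]ₒ · e^{E·F/(RT)}.

Defaults: [Cl⁻]ₒ = 132.5 mM (the standard ACSF: 126 NaCl + 2.5 KCl +
2 × 2.0 CaCl₂), T = 303.15 K (30 °C perfusate), R and F from scipy's
CODATA tables; RT/F ≈ 26.12 mV. Both directions are exposed and are exact
inverses (round-trip tested to 10⁻⁹ relative). HCO₃⁻ permeability of the
GABA_A channel is deliberately ignored — E_GABA is treated as a pure
chloride potential, which overstates [Cl⁻]ᵢ slightly in real neurons.
Note that a population-mean [Cl⁻]ᵢ is a mean over per-cell Nernst images
and is **not** the Nernst image of the mean E_GABA (Jensen's inequality);
the package always converts per cell.

Solution chemistry: `chloride_from_solution` sums concentration ×
chloride stoichiometry over a declared salt table; an unknown salt is an
error, never a silent zero. Junction-potential correction is
corrected = measured − LJP (so a +10.5 mV LJP makes potentials more
negative, −51.1 → −61.6 mV); the returned value carries a provenance flag
and a second application raises, preventing double correction.

## Miniature PSC detection and kinetics

Detection replaces visual identification with a reproducible rule: the
polarity-aligned, median-centred, 1-ms-smoothed signal must exceed
`threshold_multiplier` (default 3.5) × a robust noise SD (1.4826 × MAD,
insensitive to the events themselves), with a 5-ms refractory separation
and a prominence gate equal to the threshold. The prominence gate is what
prevents double counting: noise maxima riding an event's decay clear the
height threshold but have only noise-sized prominence. At 5× the noise SD
on pure noise the detector fires less than once per 5-minute record.

Per event: amplitude is peak minus a local pre-onset baseline; the
10–90% rise time is interpolated on the rising limb; the decay constant is
a least-squares monoexponential started where the falling limb first drops
below 50% of the amplitude and truncated before the next event. Starting
at the peak instead biases τ upward by ~13% for a 2 ms/8 ms
difference-of-exponentials event, because near the peak the rise component
still cancels part of the decay. Events whose fit does not converge (or
returns a τ indistinguishable from a step) are flagged and excluded from
kinetic means but still count toward frequency. Frequency is reported per
second (mIPSC convention) or per minute (mEPSC convention).

The paired-pulse ratio is peak₂/peak₁ with each peak measured against a
1-ms baseline taken immediately before its own stimulus, so the residual
decay of response 1 is subtracted from response 2; with a 30-ms decay and
50-ms interval the recovered ratio is within 2% of truth. A 1-ms
post-stimulus blank excludes the stimulus artifact from the peak search.

## Tonic current

Tonic amplitude = mean(post) − mean(pre), each mean taken over event-free
segments accumulated greedily (deterministically) from the window edge
until ≥ 3 s total, excluding [onset − 5 ms, onset + 50 ms] around every
detected synaptic event. Pooled (non-contiguous) segments are accepted.
The sign convention makes a blocked inward tonic current positive. A 10-s
wash-in settle after antagonist onset is excluded by default. The
event-exclusion step is not cosmetic: with dense minis, whole-window means
are biased by the mean synaptic current (rate × per-event charge), which
the tests demonstrate on synthetic data.

## EEG spike, discharge and band-power analysis

The detection threshold is `threshold_multiplier` (default 4) × the SD of
an annotated non-REM baseline segment (≥ 10 s); sleep staging itself is out
of scope and the baseline is a user annotation. The rectified,
median-centred signal is scanned for contiguous supra-threshold excursions;
excursions separated by < 10 ms are bridged first (so noise dips inside one
slow wave cannot split it into several short "spikes"), excursions longer
than 200 ms are rejected as artifacts, and accepted excursions closer than
40 ms are merged into a single spike (largest extremum wins). Polarity is
not assumed: both signs are detected.

Discharges are maximal runs of ≥ 3 spikes with consecutive inter-spike
intervals ≤ 200 ms (the alternative reading — three spikes inside a single
200-ms window — is available via `mode="window"` but is not the default).
Discharge burden is reported as count, analyzed duration and rate per hour,
so any alternative normalization can be recomputed from the output.

Band powers: per 9-s artifact-free epoch, a Welch periodogram (2-s Hann
segments, 50% overlap) is integrated over each band with a trapezoidal rule
on the closed interval, so a PSD bin on a shared band edge contributes half
to each neighbor. Relative power divides by the sum over the four bands,
which makes the per-epoch normalization sum to 1 by construction; the
summary averages relative powers across epochs. For white noise the
expected relative powers are the bandwidth fractions (3, 5, 4, 17)/29.
Hann-window leakage across the outer 1-Hz and 30-Hz edges leaves a small
systematic deficit (~0.02 of relative power for a strongly delta-weighted
spectrum at 2-s segments); longer Welch segments reduce it and are
configurable.

## Statistics

* Discrimination index DI = (N_N − N_F)/(N_N + N_F); undefined when both
  counts are zero; antisymmetric under swapping the objects.
* Variance-ratio F test with the larger variance on top (F ≥ 1), two-sided
  p = 2 × the upper-tail probability, capped at 1 — the doubling convention
  of the common commercial packages; a one-sided option exists. A summary
  mode accepts a printed (F, df) pair so reported values can be checked
  without raw data. Monte-Carlo tests confirm the nominal type-I error at
  α = 0.05.
* Conditional t test: Welch–Satterthwaite correction is applied exactly
  when the F test is significant at the configured α (default 0.05),
  otherwise the pooled-variance test — reproducing the common
  variance-gated testing policy. ANOVA families are intentionally not
  implemented; pipelines should call standard routines.

## Synthetic generators

All generators draw from substreams derived from one root seed (label-keyed
`SeedSequence` spawns), so identical configs give byte-identical outputs
and stages can be regenerated independently.

* **I–V protocol**: leak + transient GABA conductance (difference of
  exponentials, unit peak; default rise 2 ms, decay 30 ms, peak 10 nS over
  5 nS leak) through the R_s divider, solved in closed form per sample;
  white Gaussian current noise. The command schedule must span the true
  reversal with ≥ 3 distinct potentials, else the reversal is
  unidentifiable and the generator refuses.
* **Mini trains**: homogeneous Poisson onsets, difference-of-exponentials
  transients normalized to unit peak (default 20 pA, 2 ms/8 ms — the same
  parametrization the events module measures), optional lognormal amplitude
  scatter, white Gaussian noise.
* **Tonic traces**: holding current (default −30 pA) stepping by the
  planted shift toward 0 pA after antagonist onset with first-order
  settling (τ = 0.5 s); minis superimposed before onset and suppressed
  after, emulating GABA_A blockade.
* **EEG**: background is a sum of brick-wall band-limited Gaussian noises,
  one per canonical band, scaled so the relative band powers equal the
  requested mix (verified against a full-record periodogram to ±0.02);
  planted spikes are biphasic (sharp negative lobe, σ = 8 ms, then a
  half-amplitude positive lobe), total width well under 200 ms; artifacts
  are flat-topped (Tukey-windowed) slow waves spanning > 200 ms so the
  duration-rejection rule is exercised unambiguously.

What the generators do **not** emulate: dendritic filtering and rise-time
scatter of real minis, amplitude/kinetics correlations, seizure
electrographic morphology, mains interference, electrode drift,
movement artifacts shorter than 200 ms, and non-stationary sleep/wake
spectra. Passing recovery tests on this synthetic data therefore
demonstrates correctness of the estimators under their stated model, not
robustness to every pathology of real recordings.

## Problem sizes used in validation

Monte-Carlo recovery of E_GABA/[Cl⁻]ᵢ uses 200 replicates per condition in
the test suite (100 in the acceptance script) over true reversals
{−90, −75, −60} mV × R_s {5, 15} MΩ at 5 pA noise; mini recovery uses a
300-s, 5 events/s record at 10 kHz; EEG checks use 120-s records at
2000 Hz with 50 planted spikes and two slow artifacts; the F-test
calibration uses 10⁴ null replicates at n = 27/26. These sizes give
comfortable Monte-Carlo margins for the stated tolerances.

## Known limitations

* The linear I–V model will misplace E_GABA if the sampled range extends
  into strong GABA_A rectification; the residual diagnostics flag this but
  no polynomial fallback is provided.
* The decay "time constant" is a monoexponential summary; genuinely
  bi-exponential decays are compressed into one number (the definition is
  configurable in window and start fraction, not in functional form).
* Spike duration is measured between rectified threshold crossings, which
  depends on amplitude; a half-amplitude width alternative is available.
* The tonic estimator assumes the antagonist fully blocks synaptic events
  after onset; residual post-onset events must be supplied in the event
  list or they bias the post-window mean.
* EDF reading requires the optional mne dependency; EDF writing is not
  supported.
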