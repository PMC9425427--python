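# Methods

`cracm` reimplements, as a tested pipeline, the analysis by which
channelrhodopsin-assisted circuit mapping (CRACM) experiments classify
synaptic connectivity and effective inhibition between the substantia
nigra pars reticulata (SNr) and projection-defined dopamine neurons of
the pars compacta (SNc). This note documents the models, the parameters
that matter, and the design choices made where the procedure left the
implementation open.

Units throughout: currents in pA, times in ms, voltages in mV,
resistances in MOhm, rates in Hz. Inward current is negative. Reported
cohort amplitudes are converted to nA.

## Evoked-IPSC detection and the connectivity call

An optogenetically evoked IPSC (oIPSC) is defined operationally as a
fast-onset monotonic excursion of the clamped current after the light
pulse. Two presets encode the two recording configurations:

| preset | polarity | monotonic window | search window |
|---|---|---|---|
| `minus70` (high-Cl internal, -70 mV) | inward | 1.5 ms | 20 ms |
| `minus40` (low-Cl internal, -40 mV) | outward | 0.5 ms | 5 ms |

The defining criterion is stated on data; turning it into an algorithm
required several decisions:

- **Smoothing.** Monotonicity is evaluated on a trace smoothed with a
  0.3 ms centred moving average. Strict sample-wise monotonicity at
  10 kHz would reject essentially every real event.
- **Tolerance.** Within the monotonic window the smoothed trace may dip
  below its running extremum by up to 1.0x the MAD-based noise SD of the
  pre-stimulus baseline. A tighter tolerance (0.5x) was found in
  Monte-Carlo to reject ~7% of genuine events at moderate SNR, because
  sample-to-sample noise near the flat top of the IPSC exceeds it;
  monotonicity tolerance does not control false positives here — the
  amplitude floor does.
- **Onset.** The earliest qualifying run — one whose first step moves in
  the configured polarity and whose net change over the window exceeds
  twice the smoothed-noise SD — establishes that an event exists. The
  reported onset is then localized by a threshold crossing walked back
  from the peak (5% of the excursion, or 2 smoothed-noise SDs if
  larger), because the run start itself is biased early by pre-onset
  noise at high SNR. Measured latency is accurate to one sample
  (0.1 ms) on clean traces and nearly unbiased (< 0.1 ms) at 10 pA
  noise.
- **Amplitude.** Peak location is taken on the smoothed trace within
  50 ms of onset (for trains: limited to the inter-pulse interval);
  amplitude is the raw-trace mean over +-0.3 ms around the peak minus
  the median of the 50 ms pre-stimulus baseline. With negligible noise
  (< 0.5 pA) the averaging neighbourhood narrows to one sample so the
  peak curvature is not shaved.
- **Noise floor.** Minimum amplitude defaults to 5x the MAD-based
  baseline noise SD with a 1 pA floor; configurable.

Measured operating characteristics at the simulator's standard
conditions (amplitudes >= 5x a 10 pA noise SD): sensitivity >= 95%,
mean amplitude bias < 1%, false positives < 1% per event-free sweep.

A **cell** is called connected only if events are detected in strictly
more than 50% of sweeps; cell-level amplitude and latency are means over
event-bearing sweeps. This guards against occasional miniature IPSCs
inside the search window. Exclusions: series resistance above 25 MOhm
on any sweep or drifting more than 30% relative to the first sweep;
and ChR2 contamination, i.e. a gabazine-insensitive evoked current with
mean onset latency below 1 ms (direct opsin photocurrent in the
recorded cell). A GBZ-insensitive response at longer latency is kept
but flagged for review.

## Loose-seal firing suppression

Spike detection (the original study used unspecified custom scripts) is
band-pass filtering (100-2000 Hz, 3rd-order Butterworth, zero-phase),
threshold at 6x the MAD-based noise SD of the filtered trace, one spike
per supra-threshold excursion at its extremum, 2 ms refractory.
Waveform total duration — the dopamine-neuron identity criterion
(> 2 ms) — is measured on the unfiltered mean spike waveform as the
span where |signal| exceeds 10% of the peak, after re-aligning every
spike on its positive lobe (threshold crossings land on either lobe of
a biphasic spike and would otherwise smear the average).

Firing rates are spike counts in two 3 s windows (before the train;
during the train) divided by 3. A cell is **suppressed** iff

    during_mean < baseline_mean - 2 * SD(baseline)   (strict),

with mean and SD across sweeps of the per-sweep baseline rate. The SD
across sweeps (rather than across time bins within a sweep) is the
reading consistent with how the criterion band is displayed per cell in
the source figures. Cells without tonic firing are excluded (mean
baseline below 0.5 Hz, or any baseline gap above 2 s — both thresholds
are this package's choices, since the exclusion was stated without a
criterion). Light-evoked excitation surviving gabazine (rate rising
more than 2 SDs above baseline in both conditions) excludes the cell as
ChR2-contaminated.

With fewer than 2 sweeps the SD is undefined and the cell is flagged
not classifiable.

## Train short-term plasticity

For 20 Hz / 3 s trains at -40 mV, every pulse's amplitude is measured
against a local baseline in the 2 ms immediately preceding that pulse's
light onset, because the 10 ms decay tail has not returned to baseline
at 50 ms inter-pulse intervals. The residual tail bias on the next
pulse is below 0.5%. Pulses with no detected event contribute amplitude
0 (a release failure, not a missing value), so normalized means average
over failures. Amplitudes are averaged across sweeps, then normalized
to the first pulse; the paired-pulse ratio is second/first and the
depression index last/first. A cell with no first-pulse event in any
sweep is non-responding and yields no train response. A slow current is
flagged when the median current 50-500 ms after the last pulse deviates
from the pre-train baseline median by more than 5x the baseline noise
SD (window and threshold are this package's choices).

## Cohort statistics

Percentages are integer-rounded (half away from zero) against the
number of cells tested in each assay; connectivity and suppression use
separate denominators because they come from different recordings.
Cross-circuit comparisons use the tie-corrected Kruskal-Wallis H test
(scipy), with pairwise two-sided Mann-Whitney post-hoc tests — the
exact post-hoc scheme in the source analysis was a named software
default and is artifact-defined here. Discovery control uses the
Benjamini-Krieger-Yekutieli two-stage step-up procedure at q = 0.05,
implemented from its definition: stage 1 is Benjamini-Hochberg at
q' = q/(1+q); the number of non-rejections estimates the true nulls
m0; stage 2 reruns BH at q'·m/m0. The implementation is verified
against statsmodels' independent `fdr_tsbky` on thousands of random
p-sets. Note the two-stage procedure dominates BH at level q', not at
level q: with no stage-1 rejections it stops, occasionally making fewer
discoveries than plain BH at q.

Connection probability versus soma location (AP/ML/DV, mm) is a binary
logistic regression — the two-class case of the multinomial model —
with Wald p-values and a likelihood-ratio test against the
intercept-only model. Complete or quasi-complete separation, likely at
cohort sizes of 15-30 cells, is flagged and refit with a small ridge
penalty (alpha = 1e-3); p-values are withheld in that case. Under null
simulations the per-coefficient type-I error is ~5% at alpha = 0.05.
Power to detect a location gradient depends on the spatial spread: a
slope of 2 log-odds/mm is detected with > 80% power at n = 30 only when
the coordinate SD is ~0.8 mm; at the ~0.2-0.3 mm spreads typical of a
targeted recording region, power is low — a null regression result is
weak evidence against location dependence.

## Synthetic data: what it emulates, and what it does not

The simulator produces recordings whose statistical structure matches
what the analysis assumes, with full ground truth:

- **IPSCs**: biexponential kernel (rise 0.8 ms, decay 10 ms — chosen to
  produce fast-rise events; the source reports no kinetics), unit-peak
  normalized; amplitude lognormal at cohort level (median 1.2 nA,
  log-SD 0.8, clipped to 0.08-5 nA) spanning the reported 0.1-4.5 nA
  range; onset latency per cell ~N(1.8, 0.3) ms clipped to [1, 4.5],
  jitter SD 0.2 ms per event. Inward at -70 mV, outward at -40 mV.
- **Miniature IPSCs**: Poisson at 2 Hz, 20-60 pA — small enough to be
  realistic distractors for the >50%-of-sweeps rule.
- **ChR2 contamination**: a GBZ-insensitive inward photocurrent with
  ~0.5 ms latency, sustained for the light pulse, then decaying
  (tau 2 ms) — opsin photocurrents plateau during illumination.
- **Tonic spiking**: truncated-Gaussian ISI process (CV 0.15) rendered
  with a biphasic template whose 10%-of-peak span equals the specified
  total duration (default 2.5 ms). Suppression multiplies the
  instantaneous rate inside the train window via time rescaling, which
  keeps the process stationary within each window and makes rate
  recovery exactly testable. The pacemaker rate drifts across sweeps
  (5% CV): without this nonstationarity, per-sweep baseline counts of a
  regular pacemaker are often identical, the across-sweep SD collapses
  to zero, and the strict 2-SD rule degenerates — a failure mode real
  recordings do not exhibit.
- **Short-term depression**: per-pulse multiplicative scale factors
  (default geometric, ratio 0.985 — modest depression; tests use 0.9
  for closed-form recovery).
- **Noise**: white Gaussian (default 10 pA). Series-resistance logs are
  drawn stable around 15 MOhm.

Not emulated: conductance-based neuron dynamics, dendritic filtering,
electrode drift and seal instability, temperature effects, correlated
(1/f) noise, rebound firing, or any mechanistic difference between
closed-loop and open-spiral synapses. Passing tests therefore show that
the *analysis* recovers the structure it is designed for, not that the
simulator reproduces every property of slice recordings.

Reference cohorts (`cracm.reference_cohorts`) pin per-cell ground truth
to the response counts reported for each of the six circuit
configurations; simulating them at the default high-SNR parameters and
running the pipeline reproduces every reported integer percentage.
Suppressed cells use suppression factor 0.1 (strong but incomplete
silencing); suppression cohorts are simulated with 10 loose-seal sweeps,
the standard protocol depth for that assay.

## Problem sizes and determinism

All randomness flows through integer seeds via `numpy` `SeedSequence`
spawning; identical (spec, seed) pairs give bit-identical recordings
and byte-identical pipeline outputs. Monte-Carlo validation sizes were
chosen so the whole suite completes in well under a minute per module:
250 events for detector operating characteristics, 500-1000 event-free
sweeps for false positives, 200-500 cells for suppression-classifier
recovery, 1000 random p-sets for the FDR cross-check, 300-500
replicates for regression calibration. `scripts/acceptance.py` re-runs
the full set from scratch in roughly 15 s.

## Known limitations

- Mouse-level clustering is ignored: n is cells, as in the source
  analysis; a mixed-effects treatment is out of scope.
- The -40 mV detector operates on sweep traces whose spontaneous IPSCs
  are assumed masked by the holding potential; the simulator renders
  minis at both potentials.
- Spike detection assumes the biphasic extracellular waveform dominates
  the band-passed trace; field potentials and stimulation artifacts are
  not modelled or rejected.
- The >50% rule is applied to the first pulse of a protocol; counting
  behaviour for multi-pulse protocols with partial failures is
  analysis-defined (failures count as sweeps without events only for
  the connectivity call, not for train quantification).
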