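# Methods

## The problem

Extracellular electrodes on a multi-electrode array (MEA) record spikes
(eAPs) from any sufficiently close neuron, so a single electrode's spike
train is generally a mixture of units and spike-sorting assignments cannot
be routinely validated. `axocouple` implements an alternative route to
single-neuron resolution: when one axon passes over several electrodes, its
action potentials appear on that electrode cohort in a fixed order with
fixed sub-millisecond delays and very low jitter (latency CV ≈ 0.08).  Such
*propagation signals* self-classify their spikes as coming from one neuron.
With those spike times as a clock, clusters of spikes at other electrodes
occurring at short (1–5 ms), moderately jittered latency (CV ≈ 0.5) behave
like postsynaptic responses, and are detected as *couplings*.

## Propagation-signal detection

For every ordered electrode pair (e_i, e_j) a cross-correlogram (CCG) of
Δt = t_j − t_i is built over a ±2 ms window.  Let n_all be the reference
electrode's spike count and n_win the largest count sum in any 0.5 ms
moving window of the CCG.  A ratio n_win/n_all strictly greater than 0.3
marks a consistent delay; the delay is recorded as the mean Δt inside the
maximizing window.  If every consistent partner of e_i lags it
(non-negative delays), e_i is the earliest electrode of a propagation
signal comprising e_i and its partners, sorted by delay.

Signal spike times are computed from the two anchor electrodes — e₁ (the
earliest) and e_x (the electrode with the most spikes other than e₁): each
e₁ spike is matched greedily, in time order, to its nearest unused e_x
spike within 2 ms (one co-occurrence per spike), and the signal time is the
mean of the two spike times.  Note that this timestamp is offset from the
neuron's origin-electrode spike time by the mean anchor delay; all
downstream latencies are measured in this signal-time frame.

Numerical choices: CCG bin width 0.05 ms (one sample at 20 kHz), moving
windows slid one bin at a time, ties broken toward the earliest window.
Two detections whose cohorts share ≥ 2 electrodes with delay profiles
agreeing within 0.2 ms (after offsetting) are merged, keeping the variant
with the most electrodes and earliest origin; in practice the
all-non-negative-delay rule already suppresses almost all duplicates, and
the merge handles zero-delay ties.

## Coupling detection

With a signal's spike times (or stimulation onsets) as reference events, a
one-sided CCG over 0.5–10 ms is built against every other signal and every
electrode outside the reference signal's own cohort.  With n the reference
spike count, n₁ the total CCG count and n₂ the largest count sum in any
3 ms moving window, a coupling is accepted iff

1. n₁/n > v₁ (default 0.1) — enough coupled spikes overall;
2. n₂/n₁ > v₂ (default 0.57) — counts concentrated in one peak;
3. the mean Δt inside the maximizing 3 ms window lies in [v₃, v₄]
   (defaults 1 and 5 ms) — the plausible monosynaptic latency range;
4. the sd of all Δt in the CCG is < v₅ (default 2.7 ms) — filters
   electrodes mixing several source neurons.

The coupling probability is n₂/n: the fraction of reference spikes followed
by a target spike in the CCG peak.  "Delay" in criterion 3 is the mean of
the peak-window Δt (the criterion is phrased as a bound on the *average*
latency, so the mean rather than the mode is used).  For electrode targets
a verification flag is set when the coefficient of variation of the
electrode's |amplitude| distribution exceeds v₆ (default 0.25), suggesting
multi-unit contamination worth manual review.  All vᵢ are user-settable;
rejected pairs are kept in a rejection log with the failed criterion, so
the filters can be audited.

Stimulation mode uses stimulation onsets as reference events; latency is
measured from stimulation onset and a blanking parameter (default 1.5 ms)
raises the lower CCG bound, since no voltage is usable during blanking.

The reverse (presynaptic-input) analysis asks, for each candidate input,
what fraction of postsynaptic signal spikes have *at least one* candidate
spike 0.5–10 ms before them.  This at-least-one counting deliberately
differs from the forward probability and is only used in this analysis.

## Statistical controls

*Amplitude identity.*  If coupled spikes come from one postsynaptic neuron,
their |amplitude| distribution should be a discrete subset of the target
electrode's full distribution.  The coupled set is compared against
repeated random subsets of equal size (drawn without replacement) with
two-sided two-sample KS tests; random-vs-random draws provide the null
reference, in which ~95% of comparisons exceed the 5% threshold.  On a
unimodal electrode (one proximal neuron) the coupled set is expected to be
indistinguishable from a random draw — a non-significant KS here is not a
failure of the method.  No multiple-testing correction is applied across
couplings; the draws characterise one coupling at a time.

*Timing specificity.*  The target train is rebuilt as first spike time +
cumulative sum of a random permutation of its inter-spike intervals.  This
preserves spike count, ISI multiset, first spike and total span (asserted
per repetition) while destroying fine timing.  The chance-coupling ratio —
target spikes within 0.5–10 ms after any reference spike (each counted
once) over reference spikes — collapses by >95% for genuine couplings and
stays inside the surrogate distribution for spurious ones.  Amplitudes keep
their original order: the control concerns timing only.

## Spike detection from raw voltage

Raw traces are band-passed with a 2nd-order Butterworth filter
(200–4000 Hz) applied forward–backward, so spike times are not shifted by
the filter phase.  The per-channel noise scale is the robust median
estimator σ = median(|v|)/0.6745, insensitive to the spikes themselves; a
spike is recorded at each local negative minimum below −6σ, with a 1 ms
dead time to avoid double-counting multiphasic waveforms.  Spike time and
amplitude are the time and value of the negative peak.  The exact noise
estimator of upstream acquisition toolchains is not standardised; the
median-based choice is documented here as this package's definition.

## The simulator

`axocouple.simulate` generates recordings with known ground truth: Poisson
unit trains with a 2 ms refractory period; cohort projection with fixed
delays plus Gaussian jitter; couplings as Bernoulli-thinned,
Gaussian-latency triggers inserted into the follower's train (the coupled
spike wins refractory ties); Gaussian per-(unit, electrode) amplitude modes
(multimodal electrodes arise by assigning ≥ 2 units to one electrode); and
Poisson background spikes with a distinct amplitude mode.

Defaults, fixed once from the regimes the detectors are calibrated for:
unit rate 2 Hz; cohort delay step 0.3 ms with jitter sd 0.015 ms
(inter-anchor latency CV ≈ 0.07); coupling latency mean 2.79 ms, sd 0.6 ms;
unit amplitude mode −45 ± 4 µV; background 0.5 Hz at −20 ± 3 µV.  The
benchmark condition is a full 120-electrode array, 300 s, five 3-electrode
units and four couplings with probabilities 0.2–0.8 converging from four
distinct presynaptic units onto one follower.  The convergent topology is
deliberate: followers sharing a presynaptic driver are mutually correlated,
and a CCG detector cannot distinguish that common-input correlation from
coupling, so sibling pairs would be detected as couplings.  That is a
genuine property of the method (acknowledged as the indirect-coupling
ambiguity), not a detector bug; the clean benchmark therefore plants only
direct, driver-disjoint couplings.  The shuffle-control scenario gives the
follower a low intrinsic rate (0.5 Hz), reflecting target electrodes
dominated by the coupled unit.

What the simulator does **not** emulate: bursting and network-wide
synchronised events, non-stationary rates, electrode drift, waveform shape
variation and overlap distortion, inhibition, and realistic extracellular
fields (raw traces are template + white noise).  Passing the recovery
benchmarks therefore shows the detector chain is correct and calibrated in
its intended regime, not that it is robust to every pathology of real
cultures.

## Recovery scoring

A detected signal matches a planted unit when they share ≥ 2 electrodes
with delay profiles agreeing within 0.2 ms; the same rule matches signals
across experimental conditions in graph comparisons.  A detected coupling
matches a planted (pre, post) pair when its reference maps to pre and its
target — a signal, or an electrode hosting the post unit — maps to post;
detections of one unit pair are pooled, preferring the signal-level
detection for error measurement.  Probability error is measured against
the realisation's triggered fraction (what was actually planted in that
recording), not the generating parameter, which differs from it by
binomial sampling noise (sd ≈ 0.02 at 600 presynaptic spikes).  Expected
latency is corrected for the timestamp convention: planted latency + post
anchor offset − pre anchor offset.  With no detections, recall is 0 and
precision is reported as 1 with zero support.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the recovery benchmark on
20 seeded 300 s simulations of the full 120-electrode layout, the null
control on 20 seeded 300 s simulations of six independent units on a 30-
electrode grid, the shuffle control with 20 surrogate repetitions, KS
discrimination with 100 draws of size 200, the CCG brute-force
equivalence on 100 random instances of ≤ 500 spikes, and the ISI-shuffle
invariants on 1000 random trains.

## Known limitations

- Couplings are *putative*: common input, indirect (polysynaptic) paths
  with unusually tight timing, and chains can satisfy the criteria; the
  criteria bound, but cannot eliminate, these confounds.
- Units whose axon crosses fewer than two electrodes are invisible to
  propagation detection by construction.
- The criterion thresholds (v₂, v₅ especially) were calibrated empirically
  on dissociated hippocampal cultures at ~2 Hz firing; dense or bursty
  preparations may need user-set values.
- The prose description of the peak-concentration filter ("60% of the
  total area") and its numeric threshold v₂ = 0.57 differ slightly; the
  numeric value is what this implementation binds, and it is configurable.
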