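# axocouple

Detection of single neurons and their short-latency (putatively synaptic)
couplings from multi-electrode-array (MEA) extracellular recordings —
without spike sorting.

## The problem

An MEA electrode records extracellular action potentials (eAPs) from any
neuron close enough, so per-electrode spike trains are mixtures of unknown
units and spike sorting cannot be routinely validated against ground
truth.  When a single axon passes over several electrodes, however, its
eAPs appear on that electrode cohort in a fixed order with fixed
sub-millisecond delays and very low jitter (latency CV ≈ 0.08).  These
**propagation signals** self-classify their spikes as coming from one
identified neuron.  Using a propagation signal's spike times as a clock,
clusters of spikes at other electrodes with short, moderately jittered
latency (1–5 ms, CV ≈ 0.5) behave like postsynaptic responses; `axocouple`
detects them, validates them statistically, and assembles the resulting
directed connectivity graph.

## The method

**Propagation.**  For every ordered electrode pair a ±2 ms
cross-correlogram (CCG) is built.  With n_all the reference electrode's
spike count and n_win the largest count sum in any 0.5 ms moving window,
a ratio n_win/n_all > 0.3 marks a consistent delay.  A reference electrode
whose consistent partners all lag it is the origin of a propagation
signal; the signal's spike times are the means of co-occurring spike pairs
on its two anchor electrodes.

**Coupling.**  A signal's spike times (or stimulation onsets) are compared
against every other signal and electrode with a one-sided CCG over
0.5–10 ms.  With n reference spikes, n₁ total CCG counts and n₂ the
largest count sum in any 3 ms moving window, a coupling is accepted iff

    n₁/n > v₁ = 0.1        (enough coupled spikes)
    n₂/n₁ > v₂ = 0.57      (counts concentrated in one peak)
    v₃ = 1 ms ≤ mean Δt in the peak ≤ v₄ = 5 ms
    sd of all Δt < v₅ = 2.7 ms

The **coupling probability** is n₂/n.  Electrode targets whose amplitude
CV exceeds v₆ = 0.25 are flagged for manual review (multi-unit
suspicion).  All thresholds are user-settable and every rejection is
logged with the criterion that failed.

**Controls.**  Coupled-spike amplitudes are compared to random
equal-sized draws from the electrode's full amplitude distribution
(two-sample KS, repeated); spike timing is destroyed by an ISI-preserving
shuffle and the chance-coupling ratio recomputed — genuine couplings
collapse by >95%.

**Simulator.**  `axocouple.simulate` plants Poisson units, propagation
cohorts, coupled followers, multimodal electrodes and background spikes
with full ground truth, and scores detector recovery.  See
`docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

The single-command demo simulates a 60 s recording on the full
120-electrode layout (5 propagating units, 4 planted couplings with
probabilities 0.2–0.8), runs the full pipeline, and scores recovery:

```sh
axocouple demo --seed 7 --duration 60 --out axocouple-demo
```

prints

```json
{
 "n_signals": 5,
 "n_couplings": 16,
 "cohort_precision": 1.0,
 "cohort_recall": 1.0,
 "coupling_precision": 1.0,
 "coupling_recall": 1.0,
 "probability_errors": {
  "u0->u4": 0.0,
  "u1->u4": 0.0092592592592593,
  "u2->u4": 0.0,
  "u3->u4": 0.025641025641025605
 },
 "latency_errors_ms": {
  "u0->u4": 0.12427053236856933,
  "u1->u4": 0.060105420215826655,
  "u2->u4": 0.09221089785935765,
  "u3->u4": 0.013491810761524281
 }
}
```

All 5 planted electrode cohorts and all 4 planted couplings are recovered
with no false positives (precision = recall = 1).  The 16 accepted
couplings are the 4 signal→signal relations plus the same relations seen
at the followers' individual cohort electrodes; recovery scoring pools
them per unit pair.  Recovered coupling probabilities are within ~0.03 of
the planted (realised) values and latencies within ~0.13 ms.  The run
directory contains `signals.json`, `couplings.csv`, `rejections.csv`,
`validation.json` (KS and shuffle controls per coupling),
`graph.graphml`, and `provenance.json` (config hash, seed, versions).

Other subcommands: `detect-spikes` (raw HDF5 voltage → spike table via
band-pass + 6σ threshold), `detect-propagation`, `detect-coupling`,
`upstream` (reverse presynaptic-input analysis), `validate`, `graph`,
`graph-diff` (retained/lost/gained edges across conditions), `simulate`,
and `run` (full pipeline on a spike table).  Spike tables are CSV
(`electrode,time_s,amplitude_uV`) or HDF5 (one group per electrode with
`times`/`amplitudes` datasets and root attributes `duration`, electrode
labels and coordinates).

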