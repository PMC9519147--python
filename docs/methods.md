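# Methods notes

This note documents the models behind `cctype`, the defaults that matter,
and the numerical and design choices made where more than one reasonable
option existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task and trial model

A session is a single run of an attention/memory switch task with five
conditions — two executive/attentional (`search`, `add`), two episodic
self-projection (`past`, `future`), and fixation `rest` — in randomized
order, 18 trials per condition (90 total) by default. Timing per trial:

| parameter | default | notes |
|---|---|---|
| cue → task interval | 1.0 s | 500 ms cue plus pre-task fixation; the analysis windows ("early" = task onset + 0–1 s, i.e. 1–2 s post-cue) presuppose task onset 1 s after cue onset |
| non-rest duration | mean 7.27 s, cap 10 s | clipped normal (SD 1.8 s, floor 1 s); the location parameter is solved so the *clipped* mean equals the target, the cap leaving a realistic point mass at timeout |
| rest duration | 4.0 s fixed | |
| inter-trial interval | 1.0 s | not constrained by the task description; neutral default |
| response period | 0 s | response screens are not simulated (no neural model attached to them); a knob exists to insert the gap |

All event times are seconds from recording start; epoch windows are
half-open `[start, end)`.

## LFP model and BBG pipeline

Each macro channel is the sum of

1. **1/f background** (power ∝ 1/f, flattened below 1 Hz), RMS 10 µV;
2. **60 Hz line noise**, amplitude 10 % of the background RMS (exists to
   exercise the notch stage);
3. **band-limited 70–150 Hz noise**, RMS 40 µV at baseline, whose envelope
   is multiplied by the trial condition's gain from cue onset through task
   offset (an instantaneous step — the LFP gain is not given a ramp).

The band-to-background ratio is deliberately high. Background and band
components add in quadrature inside each Morlet band, so an injected
amplitude gain g is measured as
`sqrt(b² + g²s²) / sqrt(b² + s²)` with `s/b` the per-frequency
amplitude ratio of band noise to background. With the defaults the in-band
PSD ratio is ≈130:1, which biases the recovered percent change
`100·(g−1)` by well under 1 % at g = 2; at equal RMS the bias would be tens
of percentage points. This is a property of baseline-division percent
change on additive backgrounds, not of the implementation.

Pipeline defaults: notch at 60 Hz and 2 harmonics (2 Hz-wide second-order
IIR, forward–backward), bipolar differencing of adjacent contacts within a
probe (sign convention `contact i − contact i+1`), polyphase FIR
downsampling to 1 kHz, Morlet decomposition at 7 cycles. The wavelet is
applied exactly in the frequency domain — the analytic wavelet's spectrum is
a Gaussian of SD `f/7` centered on f — normalized so that a unit-amplitude
sinusoid at a center frequency yields envelope 1.0; this normalization makes
the downstream percent change invariant to any amplitude convention.
Because the transform is computed once on the continuous recording and
epochs are cut afterwards, wavelet edge artifacts cannot leak into trials;
the first/last ~3 temporal SDs of the recording are reported per frequency
(`SpectralEnvelope.edge_sec`). Amplitudes are stored float32 (memory), and
percent change is computed in float64.

Baseline division uses the −500–0 ms pre-cue window **per trial, per
channel, per frequency**; the per-trial baseline-window mean of the
normalized signal is zero by construction, which the tests assert to 1e−6.
A zero baseline mean flags the trial invalid rather than producing
infinities. Group summaries average runs within a channel before averaging
channels.

## Single-unit model

A unit of type k fires with intensity
`λ(t) = basal · gain_k(condition(t), t − cue)` where the gain relaxes
exponentially from 1 toward the condition gain (time constant 300 ms)
starting `onset_lag` after cue onset, and returns to 1 at task offset. The
default profiles encode the four functional types:

| type | gains | lag | basal scale | character |
|---|---|---|---|---|
| 1 | search ×4 | 0 | 1 | search-selective |
| 2 | add ×4 | 0 | 1 | add-selective |
| 3 | past/future ×3, rest ×1.5, search/add ×0.35 | 1.5 s | 1 | delayed episodic, executive-suppressed |
| 4 | rest ×3.5 | 0 | 2.5 | rest-active, high basal rate |

Basal rates are log-normal (σ = 0.4 on the log scale — sparse but rarely
below ~0.5 Hz) scaled by the type multiplier, then globally rescaled so the
expected grand-mean session rate of the drawn population equals the
set-point (default 1.7 Hz) exactly; residual deviation in realized rates is
pure point-process sampling error (<1 % at session length).

**Spiking noise knob.** Spikes are sampled by time rescaling: the cumulative
intensity maps real time to rescaled time, where events form a renewal
process with unit-mean inter-event intervals of coefficient of variation
`noise_cv`. `noise_cv = 1` gives exactly the inhomogeneous Poisson process
(the default study condition); larger values give burstier, noisier trains;
`noise_cv = 0` gives a deterministic "clockwork" train. This single scalar
monotonically degrades downstream cluster recovery, which the tests verify
at four levels.

Two subtleties of the zero-noise limit are worth recording. First, a
clockwork train is a regular comb; its kernel rate converges to the smooth
intensity profile only when ISIs are comparable to the 10 ms kernel, so the
zero-noise recovery properties are exercised at ~20 Hz basal rates. Second,
the 90 %-of-max dendrogram cut yields exactly four clusters at zero noise
only if the three between-type merge heights lie within 10 % of each other
— with within-type distances near 0, an uneven between-type geometry lets
the cut swallow the lowest between-type merge. The zero-noise property
tests therefore use four orthogonal single-condition-selective profiles
(equidistant by symmetry). The paper-like default profiles are validated
instead at the default (Poisson) noise level, where within-type merge
heights (~0.6–0.97) and between-type heights (~1.05–1.15) bracket the cut
with a comfortable margin; this separation is stable across seeds, which is
what the acceptance-level checks measure.

**Artifact injection.** Outlier units are homogeneous Poisson trains planted
at the clean mean + 30 clean-SD (±1 % jitter), i.e. ~35–40 Hz against a
~1.7 Hz population — plausible for noise-contaminated channels. The
magnitude is far above the nominal "5 SD" screening criterion because the
screen computes mean and SD on the *contaminated* population: three large
outliers inflate the threshold, and analysis shows outliers staggered in
magnitude can leave the smallest one below it, so all three are planted at
equal magnitude. Duplicates copy an existing unit's spike times with
±0.2 ms uniform jitter — coincidence-detectable at 1 ms tolerance but not
byte-identical.

## Spike detection

The microwire render places a biphasic template (negative peak aligned to
the spike time, default −40 µV against 5 µV Gaussian noise, 30 kHz) on a
noise floor. Detection thresholds the 300–3000 Hz band-passed trace at
`mean − k·SD` (k = 5), interpreting the stated "mean plus 5 SD negative
threshold" as a negative deflection criterion; a median-absolute-deviation
SD estimate is available behind `robust=True` but is not the default since
the criterion names mean and SD. Events are timestamped at the excursion
minimum (stable under noise, unlike first crossing), with a 1 ms lockout
(the refractory window for detection is otherwise unspecified).
Single/multi isolation follows the <1 % of ISIs below 3 ms rule. Waveform
clustering (sorting) is out of scope; synthetic sessions carry ground-truth
identities, and the full pipeline's detection stage runs on a short rendered
snippet as a self-check rather than pretending single-channel thresholding
could separate 95 overlapping units.

## Unit screening, features, clustering

- Session-mean rate for the outlier screen is spike count / duration
  (identical to the kernel-rate trace mean to <0.1 % by kernel mass
  conservation). Duplicate screening needs the spike times themselves, so
  the screen takes spike trains rather than rate traces.
- The rate→percent-change baseline is pooled over the pre-cue windows of all
  trials per unit (a per-trial baseline would divide by zero for sparse
  units); units with pooled baseline below 0.1 Hz are flagged and excluded
  from clustering by default.
- Feature vectors concatenate the per-condition trial-mean percent-change
  response, cue to 3 s post-cue, in the fixed condition order, sampled at
  1 kHz (length 15 000). Clustering is invariant to halving this rate
  (tested); Pearson correlation is assumed for `1 − r`.
- Linkage is configurable among single/complete/average; the default is
  **average** (robust to the chaining that single linkage exhibits on noisy
  correlation distances). "90 % max distance" is interpreted as 90 % of the
  maximum **merge height** of the tree — the quantity a dendrogram cut
  operates on — with flat clusters being the subtrees entirely at or below
  the cut. A corollary of that rule: if all pairwise distances are equal,
  every merge sits at the maximum height, the cut falls below all of them,
  and every unit is its own cluster (the tests pin this tie case down).
  Cluster ids are relabeled by size (ties by smallest member index), making
  results invariant to input order.
- Leave-one-out stability reclusters after removing each unit in turn
  (n iterations for n units) and compares to the full partition restricted
  to the remaining units, via optimal one-to-one cluster matching
  (assignment problem on the contingency table). An iteration is
  "identical" only if cluster counts agree and every unit keeps its matched
  label; a per-unit fractional scoring mode exists behind `score="unitwise"`.

## Problem sizes and determinism

Every generator is a pure function of (config, seed); the full pipeline
report is reproducible byte-identically from (config, seed), and the config
hash embedded in outputs excludes only the output directory. The default
synthetic session is ~13 min long (90 trials); the acceptance script runs
the full unit-typing chain on it in seconds. LFP tests decompose only the
band they analyze (the full 2–200 Hz decomposition at 1 Hz steps is
available but memory-hungry at ~200 frequencies × session length per
channel); the end-to-end gain-recovery check uses 100 trials on one
channel, the scale at which the ±10 % recovery band is comfortably
resolved.

## What the generator does and does not emulate

It reproduces: condition-gated band-limited gamma amplitude on realistic
backgrounds; sparse, heterogeneous, approximately Poisson unit firing with
condition- and latency-structured modulation; the documented artifact modes
(rate outliers, duplicate trains); task timing. It does **not** emulate:
interictal/epileptic artifacts, volume conduction or biophysical LFP
generation, electrode drift, bursting structure beyond the renewal CV knob,
waveform overlap on microwires, behavioral responses or eye movements.
Passing tests therefore demonstrate that the pipeline recovers what it
assumes — gains, types, planted artifacts — under these statistics; they do
not certify performance on clinical recordings, where channel screening and
spike sorting (both out of scope here) dominate data quality.

## Known limitations

- The events/continuous/spike-train dialects are package-specific
  (documented in `io.py`); no NWB export.
- Group statistics (mixed-effects models with condition/subject structure)
  are intentionally not fitted; the pipeline emits the tidy per-trial table
  such models consume.
- The 90 %-of-max cut re-derives the cluster count at every leave-one-out
  iteration (the count is never fixed at 4), so stability rates can drop
  sharply once cluster margins shrink — by design, since that is what the
  stability metric is meant to detect.
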