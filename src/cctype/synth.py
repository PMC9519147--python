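"""Synthetic session generator.

Emulates a single run of the attention/memory switch task: five conditions
(``search``, ``add``, ``past``, ``future``, ``rest``), 18 trials per condition
by default, a 1 s cue-to-task interval, self-paced non-rest trials (mean
7.27 s, capped at 10 s) and fixed 4 s rest trials.  On that skeleton it
synthesizes

* macro-LFP channels: 1/f background + 60 Hz line + a 70-150 Hz band-limited
  component whose envelope is multiplied by a per-condition gain from cue
  onset through the trial (the substrate of the broadband-gamma analysis);
* single units: time-rescaled renewal processes around four functional type
  profiles (search-selective, add-selective, delayed episodic, rest-active)
  with log-normal basal rates calibrated to a target grand mean;
* unit artifacts (rate outliers, near-duplicate trains) and a raw 30 kHz
  microwire voltage render for the spike-detection stage.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.optimize import brentq

from .core import (
    CONDITIONS,
    ContinuousRecording,
    GroundTruth,
    InvalidConfigError,
    SpikeTrain,
    TrialTable,
    UnitProfile,
)

__all__ = [
    "DEFAULT_TYPE_PROFILES",
    "DEFAULT_MIX",
    "generate_trial_table",
    "condition_gain_envelope",
    "generate_lfp",
    "generate_units",
    "inject_unit_artifacts",
    "default_spike_template",
    "render_microwire_signal",
]

#: Default functional-type profiles.  Type 1 and 2 are selective for one
#: executive condition each; Type 3 prefers both episodic conditions with a
#: delayed onset, is weakly elevated at rest and suppressed during executive
#: tasks; Type 4 is rest-active with an elevated basal rate.
DEFAULT_TYPE_PROFILES: dict[int, UnitProfile] = {
    1: UnitProfile(1, {"search": 4.0, "add": 1.0, "past": 1.0, "future": 1.0, "rest": 1.0}),
    2: UnitProfile(2, {"search": 1.0, "add": 4.0, "past": 1.0, "future": 1.0, "rest": 1.0}),
    3: UnitProfile(
        3,
        {"search": 0.35, "add": 0.35, "past": 3.0, "future": 3.0, "rest": 1.5},
        onset_lag=1.5,
    ),
    4: UnitProfile(
        4,
        {"search": 1.0, "add": 1.0, "past": 1.0, "future": 1.0, "rest": 3.5},
        basal_scale=2.5,
    ),
}

#: Default population mix (type -> unit count), 91 units total.
DEFAULT_MIX: dict[int, int] = {1: 13, 2: 34, 3: 26, 4: 18}


def _clipped_normal_mu(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter so that a normal clipped to [lo, hi] has the target mean."""

    def clipped_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return (
            lo * stats.norm.cdf(a)
            + hi * stats.norm.sf(b)
            + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
            - sd * (stats.norm.pdf(b) - stats.norm.pdf(a))
        )

    return brentq(lambda m: clipped_mean(m) - target_mean, lo - 5 * sd, hi + 5 * sd, xtol=1e-10)


def generate_trial_table(
    n_per_condition: int = 18,
    cue_period: float = 1.0,
    iti: float = 1.0,
    mean_duration: float = 7.27,
    duration_sd: float = 1.8,
    max_duration: float = 10.0,
    min_duration: float = 1.0,
    rest_duration: float = 4.0,
    response_period: float = 0.0,
    start_pad: float = 2.0,
    run_id: int = 0,
    seed: int = 0,
) -> TrialTable:
    """Random condition order; self-paced non-rest durations, fixed rest.

    Non-rest durations are drawn from a normal clipped to
    ``[min_duration, max_duration]`` whose location is solved so the expected
    duration equals ``mean_duration`` (the cap at 10 s puts a realistic point
    mass at timeout).
    """
    if n_per_condition < 1:
        raise InvalidConfigError("n_per_condition must be >= 1")
    for name, val in [("cue_period", cue_period), ("iti", iti), ("mean_duration", mean_duration)]:
        if val <= 0:
            raise InvalidConfigError(f"{name} must be positive")
    if not (min_duration < mean_duration < max_duration):
        raise InvalidConfigError("need min_duration < mean_duration < max_duration")

    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(CONDITIONS)), n_per_condition)
    rng.shuffle(order)
    conditions = np.array(CONDITIONS)[order]

    mu = _clipped_normal_mu(mean_duration, duration_sd, min_duration, max_duration)
    durations = np.clip(rng.normal(mu, duration_sd, size=order.size), min_duration, max_duration)
    durations[conditions == "rest"] = rest_duration

    t = start_pad
    rows = []
    for i, (cond, dur) in enumerate(zip(conditions, durations)):
        cue = t
        task_on = cue + cue_period
        task_off = task_on + dur
        rows.append((i, run_id, cond, cue, task_on, task_off))
        t = task_off + response_period + iti
    df = pd.DataFrame(rows, columns=["trial_id", "run_id", "condition", "cue_onset", "task_onset", "task_offset"])
    return TrialTable(df)


def condition_gain_envelope(
    trials: TrialTable,
    gains: Mapping[str, float],
    t: np.ndarray,
    onset_lag: float = 0.0,
    ramp_tau: Optional[float] = None,
) -> np.ndarray:
    """Gain-versus-time profile: 1 outside trials, condition gain inside.

    With ``ramp_tau`` set, the gain relaxes exponentially from 1 toward the
    condition gain starting ``onset_lag`` seconds after cue onset; with
    ``ramp_tau=None`` it steps instantaneously at cue onset (used for the LFP
    band amplitude).  The envelope returns to 1 at task offset.
    """
    env = np.ones_like(t, dtype=float)
    for cue, off, cond in zip(trials.cue_onsets, trials.task_offsets, trials.conditions):
        g = float(gains.get(cond, 1.0))
        if g == 1.0:
            continue
        i0, i1 = np.searchsorted(t, [cue, off])
        if ramp_tau is None:
            env[i0:i1] = g
        else:
            tt = t[i0:i1] - cue - onset_lag
            ramp = np.where(tt > 0, 1.0 - np.exp(-np.maximum(tt, 0) / ramp_tau), 0.0)
            env[i0:i1] = 1.0 + (g - 1.0) * ramp
    return env


def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float, f_floor: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f power spectrum (flattened below ``f_floor``)."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, f_floor))
    shape[0] = 0.0
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n)
    return x * (rms / np.std(x))


def generate_lfp(
    trials: TrialTable,
    channel_gains: Mapping[object, Mapping[str, float]],
    fs: float = 2000.0,
    probe_of_channel: Optional[Mapping] = None,
    background_rms: float = 10.0,
    band_rms: float = 40.0,
    band: tuple[float, float] = (70.0, 150.0),
    line_freq: float = 60.0,
    line_amp_frac: float = 0.1,
    end_pad: float = 2.0,
    seed: int = 0,
) -> tuple[ContinuousRecording, GroundTruth]:
    """Synthesize macro-LFP channels with condition-gated 70-150 Hz amplitude.

    Each channel is 1/f background noise plus a 60 Hz line component
    (amplitude ``line_amp_frac * background_rms``) plus band-limited noise
    whose envelope is multiplied by the channel's condition gain from cue
    onset through the trial.  ``band_rms`` is deliberately large relative to
    the in-band background so that the measured band amplitude tracks the
    injected gain (see docs/methods.md).
    """
    if fs < 500.0:
        raise InvalidConfigError("fs must be >= 500 Hz to resolve the 70-150 Hz band")
    if band[1] >= fs / 2:
        raise InvalidConfigError("band upper edge must be below Nyquist")

    duration = trials.end_time(end_pad)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")

    channel_ids = list(channel_gains)
    rng = np.random.default_rng(seed)
    data = np.empty((len(channel_ids), n))
    for i, ch in enumerate(channel_ids):
        pink = _pink_noise(rng, n, fs, background_rms)
        line = line_amp_frac * background_rms * np.sin(2 * np.pi * line_freq * t + rng.uniform(0, 2 * np.pi))
        bb = signal.sosfiltfilt(sos, rng.standard_normal(n))
        bb *= band_rms / np.std(bb)
        env = condition_gain_envelope(trials, channel_gains[ch], t, ramp_tau=None)
        data[i] = pink + line + bb * env

    if probe_of_channel is None:
        probe_of_channel = {ch: "P0" for ch in channel_ids}
    rec = ContinuousRecording(data, fs, channel_ids, dict(probe_of_channel))
    gt = GroundTruth(channel_gains={ch: dict(channel_gains[ch]) for ch in channel_ids})
    return rec, gt


def _gamma_renewal_times(
    rng: np.random.Generator, total_mass: float, cv: float
) -> np.ndarray:
    """Event positions of a renewal process on [0, total_mass] in rescaled time.

    Unit-mean increments with coefficient of variation ``cv``: exponential at
    cv=1 (Poisson process), deterministic at cv=0, gamma otherwise.
    """
    if total_mass <= 0:
        return np.empty(0)
    if cv == 0:
        # clockwork train: events at 0.5, 1.5, 2.5, ... (phase-centered)
        return np.arange(0.5, total_mass, 1.0)
    k = 1.0 / cv**2
    out = []
    pos = 0.0
    while pos < total_mass:
        m = max(64, int((total_mass - pos) + 6 * cv * np.sqrt(total_mass - pos) + 16))
        incr = rng.gamma(k, cv**2, size=m)
        cum = pos + np.cumsum(incr)
        out.append(cum[cum < total_mass])
        pos = cum[-1]
    return np.concatenate(out) if out else np.empty(0)


def sample_inhomogeneous_train(
    rate: np.ndarray,
    t: np.ndarray,
    rng: np.random.Generator,
    cv: float = 1.0,
) -> np.ndarray:
    """Sample spike times from a rate profile by time rescaling.

    The cumulative intensity maps real time to rescaled time, where events
    are a unit-rate renewal process with ISI coefficient of variation ``cv``
    (cv=1: inhomogeneous Poisson).
    """
    dt = t[1] - t[0]
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    edges = np.concatenate([t, [t[-1] + dt]])
    marks = _gamma_renewal_times(rng, cum[-1], cv)
    return np.interp(marks, cum, edges)


def generate_units(
    trials: TrialTable,
    mix: Optional[Mapping[int, int]] = None,
    rate_distribution_mean: float = 1.7,
    basal_sigma: float = 0.4,
    noise_cv: float = 1.0,
    profiles: Optional[Mapping[int, UnitProfile]] = None,
    grid_fs: float = 1000.0,
    end_pad: float = 2.0,
    n_probes: int = 6,
    seed: int = 0,
) -> tuple[list[SpikeTrain], GroundTruth]:
    """Simulate the single-unit population.

    Each unit follows ``rate(t) = basal * gain(condition(t), t)`` with its
    type's gain profile.  Basal rates are log-normal (``basal_sigma`` on the
    log scale, sparse-firing regime) scaled by the type's basal multiplier,
    then globally rescaled so the *expected* grand-mean session rate over the
    drawn population equals ``rate_distribution_mean`` exactly.
    """
    if len(trials) == 0:
        raise InvalidConfigError("empty trial table")
    if rate_distribution_mean <= 0:
        raise InvalidConfigError("rate_distribution_mean must be positive")
    mix = dict(DEFAULT_MIX if mix is None else mix)
    if any(c < 0 for c in mix.values()):
        raise InvalidConfigError("unit counts must be >= 0")
    profiles = dict(DEFAULT_TYPE_PROFILES if profiles is None else profiles)

    duration = trials.end_time(end_pad)
    t = np.arange(int(round(duration * grid_fs))) / grid_fs

    envelopes = {}
    mean_gain = {}
    for utype in mix:
        p = profiles[utype]
        env = condition_gain_envelope(trials, p.condition_gain, t, p.onset_lag, p.ramp_tau)
        envelopes[utype] = env
        mean_gain[utype] = float(env.mean())

    rng = np.random.default_rng(seed)
    types = np.concatenate([np.full(mix[u], u) for u in sorted(mix)]) if mix else np.empty(0, int)
    raw = np.exp(rng.normal(0.0, basal_sigma, size=types.size))
    raw *= np.array([profiles[u].basal_scale for u in types])
    expected = raw * np.array([mean_gain[u] for u in types])
    scale = rate_distribution_mean / expected.mean()
    basal = raw * scale

    trains: list[SpikeTrain] = []
    gt = GroundTruth()
    for i, (utype, b) in enumerate(zip(types, basal)):
        times = sample_inhomogeneous_train(b * envelopes[utype], t, rng, cv=noise_cv)
        uid = i
        trains.append(SpikeTrain(uid, times, probe_id=f"mw{i % n_probes}"))
        gt.unit_types[uid] = int(utype)
        gt.artifact_flags[uid] = "clean"
        gt.basal_rates[uid] = float(b)
    return trains, gt


def inject_unit_artifacts(
    units: Sequence[SpikeTrain],
    duration: float,
    n_outliers: int = 3,
    n_duplicates: int = 1,
    outlier_sd_above: float = 30.0,
    duplicate_jitter: float = 2e-4,
    ground_truth: Optional[GroundTruth] = None,
    seed: int = 0,
) -> tuple[list[SpikeTrain], GroundTruth]:
    """Append rate-outlier units and near-duplicate trains to a clean set.

    Outliers are homogeneous Poisson trains planted at
    ``clean_mean + outlier_sd_above * clean_SD`` (equal magnitude, small
    jitter).  The magnitude is far above the nominal 5 SD criterion because
    the removal rule computes its statistics on the *contaminated*
    population, which the outliers themselves inflate; equal placement keeps
    every planted outlier above that threshold.  Duplicates copy a clean
    unit's spike times with uniform +/-``duplicate_jitter`` jitter.
    """
    if n_duplicates > len(units):
        raise InvalidConfigError("more duplicates requested than clean units")
    if n_outliers < 0 or n_duplicates < 0:
        raise InvalidConfigError("artifact counts must be >= 0")

    gt = ground_truth if ground_truth is not None else GroundTruth()
    for u in units:
        gt.artifact_flags.setdefault(u.unit_id, "clean")
    out = list(units)
    if n_outliers == 0 and n_duplicates == 0:
        return out, gt

    rng = np.random.default_rng(seed)
    rates = np.array([u.mean_rate(duration) for u in units])
    mu, sd = rates.mean(), rates.std()
    next_id = max(int(u.unit_id) for u in units) + 1 if units else 0

    for j in range(n_outliers):
        r = (mu + outlier_sd_above * sd) * (1.0 + rng.uniform(-0.01, 0.01))
        n = rng.poisson(r * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n))
        out.append(SpikeTrain(next_id, times, probe_id=f"mw{j % 6}"))
        gt.artifact_flags[next_id] = "outlier"
        next_id += 1

    src_idx = rng.choice(len(units), size=n_duplicates, replace=False)
    for j in src_idx:
        src = units[j]
        times = np.sort(src.spike_times + rng.uniform(-duplicate_jitter, duplicate_jitter, src.n_spikes))
        times = np.clip(times, 0.0, duration)
        out.append(SpikeTrain(next_id, times, probe_id=src.probe_id))
        gt.artifact_flags[next_id] = f"duplicate-of:{src.unit_id}"
        next_id += 1
    return out, gt


def default_spike_template(fs: float = 30000.0, amplitude: float = 40.0) -> np.ndarray:
    """Biphasic extracellular waveform, ~2 ms, negative peak of -``amplitude`` uV."""
    t = np.arange(int(round(2e-3 * fs))) / fs
    w = -np.exp(-((t - 0.5e-3) ** 2) / (2 * (0.12e-3) ** 2)) + 0.35 * np.exp(
        -((t - 1.0e-3) ** 2) / (2 * (0.3e-3) ** 2)
    )
    return amplitude * w / np.abs(w.min())


def render_microwire_signal(
    units: Sequence[SpikeTrain],
    duration: float,
    template: Optional[np.ndarray] = None,
    noise_sd: float = 5.0,
    fs: float = 30000.0,
    channel_id: object = "mw0",
    seed: int = 0,
) -> tuple[ContinuousRecording, GroundTruth]:
    """Raw extracellular voltage: Gaussian noise plus a template at each spike.

    The template's negative peak is aligned to the spike time, so detection
    timestamps are directly comparable to planted ground truth.
    """
    if template is None:
        template = default_spike_template(fs)
    template = np.asarray(template, float)
    if template.min() >= 0:
        raise InvalidConfigError("template peak must be negative")
    n = int(round(duration * fs))
    if template.size > n:
        raise InvalidConfigError("template longer than signal")

    rng = np.random.default_rng(seed)
    x = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    peak = int(np.argmin(template))
    planted = []
    for u in units:
        for ts in u.spike_times:
            i0 = int(round(ts * fs)) - peak
            if i0 < 0 or i0 + template.size > n:
                continue
            x[i0 : i0 + template.size] += template
            planted.append(ts)
    rec = ContinuousRecording(x[None, :], fs, [channel_id], {channel_id: channel_id})
    gt = GroundTruth(spike_times={channel_id: np.sort(np.array(planted))})
    return rec, gt
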