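"""Macro-LFP preprocessing and broadband-gamma (BBG) quantification.

The pipeline mirrors standard intracranial practice: notch filtering of line
noise and harmonics, bipolar re-referencing along each depth probe,
downsampling to 1 kHz, Morlet-wavelet spectral decomposition (2-200 Hz, 1 Hz
steps, 7 cycles), per-trial percent-change normalization against the -500 to
0 ms pre-cue baseline at every time-frequency point, averaging over the
70-150 Hz band, and per-trial window means relative to task onset (early:
0-1 s, late: 2-3 s).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import fft, ifft, next_fast_len

from .core import (
    ContinuousRecording,
    EpochedResponse,
    EpochedSpectra,
    InvalidConfigError,
    SpectralEnvelope,
    TrialTable,
)

__all__ = [
    "notch_filter",
    "bipolar_rereference",
    "resample",
    "morlet_amplitude",
    "epoch_percent_change",
    "band_average",
    "window_mean",
    "summarize_windows",
    "EARLY_WINDOW",
    "LATE_WINDOW",
]

#: Window presets in seconds relative to task onset.
EARLY_WINDOW = (0.0, 1.0)
LATE_WINDOW = (2.0, 3.0)


def notch_filter(
    rec: ContinuousRecording,
    base: float = 60.0,
    n_harmonics: int = 3,
    bandwidth: float = 2.0,
) -> ContinuousRecording:
    """Zero-phase notch at the line frequency and its harmonics.

    Each notch is a second-order IIR of fixed ``bandwidth`` (Hz) applied
    forward-backward.  Harmonics at or above Nyquist are skipped with a
    warning.
    """
    nyq = rec.fs / 2
    if base >= nyq:
        raise InvalidConfigError("notch base frequency must be below Nyquist")
    data = rec.data.astype(float, copy=True)
    for h in range(1, n_harmonics + 1):
        f = base * h
        if f >= 0.95 * nyq:
            warnings.warn(f"notch harmonic {f:g} Hz at/above Nyquist; skipped")
            continue
        b, a = signal.iirnotch(f, Q=f / bandwidth, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    return rec.copy_with(data=data)


def bipolar_rereference(rec: ContinuousRecording) -> ContinuousRecording:
    """Difference adjacent contacts along each probe (contact i minus i+1).

    Contacts are taken in ``channel_ids`` order within a probe; a probe with
    k contacts yields k-1 channels, and no difference ever crosses probes.
    """
    rows, ids, probes = [], [], {}
    by_probe: dict = {}
    for i, ch in enumerate(rec.channel_ids):
        by_probe.setdefault(rec.probe_of_channel[ch], []).append(i)
    for probe, idx in by_probe.items():
        if len(idx) < 2:
            warnings.warn(f"probe {probe!r} has a single contact; no bipolar channel")
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            rows.append(rec.data[a] - rec.data[b])
            new_id = f"{rec.channel_ids[a]}-{rec.channel_ids[b]}"
            ids.append(new_id)
            probes[new_id] = probe
    if not rows:
        raise InvalidConfigError("no probe has >= 2 contacts; nothing to re-reference")
    return ContinuousRecording(np.vstack(rows), rec.fs, ids, probes, rec.t0)


def resample(rec: ContinuousRecording, target_fs: float = 1000.0) -> ContinuousRecording:
    """Anti-aliased downsampling (polyphase FIR, zero phase)."""
    if target_fs > rec.fs:
        raise InvalidConfigError("upsampling is not supported")
    if target_fs == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return ContinuousRecording(data, target_fs, list(rec.channel_ids), dict(rec.probe_of_channel), rec.t0)


def morlet_amplitude(
    rec: ContinuousRecording,
    f_lo: float = 2.0,
    f_hi: float = 200.0,
    step: float = 1.0,
    cycles: float = 7.0,
    dtype=np.float32,
) -> SpectralEnvelope:
    """Amplitude envelope from complex Morlet wavelet convolution.

    The analytic wavelet at center frequency f has temporal SD
    ``cycles / (2*pi*f)``; convolution is performed exactly in the frequency
    domain (the wavelet's spectrum is a Gaussian of SD ``f / cycles``),
    normalized so a unit-amplitude sinusoid at a center frequency yields an
    envelope of 1.0.  The first/last ~3 temporal SDs of the recording are
    edge regions (``edge_sec``) where circular convolution can leak.
    """
    if f_hi >= rec.fs / 2:
        raise InvalidConfigError("f_hi must be below Nyquist")
    freqs = np.arange(f_lo, f_hi + step / 2, step, dtype=float)
    n = rec.n_samples
    nfft = next_fast_len(n)
    nu = np.fft.fftfreq(nfft, 1 / rec.fs)
    X = fft(rec.data, nfft, axis=-1)

    amp = np.empty((rec.data.shape[0], freqs.size, n), dtype=dtype)
    for i, f in enumerate(freqs):
        sigma_f = f / cycles
        W = 2.0 * np.exp(-((nu - f) ** 2) / (2 * sigma_f**2))
        amp[:, i, :] = np.abs(ifft(X * W, axis=-1)[:, :n]).astype(dtype)
    edge_sec = 3.0 * cycles / (2 * np.pi * freqs)
    return SpectralEnvelope(amp, freqs, rec.fs, list(rec.channel_ids), rec.t0, edge_sec)


def epoch_percent_change(
    env: SpectralEnvelope,
    trials: TrialTable,
    baseline: tuple[float, float] = (-0.5, 0.0),
    span: tuple[float, float] = (-0.5, 4.0),
) -> EpochedSpectra:
    """Cut cue-aligned epochs and normalize to per-trial baseline division.

    value(t, f) = 100 * (amp(t, f) / mean_baseline(f) - 1), with the baseline
    mean computed per trial, per channel, per frequency over the pre-cue
    window.  Trials whose epoch exceeds the recording are dropped with a
    warning; trials with a zero baseline mean are flagged invalid.
    """
    if baseline[0] >= baseline[1] or baseline[1] > 0:
        raise InvalidConfigError("baseline window must precede cue onset")
    fs = env.fs
    n = env.amplitude.shape[-1]
    n_t = int(round((span[1] - span[0]) * fs))
    rel_times = span[0] + np.arange(n_t) / fs
    b0 = int(round((baseline[0] - span[0]) * fs))
    b1 = int(round((baseline[1] - span[0]) * fs))

    keep, starts = [], []
    for i, cue in enumerate(trials.cue_onsets):
        s = int(round((cue + span[0] - env.t0) * fs))
        if s < 0 or s + n_t > n:
            warnings.warn(f"trial {trials.df['trial_id'].iloc[i]} epoch exceeds recording; dropped")
            continue
        keep.append(i)
        starts.append(s)

    n_ch, n_f = env.amplitude.shape[:2]
    data = np.empty((n_ch, len(keep), n_f, n_t), dtype=np.float64)
    valid = np.ones((n_ch, len(keep)), dtype=bool)
    for j, s in enumerate(starts):
        seg = env.amplitude[:, :, s : s + n_t].astype(np.float64)
        base = seg[:, :, b0:b1].mean(axis=-1, keepdims=True)
        zero = base[:, :, 0] == 0
        base[base == 0] = np.nan
        data[:, j] = 100.0 * (seg / base - 1.0)
        valid[:, j] = ~zero.any(axis=1)

    df = trials.df.iloc[keep]
    return EpochedSpectra(
        data=data,
        freqs=env.freqs,
        times=rel_times,
        conditions=df["condition"].to_numpy(),
        trial_ids=df["trial_id"].to_numpy(),
        channel_ids=list(env.channel_ids),
        valid=valid,
    )


def band_average(
    epoched: EpochedSpectra, f_lo: float = 70.0, f_hi: float = 150.0
) -> list[EpochedResponse]:
    """Unweighted mean over center frequencies in [f_lo, f_hi] inclusive."""
    sel = (epoched.freqs >= f_lo) & (epoched.freqs <= f_hi)
    if not sel.any():
        raise InvalidConfigError(f"no decomposed frequencies in [{f_lo}, {f_hi}]")
    band = epoched.data[:, :, sel, :].mean(axis=2)
    return [
        EpochedResponse(
            data=band[c],
            times=epoched.times,
            conditions=epoched.conditions,
            trial_ids=epoched.trial_ids,
            label=ch,
            valid=epoched.valid[c].copy(),
        )
        for c, ch in enumerate(epoched.channel_ids)
    ]


def window_mean(
    bbg: Union[EpochedResponse, Sequence[EpochedResponse]],
    trials: TrialTable,
    window_rel_task: tuple[float, float] = EARLY_WINDOW,
    window_label: Optional[str] = None,
) -> pd.DataFrame:
    """Per-trial scalar mean over a window expressed relative to task onset.

    Windows extending past the trial's task offset are truncated there and
    flagged (``truncated``); rest trials end at 4 s.  Returns the tidy table
    consumed by external mixed-effects model fitting, with columns
    ``trial_id, condition, channel, window, mean_pct, truncated, valid``.
    """
    if isinstance(bbg, EpochedResponse):
        bbg = [bbg]
    if window_label is None:
        window_label = f"{window_rel_task[0]:g}-{window_rel_task[1]:g}s"
    tdf = trials.df.set_index("trial_id")
    rows = []
    for resp in bbg:
        dt = resp.times[1] - resp.times[0]
        for j, tid in enumerate(resp.trial_ids):
            cue = tdf.loc[tid, "cue_onset"]
            task_rel = tdf.loc[tid, "task_onset"] - cue
            off_rel = tdf.loc[tid, "task_offset"] - cue
            w0 = task_rel + window_rel_task[0]
            w1 = task_rel + window_rel_task[1]
            truncated = w1 > off_rel
            w1 = min(w1, off_rel)
            sel = (resp.times >= w0 - dt / 2) & (resp.times < w1 - dt / 2)
            if not sel.any():
                continue
            rows.append(
                (
                    tid,
                    tdf.loc[tid, "run_id"],
                    tdf.loc[tid, "condition"],
                    resp.label,
                    window_label,
                    float(resp.data[j, sel].mean()),
                    bool(truncated),
                    bool(resp.valid[j]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["trial_id", "run_id", "condition", "channel", "window", "mean_pct", "truncated", "valid"],
    )


def summarize_windows(table: pd.DataFrame) -> pd.DataFrame:
    """Two-level group summary: runs averaged within channel, then channels.

    Mirrors group analyses where electrodes recorded in multiple blocks are
    first averaged per electrode before averaging across electrodes.
    """
    per_run = (
        table[table["valid"]]
        .groupby(["condition", "window", "channel", "run_id"], observed=True)["mean_pct"]
        .mean()
    )
    per_channel = per_run.groupby(["condition", "window", "channel"], observed=True).mean()
    return per_channel.groupby(["condition", "window"], observed=True).mean().reset_index()
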