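"""Microwire spike extraction: band-pass, amplitude-threshold detection,
and single/multi-unit isolation by inter-spike-interval violations.

This is a transparent thresholding stage (detection validates the negative
mean-minus-5-SD rule on synthetic renders); waveform clustering into units is
deliberately out of scope — synthetic sessions carry ground-truth identities.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import signal

from .core import ContinuousRecording, InvalidConfigError, SpikeTrain

__all__ = ["bandpass_filter", "detect_spikes", "classify_isolation"]


def bandpass_filter(
    rec: ContinuousRecording, lo: float = 300.0, hi: float = 3000.0, order: int = 4
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (default 300-3000 Hz)."""
    if hi >= rec.fs / 2:
        raise InvalidConfigError("band upper edge must be below Nyquist")
    if lo <= 0 or lo >= hi:
        raise InvalidConfigError("need 0 < lo < hi")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(data=signal.sosfiltfilt(sos, rec.data, axis=-1))


def detect_spikes(
    rec: ContinuousRecording,
    k: float = 5.0,
    lockout: float = 1e-3,
    snippet: tuple[float, float] = (-0.5e-3, 1.5e-3),
    robust: bool = False,
) -> list[SpikeTrain]:
    """Negative threshold crossing detection, one train per channel.

    The threshold is ``mean - k * SD`` of the (filtered) trace, computed over
    the whole recording; with ``robust=True`` the SD estimate is the median
    absolute deviation divided by 0.6745.  Each contiguous sub-threshold
    excursion yields one event timestamped at its minimum; events closer than
    ``lockout`` to the previous accepted event are discarded.  Waveform
    snippets are cut around each event.
    """
    if k <= 0:
        raise InvalidConfigError("k must be positive")
    trains = []
    s0 = int(round(snippet[0] * rec.fs))
    s1 = int(round(snippet[1] * rec.fs))
    for c, ch in enumerate(rec.channel_ids):
        x = rec.data[c]
        if robust:
            sd = np.median(np.abs(x - np.median(x))) / 0.6745
        else:
            sd = x.std()
        if sd == 0:
            warnings.warn(f"channel {ch!r}: flat signal, no events")
            trains.append(SpikeTrain(ch, np.empty(0), probe_id=rec.probe_of_channel.get(ch)))
            continue
        theta = x.mean() - k * sd
        below = x < theta
        # contiguous excursion boundaries
        d = np.diff(below.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if below[0]:
            starts = np.concatenate([[0], starts])
        if below[-1]:
            ends = np.concatenate([ends, [x.size]])
        peaks = np.array([s + np.argmin(x[s:e]) for s, e in zip(starts, ends)], dtype=int)
        # lockout: greedy scan
        accepted = []
        last = -np.inf
        min_gap = lockout * rec.fs
        for p in peaks:
            if p - last >= min_gap:
                accepted.append(p)
                last = p
        accepted = np.array(accepted, dtype=int)
        waveforms = None
        if accepted.size:
            idx = accepted[:, None] + np.arange(s0, s1)
            idx = np.clip(idx, 0, x.size - 1)
            waveforms = x[idx]
        trains.append(
            SpikeTrain(
                ch,
                rec.t0 + accepted / rec.fs,
                probe_id=rec.probe_of_channel.get(ch),
                waveforms=waveforms,
            )
        )
    return trains


def classify_isolation(
    train: SpikeTrain,
    isi_threshold: float = 0.003,
    max_violation_fraction: float = 0.01,
) -> str:
    """Single- vs multi-unit label from refractory-period violations.

    A unit is ``single`` iff fewer than ``max_violation_fraction`` of its
    inter-spike intervals fall below ``isi_threshold`` (default: <1% of ISIs
    under 3 ms).  Trains with fewer than 2 spikes are ``unknown``.
    """
    if train.n_spikes < 2:
        return "unknown"
    isi = np.diff(train.spike_times)
    frac = float(np.mean(isi < isi_threshold))
    return "single" if frac < max_violation_fraction else "multi"
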