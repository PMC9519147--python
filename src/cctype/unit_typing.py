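"""Functional typing of single units.

Spike trains are converted to Gaussian-kernel instantaneous firing rates
(10 ms SD), screened for rate outliers (>5 population SD) and duplicate
trains, normalized to percent change against the pooled pre-cue baseline,
reduced to a task-response feature vector (condition-mean response, cue to
3 s post-cue, concatenated over the five conditions in fixed order), and
clustered agglomeratively on the correlation distance 1 - r with a cut at
90% of the maximum merge height.  Leave-one-out reclustering quantifies the
stability of the resulting partition.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .core import (
    CONDITIONS,
    ClusterResult,
    EpochedResponse,
    InvalidConfigError,
    RateTrace,
    SpikeTrain,
    StabilityResult,
    TrialTable,
)

__all__ = [
    "instantaneous_rate",
    "filter_units",
    "normalize_rate",
    "build_feature_vectors",
    "correlation_distance_matrix",
    "cluster_units",
    "match_partitions",
    "loo_stability",
    "unit_feature_matrix",
]


def instantaneous_rate(
    train: SpikeTrain,
    duration: float,
    kernel_sd: float = 0.010,
    out_fs: float = 1000.0,
    t_start: float = 0.0,
) -> RateTrace:
    """Gaussian-kernel rate estimate: rate(t) = sum_spikes N(t - t_s; sd).

    The kernel is the exact normal density evaluated on the output grid
    (truncated at 6 SD), so the trace integral equals the spike count for
    spikes away from the edges.
    """
    if kernel_sd <= 0:
        raise InvalidConfigError("kernel_sd must be positive")
    dt = 1.0 / out_fs
    n = int(round((duration - t_start) * out_fs))
    t = t_start + np.arange(n) * dt
    rate = np.zeros(n)
    ts = train.spike_times
    if ts.size:
        half = int(np.ceil(6 * kernel_sd * out_fs))
        offs = np.arange(-half, half + 1)
        centers = np.round((ts - t_start) * out_fs).astype(int)
        idx = centers[:, None] + offs[None, :]
        tt = t_start + idx * dt
        vals = np.exp(-((tt - ts[:, None]) ** 2) / (2 * kernel_sd**2)) / (kernel_sd * np.sqrt(2 * np.pi))
        ok = (idx >= 0) & (idx < n)
        np.add.at(rate, idx[ok], vals[ok])
    return RateTrace(train.unit_id, t, rate, kernel_sd)


def filter_units(
    trains: Sequence[SpikeTrain],
    duration: float,
    outlier_sd: float = 5.0,
    duplicate_tolerance: float = 1e-3,
    duplicate_fraction: float = 0.95,
) -> tuple[list[SpikeTrain], pd.DataFrame]:
    """Remove firing-rate outliers and duplicate trains.

    A unit is an outlier if its session-mean rate exceeds the population
    mean + ``outlier_sd`` SD (population statistics over all input units).
    Two units are duplicates if at least ``duplicate_fraction`` of one's
    spikes fall within ``duplicate_tolerance`` of the other's; the member
    with fewer spikes (ties: the later unit) is removed.  Returns the
    retained units and a removal report.
    """
    if len(trains) < 3:
        raise InvalidConfigError("need >= 3 units for population statistics")
    rates = np.array([u.mean_rate(duration) for u in trains])
    thr = rates.mean() + outlier_sd * rates.std()
    removed: dict[int, str] = {}
    for i, r in enumerate(rates):
        if r > thr:
            removed[i] = f"outlier (rate {r:.2f} Hz > {thr:.2f} Hz)"

    def coincident_fraction(a: np.ndarray, b: np.ndarray) -> float:
        if a.size == 0 or b.size == 0:
            return 0.0
        j = np.searchsorted(b, a)
        d = np.full(a.size, np.inf)
        ok = j < b.size
        d[ok] = np.abs(b[j[ok]] - a[ok])
        ok = j > 0
        d[ok] = np.minimum(d[ok], np.abs(b[j[ok] - 1] - a[ok]))
        return float(np.mean(d <= duplicate_tolerance))

    n = len(trains)
    for i in range(n):
        if i in removed:
            continue
        for j in range(i + 1, n):
            if j in removed:
                continue
            fi = coincident_fraction(trains[i].spike_times, trains[j].spike_times)
            fj = coincident_fraction(trains[j].spike_times, trains[i].spike_times)
            if max(fi, fj) >= duplicate_fraction:
                victim = j if trains[j].n_spikes <= trains[i].n_spikes else i
                keeper = i if victim == j else j
                removed[victim] = (
                    f"duplicate of unit {trains[keeper].unit_id} "
                    f"({100 * max(fi, fj):.1f}% coincident spikes)"
                )
                if victim == i:
                    break
    retained = [u for i, u in enumerate(trains) if i not in removed]
    if not retained:
        raise InvalidConfigError("all units removed by filtering")
    report = pd.DataFrame(
        [(trains[i].unit_id, reason) for i, reason in sorted(removed.items())],
        columns=["unit_id", "reason"],
    )
    return retained, report


def normalize_rate(
    rate: RateTrace,
    trials: TrialTable,
    baseline: tuple[float, float] = (-0.5, 0.0),
    span: tuple[float, float] = (-0.5, 3.0),
    baseline_floor: float = 0.1,
) -> EpochedResponse:
    """Percent-change epochs of a rate trace relative to the pre-cue period.

    The baseline is the unit's mean rate pooled over the pre-cue windows of
    *all* trials (a per-trial baseline would divide by zero for sparse
    units); epochs are aligned to cue onset.  Units whose pooled baseline
    falls below ``baseline_floor`` Hz are flagged ``low_baseline`` and are
    excluded from clustering by default.
    """
    fs = rate.fs
    t0 = rate.times[0]
    n = rate.rate.size
    n_t = int(round((span[1] - span[0]) * fs))
    rel_times = span[0] + np.arange(n_t) / fs

    base_vals = []
    keep, starts = [], []
    for i, cue in enumerate(trials.cue_onsets):
        b0 = int(round((cue + baseline[0] - t0) * fs))
        b1 = int(round((cue + baseline[1] - t0) * fs))
        if b0 >= 0 and b1 <= n:
            base_vals.append(rate.rate[b0:b1])
        s = int(round((cue + span[0] - t0) * fs))
        if s < 0 or s + n_t > n:
            warnings.warn(f"trial {trials.df['trial_id'].iloc[i]} epoch exceeds rate trace; dropped")
            continue
        keep.append(i)
        starts.append(s)
    if not base_vals:
        raise InvalidConfigError("no baseline window falls inside the rate trace")
    b = float(np.concatenate(base_vals).mean())
    low = b < baseline_floor
    denom = b if b > 0 else np.nan

    data = np.empty((len(keep), n_t))
    for j, s in enumerate(starts):
        data[j] = 100.0 * (rate.rate[s : s + n_t] / denom - 1.0)
    df = trials.df.iloc[keep]
    return EpochedResponse(
        data=data,
        times=rel_times,
        conditions=df["condition"].to_numpy(),
        trial_ids=df["trial_id"].to_numpy(),
        label=rate.unit_id,
        baseline_hz=b,
        low_baseline=low,
    )


def build_feature_vectors(
    epochs: Sequence[EpochedResponse],
    span: tuple[float, float] = (0.0, 3.0),
    include_low_baseline: bool = False,
) -> tuple[list, np.ndarray]:
    """Task-response feature vectors: condition means concatenated in order.

    For each unit, the trial-mean percent-change response is computed per
    condition on ``span`` (cue-relative) and concatenated over the fixed
    condition order; all vectors have length
    ``5 * (span[1]-span[0]) * sample_rate``.  Units missing a condition or
    flagged low-baseline are excluded with a warning.
    """
    unit_ids, vectors = [], []
    for ep in epochs:
        if ep.low_baseline and not include_low_baseline:
            warnings.warn(f"unit {ep.label!r} excluded: baseline below floor")
            continue
        sel_t = (ep.times >= span[0] - 1e-12) & (ep.times < span[1] - 1e-12)
        parts = []
        missing = False
        for cond in CONDITIONS:
            m = ep.conditions == cond
            if not m.any():
                warnings.warn(f"unit {ep.label!r} excluded: no {cond} trials")
                missing = True
                break
            parts.append(ep.data[m][:, sel_t].mean(axis=0))
        if missing:
            continue
        unit_ids.append(ep.label)
        vectors.append(np.concatenate(parts))
    if not vectors:
        return [], np.empty((0, 0))
    return unit_ids, np.vstack(vectors)


def correlation_distance_matrix(features: np.ndarray, unit_ids: Optional[list] = None):
    """Pairwise 1 - Pearson r between feature vectors.

    Constant vectors have undefined correlation and are excluded with a
    warning.  Returns ``(distance_matrix, kept_indices)``; the matrix is
    symmetric with zero diagonal, values in [0, 2].
    """
    features = np.asarray(features, float)
    if features.shape[0] < 2:
        raise InvalidConfigError("need >= 2 units")
    sd = features.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < features.shape[0]:
        dropped = [i for i in range(features.shape[0]) if i not in set(kept)]
        names = [unit_ids[i] for i in dropped] if unit_ids else dropped
        warnings.warn(f"constant feature vectors excluded: {names}")
    r = np.corrcoef(features[kept])
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d, kept


def cluster_units(
    d: np.ndarray,
    cutoff_fraction: float = 0.9,
    linkage_method: str = "average",
    unit_ids: Optional[list] = None,
) -> ClusterResult:
    """Agglomerative clustering with a cut at a fraction of max merge height.

    Flat clusters are the subtrees whose merges all lie at or below
    ``cutoff_fraction * max(merge height)``.  Cluster ids are relabeled by
    size (descending; ties by smallest member index) so labels are
    deterministic and order-independent.
    """
    d = np.asarray(d, float)
    n = d.shape[0]
    if n < 2:
        raise InvalidConfigError("need >= 2 units to cluster")
    if linkage_method not in ("single", "complete", "average"):
        raise InvalidConfigError(f"unsupported linkage: {linkage_method}")
    Z = linkage(squareform(d, checks=False), method=linkage_method)
    cut = cutoff_fraction * Z[:, 2].max()
    raw = fcluster(Z, t=cut, criterion="distance")
    # deterministic relabeling: by size desc, ties by first member index
    order = sorted(
        np.unique(raw),
        key=lambda c: (-np.sum(raw == c), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    if unit_ids is None:
        unit_ids = list(range(n))
    return ClusterResult(list(unit_ids), labels, Z, float(cut), int(labels.max()))


def match_partitions(labels_a: np.ndarray, labels_b: np.ndarray):
    """Optimal one-to-one cluster matching between two labelings.

    Solves the assignment problem on the contingency table, maximizing
    matched overlap.  ``identical`` is True iff the cluster counts agree and
    every unit keeps its matched label.  Returns ``(mapping, identical)``
    with ``mapping`` from labels_a clusters to labels_b clusters (for the
    smaller cluster count when they differ).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("labelings must cover the same units")
    ua, ub = np.unique(a), np.unique(b)
    cont = np.zeros((ua.size, ub.size), dtype=int)
    for i, ca in enumerate(ua):
        for j, cb in enumerate(ub):
            cont[i, j] = np.sum((a == ca) & (b == cb))
    ri, ci = linear_sum_assignment(-cont)
    mapping = {int(ua[i]): int(ub[j]) for i, j in zip(ri, ci)}
    overlap = int(cont[ri, ci].sum())
    identical = (ua.size == ub.size) and (overlap == a.size)
    return mapping, identical


def loo_stability(
    features: np.ndarray,
    cutoff_fraction: float = 0.9,
    linkage_method: str = "average",
    unit_ids: Optional[list] = None,
    precomputed_distance: Optional[np.ndarray] = None,
    score: str = "partition",
) -> StabilityResult:
    """Leave-one-out reclustering consistency of the full-data partition.

    For each unit, the remaining units are reclustered (same distance,
    linkage and cut rule) and optimally matched against the full-data
    partition restricted to them.  With ``score='partition'`` an iteration
    counts as identical only if the matched partitions agree exactly;
    ``score='unitwise'`` instead credits the fraction of units whose matched
    label is preserved (n_identical is then the rounded sum of fractions).
    """
    if precomputed_distance is not None:
        d = np.asarray(precomputed_distance, float)
    else:
        d, kept = correlation_distance_matrix(features, unit_ids)
        if unit_ids is not None:
            unit_ids = [unit_ids[i] for i in kept]
    n = d.shape[0]
    if n < 3:
        raise InvalidConfigError("need >= 3 units for leave-one-out")
    if unit_ids is None:
        unit_ids = list(range(n))
    full = cluster_units(d, cutoff_fraction, linkage_method, unit_ids)

    per_iter = []
    credit = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        sub = cluster_units(d[np.ix_(keep, keep)], cutoff_fraction, linkage_method)
        ref = full.labels[keep]
        mapping, identical = match_partitions(sub.labels, ref)
        if score == "partition":
            per_iter.append((unit_ids[i], bool(identical)))
            credit += identical
        else:
            mapped = np.array([mapping.get(int(l), -1) for l in sub.labels])
            frac = float(np.mean(mapped == ref))
            per_iter.append((unit_ids[i], frac))
            credit += frac
    return StabilityResult(n, int(round(credit)) if score != "partition" else int(credit), per_iter)


def unit_feature_matrix(
    trains: Sequence[SpikeTrain],
    trials: TrialTable,
    duration: float,
    kernel_sd: float = 0.010,
    feature_fs: float = 1000.0,
    baseline: tuple[float, float] = (-0.5, 0.0),
    span: tuple[float, float] = (0.0, 3.0),
    baseline_floor: float = 0.1,
) -> tuple[list, np.ndarray, list[EpochedResponse]]:
    """Convenience chain: rates -> percent change epochs -> feature vectors."""
    epochs = []
    for u in trains:
        rt = instantaneous_rate(u, duration, kernel_sd, feature_fs)
        epochs.append(
            normalize_rate(rt, trials, baseline, (min(baseline[0], span[0]), span[1]), baseline_floor)
        )
    unit_ids, F = build_feature_vectors(epochs, span)
    return unit_ids, F, epochs
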