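"""Spike-train and calcium-trace statistics.

Covers the quantities used to characterize network activity: mean firing
rate, pairwise spike-count correlation under non-overlapping or sliding
binning, SIC-gated single-neuron burst detection, calcium transient
detection, burst-onset distances as a synchrony measure, and two-sample
Kolmogorov-Smirnov contrasts with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinnedTrains", "BurstTable", "TransientTable",
    "mean_firing_rate", "bin_counts", "pairwise_correlation",
    "detect_bursts", "sic_windows_from_trace", "detect_transients",
    "burst_onset_distance", "group_contrast",
]

#: burst gap thresholds (ms): spikes closer than this belong to one burst
BURST_GAP = {"exc": 2000.0, "inh": 400.0}


@dataclass
class BinnedTrains:
    """Spike-count matrix (rows = neurons, columns = bins) plus bin spec."""

    counts: np.ndarray
    width: float
    stride: float
    window: tuple[float, float]
    neuron_ids: np.ndarray | None = None


@dataclass
class BurstRow:
    onsets: np.ndarray        # ms
    durations: np.ndarray     # ms
    n_spikes: np.ndarray


@dataclass
class BurstTable:
    """Per-neuron detected bursts plus per-neuron summary statistics."""

    rows: dict[int, BurstRow] = field(default_factory=dict)
    model_time: float = 0.0   # ms

    def summary(self) -> pd.DataFrame:
        recs = []
        minutes = self.model_time / 60000.0 if self.model_time else np.nan
        for gid, row in self.rows.items():
            n = len(row.onsets)
            recs.append({
                "cell_id": gid, "n_bursts": n,
                "burst_freq_per_min": n / minutes if minutes else np.nan,
                "mean_duration_ms": float(np.mean(row.durations)) if n else np.nan,
                "mean_spikes_per_burst": float(np.mean(row.n_spikes)) if n else np.nan,
            })
        return pd.DataFrame(recs)


@dataclass
class TransientRow:
    onsets: np.ndarray   # ms
    offsets: np.ndarray  # ms
    peaks: np.ndarray    # uM


@dataclass
class TransientTable:
    rows: dict[int, TransientRow] = field(default_factory=dict)
    model_time: float = 0.0

    def summary(self) -> pd.DataFrame:
        recs = []
        minutes = self.model_time / 60000.0 if self.model_time else np.nan
        for gid, row in self.rows.items():
            n = len(row.onsets)
            durs = row.offsets - row.onsets
            recs.append({
                "cell_id": gid, "n_transients": n,
                "freq_per_min": n / minutes if minutes else np.nan,
                "mean_duration_s": float(np.mean(durs)) / 1000.0 if n else np.nan,
                "max_peak_uM": float(np.max(row.peaks)) if n else np.nan,
            })
        return pd.DataFrame(recs)


def mean_firing_rate(spikes: pd.DataFrame | np.ndarray, N: int,
                     window: tuple[float, float]) -> float:
    """Population mean rate (spikes/s): total count / (N * window length)."""
    if N <= 0:
        raise ValueError("N must be positive")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window duration must be positive")
    if isinstance(spikes, pd.DataFrame):
        times = spikes["time_ms"].to_numpy()
    else:
        times = np.asarray(spikes, dtype=float)
    count = int(np.count_nonzero((times >= t0) & (times < t1)))
    return count / (N * (t1 - t0) / 1000.0)


def bin_counts(spike_trains: dict[int, np.ndarray], width: float,
               stride: float, window: tuple[float, float]) -> BinnedTrains:
    """Bin spike trains; bin k covers the half-open interval
    [start + k*stride, start + k*stride + width)."""
    if width <= 0 or stride <= 0:
        raise ValueError("width and stride must be positive")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    n_bins = int(np.floor((t1 - t0 - width) / stride)) + 1
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    lefts = t0 + np.arange(n_bins) * stride
    rights = lefts + width
    ids = np.fromiter(spike_trains.keys(), dtype=np.int64)
    counts = np.zeros((len(ids), n_bins), dtype=np.int64)
    for row, gid in enumerate(ids):
        t = np.sort(np.asarray(spike_trains[gid], dtype=float))
        counts[row] = (np.searchsorted(t, rights, side="left")
                       - np.searchsorted(t, lefts, side="left"))
    return BinnedTrains(counts=counts, width=width, stride=stride,
                        window=(t0, t1), neuron_ids=ids)


def pairwise_correlation(bt: BinnedTrains) -> tuple[np.ndarray, float]:
    """Pearson correlation matrix of binned spike counts and its mean
    over distinct pairs.

    Rows with zero variance (silent neurons) give undefined coefficients;
    such pairs are excluded from the average and set to NaN in the matrix.
    """
    x = bt.counts.astype(float)
    if x.shape[1] < 2:
        raise ValueError("need at least two bins")
    sd = x.std(axis=1)
    valid = sd > 0
    r = np.full((x.shape[0], x.shape[0]), np.nan)
    if valid.sum() >= 1:
        sub = np.corrcoef(x[valid])
        if valid.sum() == 1:
            sub = np.array([[1.0]])
        r[np.ix_(valid, valid)] = sub
    iu = np.triu_indices(x.shape[0], k=1)
    vals = r[iu]
    mean_r = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else np.nan
    return r, mean_r


def sic_windows_from_trace(times: np.ndarray, i_sic: np.ndarray,
                           threshold: float = 0.0,
                           merge_gap: float = 500.0) -> list[tuple[float, float]]:
    """SIC windows (onset, offset) from a sampled I_SIC trace.

    A window opens when the trace rises above ``threshold`` and closes
    when it falls back; windows separated by less than ``merge_gap`` ms
    are merged.
    """
    above = i_sic > threshold
    return _intervals_from_mask(times, above, merge_gap)


def _intervals_from_mask(times, mask, merge_gap):
    if len(times) < 2:
        raise ValueError("trace must have at least 2 samples")
    idx = np.nonzero(np.diff(mask.astype(np.int8)))[0]
    onsets = []
    offsets = []
    if mask[0]:
        onsets.append(times[0])
    for i in idx:
        if mask[i + 1]:
            onsets.append(times[i + 1])
        else:
            offsets.append(times[i + 1])
    if mask[-1]:
        offsets.append(times[-1])
    merged: list[list[float]] = []
    for on, off in zip(onsets, offsets):
        if merged and on - merged[-1][1] < merge_gap:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    return [(on, off) for on, off in merged]


def detect_bursts(spike_times: np.ndarray, cell_kind: str,
                  sic_windows: list[tuple[float, float]],
                  min_spikes_per_burst: int = 2,
                  gap: float | None = None) -> BurstRow:
    """SIC-gated burst detection for one neuron.

    Spikes are grouped greedily left to right: a spike joins the current
    burst iff its distance to the previous spike is below the gap
    threshold (2 s for excitatory, 400 ms for inhibitory neurons).  A
    candidate burst is kept only if it has at least
    ``min_spikes_per_burst`` spikes and its onset falls between some SIC
    window's onset and the window's offset plus the gap threshold.
    """
    if gap is None:
        gap = BURST_GAP[cell_kind]
    t = np.sort(np.asarray(spike_times, dtype=float))
    onsets, durations, counts = [], [], []
    if len(t):
        starts = [0]
        for i in range(1, len(t)):
            if t[i] - t[i - 1] >= gap:
                starts.append(i)
        starts.append(len(t))
        for s, e in zip(starts[:-1], starts[1:]):
            onset = t[s]
            if e - s < min_spikes_per_burst:
                continue
            if not any(on <= onset <= off + gap for on, off in sic_windows):
                continue
            onsets.append(onset)
            durations.append(t[e - 1] - t[s])
            counts.append(e - s)
    return BurstRow(onsets=np.asarray(onsets), durations=np.asarray(durations),
                    n_spikes=np.asarray(counts, dtype=np.int64))


def detect_transients(times: np.ndarray, ca: np.ndarray, threshold: float,
                      merge_gap: float = 500.0) -> TransientRow:
    """Calcium transients of one astrocyte by threshold crossing.

    ``threshold`` should be the calcium level above which a SIC is
    generated (theta_SIC + 1 nM, expressed in uM).  Upward crossings open
    a transient, downward crossings close it; transients separated by
    less than ``merge_gap`` ms are merged, and the per-transient peak is
    recorded.
    """
    intervals = _intervals_from_mask(np.asarray(times, float),
                                     np.asarray(ca) > threshold, merge_gap)
    onsets = np.array([on for on, _ in intervals])
    offsets = np.array([off for _, off in intervals])
    peaks = np.empty(len(intervals))
    t = np.asarray(times, float)
    for i, (on, off) in enumerate(intervals):
        seg = (t >= on) & (t <= off)
        peaks[i] = float(np.max(np.asarray(ca)[seg]))
    return TransientRow(onsets=onsets, offsets=offsets, peaks=peaks)


def burst_onset_distance(bursts_i: np.ndarray, bursts_j: np.ndarray,
                         method: str = "greedy") -> np.ndarray:
    """Distances between matched burst onsets of two neurons.

    Each onset of the shorter list is matched to a distinct onset of the
    other list and the absolute differences (ms) are returned.  The
    default ``greedy`` matcher sorts candidate pairs by absolute onset
    difference and accepts them in that order; ``optimal`` solves the
    minimal-total-distance assignment instead.  The matcher is pluggable
    because for well-separated bursts (spacing much larger than the
    typical offset) the two coincide.
    """
    a = np.sort(np.asarray(bursts_i, dtype=float))
    b = np.sort(np.asarray(bursts_j, dtype=float))
    if len(a) == 0 or len(b) == 0:
        return np.empty(0)
    d = np.abs(a[:, None] - b[None, :])
    if method == "optimal":
        from scipy.optimize import linear_sum_assignment
        if len(a) <= len(b):
            rows, cols = linear_sum_assignment(d)
        else:
            cols, rows = linear_sum_assignment(d.T)
        return d[rows, cols]
    if method != "greedy":
        raise ValueError(f"unknown matching method {method!r}")
    order = np.argsort(d, axis=None, kind="stable")
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    out = []
    n_match = min(len(a), len(b))
    for flat in order:
        i, j = divmod(flat, len(b))
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        out.append(d[i, j])
        if len(out) == n_match:
            break
    return np.asarray(out)


def group_contrast(values_within: np.ndarray, values_all: np.ndarray,
                   n_tests: int = 1) -> tuple[float, float]:
    """Two-sample KS statistic and Bonferroni-corrected p-value."""
    vw = np.asarray(values_within, float)
    va = np.asarray(values_all, float)
    vw = vw[~np.isnan(vw)]
    va = va[~np.isnan(va)]
    if len(vw) == 0 or len(va) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(vw, va)
    return float(res.statistic), float(min(1.0, res.pvalue * n_tests))
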