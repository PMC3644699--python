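"""Threshold spike detection, waveform features, and fast 1-D online sorting.

Detection triggers on threshold crossings of the spike-band signal, with an
automatic threshold derived from a robust (median-based) noise estimate.
Each triggered waveform is reduced to three features — maximum amplitude,
minimum amplitude, and the trough-to-zero crossing time — which are
combined into a single scalar and clustered in one dimension into at most
four units per electrode.  The sorter needs no user intervention and is
pluggable: any callable with the same signature can be registered in its
place.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import silhouette_score

__all__ = [
    "ThresholdSpec",
    "SpikeEvent",
    "InvalidThresholdError",
    "auto_threshold",
    "detect_spikes",
    "spike_features",
    "sort_spikes_1d",
    "spike_rate",
    "SpikeEventWriter",
    "register_sorter",
    "get_sorter",
    "MAX_UNITS",
]

#: hard cap on sorted units per electrode
MAX_UNITS = 4

#: scale factor turning the median absolute deviation of a Gaussian into
#: its standard deviation
_MAD_TO_SD = 0.6745


class InvalidThresholdError(ValueError):
    """The noise estimate is degenerate (e.g. constant input)."""


@dataclass(frozen=True)
class ThresholdSpec:
    """How to derive the per-channel spike threshold.

    ``auto`` mode: threshold magnitude is ``k`` robust noise standard
    deviations.  ``manual`` mode: ``value`` is used directly (µV, signed).
    """

    mode: str = "auto"  # 'auto' | 'manual'
    k: float = 4.0
    value: float = 0.0
    polarity: str = "negative"  # 'negative' | 'positive'

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "manual"):
            raise ValueError("mode must be 'auto' or 'manual'")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")
        if self.mode == "auto" and self.k <= 0:
            raise ValueError("k must be positive in auto mode")
        if self.mode == "manual" and not np.isfinite(self.value):
            raise ValueError("manual threshold must be finite")


@dataclass
class SpikeEvent:
    """One triggered spike waveform with its scalar features."""

    channel: int
    t: float  # s, time of threshold crossing
    sample_index: int  # absolute sample of the crossing
    waveform: np.ndarray  # µV, trough-aligned window
    vmax: float
    vmin: float
    t_zc_ms: float  # trough-to-zero-crossing time
    unit: int | None = None  # 0..3 after sorting


def auto_threshold(
    x: np.ndarray, spec: ThresholdSpec = ThresholdSpec(), fs: float | None = None,
    min_duration_s: float = 1.0,
) -> float:
    """Spike threshold in µV for one channel.

    In auto mode the noise SD is estimated robustly as the median absolute
    deviation about the median, scaled by 0.6745 (insensitive to the spikes
    themselves), and the threshold is ``-k * sd`` for negative polarity,
    ``+k * sd`` for positive.  Recompute on demand, not per block.
    """
    if spec.mode == "manual":
        return float(spec.value)
    x = np.asarray(x, dtype=float).ravel()
    if fs is not None and x.size < min_duration_s * fs:
        raise ValueError(
            f"need at least {min_duration_s} s of data to estimate the noise level"
        )
    sd = float(np.median(np.abs(x - np.median(x))) / _MAD_TO_SD)
    if sd == 0.0:
        raise InvalidThresholdError("constant input: noise estimate is zero")
    return -spec.k * sd if spec.polarity == "negative" else spec.k * sd


def detect_spikes(
    x: np.ndarray,
    fs: float,
    threshold: float,
    window_ms: tuple[float, float] = (0.5, 1.0),
    refractory_ms: float = 1.0,
    channel: int = 0,
    start_index: int = 0,
) -> list[SpikeEvent]:
    """Detect threshold crossings on one channel and cut their waveforms.

    The sign of ``threshold`` selects the polarity: negative thresholds
    trigger when the signal goes below them, positive when above.  An event
    is registered at the first sample beyond the threshold; crossings
    within ``refractory_ms`` of an accepted event are suppressed.  The
    waveform is cut around the extremum adjacent to the crossing
    (``window_ms = (pre, post)``); events whose window would run off either
    end of the data are dropped.
    """
    if threshold == 0:
        raise ValueError("threshold must be nonzero")
    x = np.asarray(x, dtype=float).ravel()
    sign = -1.0 if threshold < 0 else 1.0
    beyond = (sign * x) > (sign * threshold)
    # first samples beyond threshold
    crossings = np.flatnonzero(beyond & ~np.r_[False, beyond[:-1]])

    pre_n = int(round(window_ms[0] / 1e3 * fs))
    post_n = int(round(window_ms[1] / 1e3 * fs))
    refr_n = int(round(refractory_ms / 1e3 * fs))
    events: list[SpikeEvent] = []
    last = -np.inf
    for c in crossings:
        if c - last < refr_n:
            continue
        last = c
        # align on the extremum within the post window after the crossing
        seg = x[c : c + post_n + 1]
        if seg.size == 0:
            continue
        ext = c + (int(np.argmin(seg)) if sign < 0 else int(np.argmax(seg)))
        lo, hi = ext - pre_n, ext + post_n + 1
        if lo < 0 or hi > x.size:
            continue  # incomplete window at a stream edge
        w = x[lo:hi].copy()
        vmax, vmin, t_zc = spike_features(w, fs)
        events.append(
            SpikeEvent(
                channel=channel,
                t=c / fs,
                sample_index=start_index + int(c),
                waveform=w,
                vmax=vmax,
                vmin=vmin,
                t_zc_ms=t_zc,
            )
        )
    return events


def spike_features(w: np.ndarray, fs: float) -> tuple[float, float, float]:
    """(vmax, vmin, trough-to-zero time in ms) of one waveform.

    The zero-crossing feature is the time from the trough (global minimum)
    to the first sign change after it; if the waveform never crosses zero
    again, the time to the window end is used as a sentinel.
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("empty waveform")
    vmax = float(np.max(w))
    vmin = float(np.min(w))
    trough = int(np.argmin(w))
    after = w[trough:]
    signs = np.sign(after)
    # first index after the trough where the sign differs from the trough's
    changed = np.flatnonzero(signs[1:] != signs[0])
    if signs[0] == 0 or changed.size == 0:
        n_zc = w.size - 1 - trough  # sentinel: window end
    else:
        n_zc = int(changed[0]) + 1
    return vmax, vmin, n_zc / fs * 1e3


def _kmeans_1d(scores: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means with sorted-quantile initialisation."""
    centers = np.quantile(scores, (np.arange(k) + 0.5) / k)
    labels = np.full(scores.size, -1, dtype=int)
    for _ in range(max_iter):
        d = np.abs(scores[:, None] - centers[None, :])
        new_labels = np.argmin(d, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = scores[mask].mean()
    return labels


def _adjacent_separation(scores: np.ndarray, labels: np.ndarray) -> float:
    """Smallest d' between neighbouring 1-D clusters.

    For clusters ordered by centre, d' = gap between centres over the sum
    of within-cluster spreads.  Splitting a unimodal cloud gives d' near
    1.3; genuinely distinct units sit well above 2.
    """
    order = np.argsort(
        [scores[labels == u].mean() for u in np.unique(labels)]
    )
    units = np.unique(labels)[order]
    worst = np.inf
    for a, b in zip(units[:-1], units[1:]):
        sa, sb = scores[labels == a], scores[labels == b]
        spread = sa.std() + sb.std()
        gap = abs(sb.mean() - sa.mean())
        worst = min(worst, gap / spread if spread > 0 else np.inf)
    return worst


def sort_spikes_1d(
    events: Sequence[SpikeEvent],
    max_units: int = MAX_UNITS,
    min_events: int = 10,
    min_separation: float = 2.0,
    min_cluster_frac: float = 0.01,
) -> np.ndarray:
    """Assign unit labels by clustering a single scalar per spike.

    The three features (vmax, vmin, t_zc) are z-scored and projected onto
    their first principal axis; the resulting scores are clustered with
    deterministic 1-D k-means for k = 1..``max_units``.  A candidate k is
    valid when its smallest cluster holds at least ``min_cluster_frac`` of
    events and every pair of neighbouring clusters is separated by at
    least ``min_separation`` d' (this rejects splits of a single unimodal
    cloud, which score d' around 1.3); among valid candidates the largest
    silhouette wins, ties resolving to the smaller k, and with no valid
    candidate all events form one cluster.  Labels are renumbered by
    descending mean |vmin| (unit 0 = biggest spikes).  The result depends
    only on the multiset of events, so it is invariant to event order.

    Modifies ``event.unit`` in place and returns the label array.
    """
    n = len(events)
    if n == 0:
        return np.empty(0, dtype=int)
    labels = np.zeros(n, dtype=int)
    if n >= min_events:
        feats = np.array([[e.vmax, e.vmin, e.t_zc_ms] for e in events])
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        z = (feats - mu) / sd
        # first principal axis; sign fixed for determinism
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        axis = vt[0]
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        scores = z @ axis
        floor = max(1, int(np.ceil(min_cluster_frac * n)))
        best_k, best_sil = 1, -np.inf
        for k in range(2, min(max_units, n) + 1):
            cand = _kmeans_1d(scores, k)
            sizes = np.bincount(cand, minlength=k)
            if sizes.min() < floor or len(np.unique(cand)) < k:
                continue
            if _adjacent_separation(scores, cand) < min_separation:
                continue
            sil = silhouette_score(scores[:, None], cand)
            if sil > best_sil + 1e-12:  # ties resolve to the smaller k
                best_k, best_sil = k, sil
        if best_k > 1:
            labels = _kmeans_1d(scores, best_k)
    # renumber by descending mean |vmin|
    vmin = np.array([e.vmin for e in events])
    order = sorted(
        np.unique(labels), key=lambda u: -np.abs(vmin[labels == u]).mean()
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[u] for u in labels], dtype=int)
    for e, u in zip(events, labels):
        e.unit = int(u)
    return labels


def spike_rate(
    events: Sequence[SpikeEvent] | Sequence[float],
    window: float,
    now: float | None = None,
) -> float:
    """Instantaneous rate: trailing-window event count / window (Hz)."""
    if window <= 0:
        raise ValueError("window must be positive")
    times = np.asarray(
        [e.t if isinstance(e, SpikeEvent) else float(e) for e in events]
    )
    if times.size == 0:
        return 0.0
    if now is None:
        now = float(times.max())
    count = int(np.sum((times > now - window) & (times <= now)))
    return count / window


# --------------------------------------------------------------------------
# event persistence

class SpikeEventWriter:
    """Append-only spike-event table (CSV) with a self-describing sidecar.

    Spike times are flushed incrementally so that online analyses outside
    the acquisition process can follow the file as it grows.
    """

    HEADER = ["trial", "channel", "unit", "sample_index", "time_s",
              "vmin_uV", "vmax_uV"]

    def __init__(self, path: str | Path, fs: float,
                 window_ms: tuple[float, float] = (0.5, 1.0)) -> None:
        self.path = Path(path)
        self._fh = open(self.path, "w", newline="")
        self._writer = csv.writer(self._fh)
        self._writer.writerow(self.HEADER)
        sidecar = self.path.with_suffix(self.path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"fs": fs, "pre_ms": window_ms[0], "post_ms": window_ms[1]},
            indent=2,
        ))

    def write(self, trial: int, events: Sequence[SpikeEvent]) -> None:
        for e in events:
            self._writer.writerow(
                [trial, e.channel, -1 if e.unit is None else e.unit,
                 e.sample_index, f"{e.t:.6f}", f"{e.vmin:.3f}", f"{e.vmax:.3f}"]
            )
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "SpikeEventWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


# --------------------------------------------------------------------------
# pluggable sorter registry

Sorter = Callable[[Sequence[SpikeEvent]], np.ndarray]
_SORTERS: dict[str, Sorter] = {}


def register_sorter(name: str, fn: Sorter | None = None):
    """Register a spike sorter under a name (usable as a decorator)."""
    def _register(f: Sorter) -> Sorter:
        _SORTERS[name] = f
        return f

    return _register(fn) if fn is not None else _register


def get_sorter(name: str = "amplitude-1d") -> Sorter:
    try:
        return _SORTERS[name]
    except KeyError:
        raise KeyError(
            f"unknown sorter {name!r}; registered: {sorted(_SORTERS)}"
        ) from None


register_sorter("amplitude-1d", sort_spikes_1d)
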