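"""Streaming signal conditioning for multichannel voltage data.

All operators work on :class:`SampleBlock` objects (channels x samples, µV)
and the streaming ones carry filter state across blocks, so processing a
stream chunk-by-chunk yields exactly the same samples as processing the
concatenated recording in one call.  Filters are causal: this is an online
system and zero-phase filtering would require the future.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.signal

__all__ = [
    "SampleBlock",
    "FilterSpec",
    "ReferenceGroups",
    "BandpassFilter",
    "NotchFilter",
    "ConsecutiveAverageFilter",
    "common_average_reference",
    "short_term_spectrum",
    "band_power",
    "decimate_minmax",
    "audio_peak_mix",
    "chunk_signal",
    "concat_blocks",
    "LFP_SPEC",
    "SPIKE_SPEC",
    "SPIKE_SPEC_WIDE",
    "EEG_BANDS",
]


@dataclass
class SampleBlock:
    """One chunk of a multichannel stream.

    ``data`` is a ``(n_channels, n_samples)`` float array in µV, ``fs`` the
    sampling rate in Hz and ``start_index`` the absolute sample offset of
    the first column within the stream.
    """

    data: np.ndarray
    fs: float
    start_index: int = 0

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(d)):
            raise ValueError("SampleBlock data must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.data = d

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def chunk_signal(
    data: np.ndarray, fs: float, chunk_samples: int, start_index: int = 0
) -> Iterator[SampleBlock]:
    """Split a (channels x samples) array into a stream of SampleBlocks."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    for s in range(0, data.shape[1], chunk_samples):
        yield SampleBlock(data[:, s : s + chunk_samples], fs, start_index + s)


def concat_blocks(blocks: Iterable[SampleBlock]) -> SampleBlock:
    """Concatenate a stream back into a single block (testing/offline use)."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("empty stream")
    data = np.concatenate([b.data for b in blocks], axis=1)
    return SampleBlock(data, blocks[0].fs, blocks[0].start_index)


# --------------------------------------------------------------------------
# filter specifications

@dataclass(frozen=True)
class FilterSpec:
    """Band-edge description of a causal IIR filter.

    ``low``/``high`` are corner frequencies in Hz; ``None`` on one side
    turns the filter into a pure low-/high-pass.  ``order`` is the design
    order of the Butterworth prototype.
    """

    low: float | None = None
    high: float | None = None
    order: int = 4

    def __post_init__(self) -> None:
        if self.low is None and self.high is None:
            raise ValueError("at least one band edge required")
        if self.low is not None and self.low < 0:
            raise ValueError("low edge must be >= 0")
        if (
            self.low is not None
            and self.high is not None
            and not self.low < self.high
        ):
            raise ValueError("need low < high")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.low is not None and self.high is not None and self.order % 2:
            raise ValueError("bandpass order must be even (poles split per edge)")

    @property
    def kind(self) -> str:
        if self.low is not None and self.high is not None:
            return "bandpass"
        return "lowpass" if self.low is None else "highpass"

    def validate_for_fs(self, fs: float) -> None:
        nyq = fs / 2
        for edge in (self.low, self.high):
            if edge is not None and edge >= nyq:
                raise ValueError(f"band edge {edge} Hz >= Nyquist {nyq} Hz")


#: local field potential band: low-pass at 300 Hz
LFP_SPEC = FilterSpec(low=None, high=300.0)
#: spike band: 300-6000 Hz
SPIKE_SPEC = FilterSpec(low=300.0, high=6000.0)
#: wider spike-band variant sometimes used for noise characterisation
SPIKE_SPEC_WIDE = FilterSpec(low=300.0, high=7000.0)

#: EEG band edges in Hz for spectrum summaries
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 80.0),
}


class _SosStreamingFilter:
    """Causal second-order-section filter with per-channel persistent state."""

    def __init__(self, sos: np.ndarray) -> None:
        self._sos = sos
        self._zi: np.ndarray | None = None

    def process(self, block: SampleBlock) -> SampleBlock:
        if self._zi is None:
            # zero initial conditions: stream assumed to start from rest
            self._zi = np.zeros(
                (self._sos.shape[0], block.n_channels, 2), dtype=float
            )
        out, self._zi = scipy.signal.sosfilt(
            self._sos, block.data, axis=1, zi=self._zi
        )
        return SampleBlock(out, block.fs, block.start_index)

    def __call__(self, stream: Iterable[SampleBlock]) -> Iterator[SampleBlock]:
        for block in stream:
            yield self.process(block)


class BandpassFilter(_SosStreamingFilter):
    """Streaming Butterworth band-/low-/high-pass filter."""

    def __init__(self, spec: FilterSpec, fs: float) -> None:
        spec.validate_for_fs(fs)
        if spec.kind == "bandpass":
            wn: float | list[float] = [spec.low, spec.high]
            # scipy doubles the prototype order for bandpass designs;
            # FilterSpec.order is the true filter order
            design_order = spec.order // 2
        elif spec.kind == "lowpass":
            wn = spec.high
            design_order = spec.order
        else:
            wn = spec.low
            design_order = spec.order
        sos = scipy.signal.butter(
            design_order, wn, btype=spec.kind, fs=fs, output="sos"
        )
        super().__init__(sos)
        self.spec = spec
        self.fs = fs


class NotchFilter(_SosStreamingFilter):
    """Streaming narrow-band notch for power-line hum removal.

    Second-order IIR notch; ``bandwidth`` is the -3 dB width in Hz.  Line
    frequencies other than 50/60 Hz are accepted (harmonics, odd mains) but
    flagged with a warning.
    """

    def __init__(self, line_freq: float, fs: float, bandwidth: float = 4.0) -> None:
        if line_freq >= fs / 2:
            raise ValueError(f"notch frequency {line_freq} Hz >= Nyquist")
        if line_freq not in (50.0, 60.0):
            import warnings

            warnings.warn(
                f"notch at {line_freq} Hz is not a standard mains frequency",
                stacklevel=2,
            )
        b, a = scipy.signal.iirnotch(line_freq, Q=line_freq / bandwidth, fs=fs)
        super().__init__(scipy.signal.tf2sos(b, a))
        self.line_freq = line_freq
        self.fs = fs


class ConsecutiveAverageFilter:
    """Subtract a running period-locked template from the stream.

    Removes regularly repeating but non-sinusoidal noise: the template is
    the mean of the last ``n_periods`` periods at each phase, and is
    subtracted phase-locked to the period.  Phases with no history yet
    (warm-up) pass through unchanged.

    Non-integer periods (e.g. 60 Hz hum at 31.25 kHz = 520.83 samples) are
    supported by accumulating phase in fractional samples; the template
    lives on a 1-sample grid and is read/written with linear interpolation,
    with the per-bin history kept as an ``n_periods``-deep running mean.
    """

    def __init__(self, period: float, n_periods: int, n_channels: int) -> None:
        if period < 2:
            raise ValueError("period must be >= 2 samples")
        if n_periods < 2:
            raise ValueError("n_periods must be >= 2")
        self.period = float(period)
        self.n_periods = int(n_periods)
        self._integer = float(period).is_integer()
        p_bins = int(np.ceil(self.period))
        if self._integer:
            # ring buffer of the last n_periods periods, filled lazily
            self._history = np.zeros((n_channels, n_periods, p_bins))
            self._count = np.zeros(p_bins, dtype=int)
            self._write_row = np.zeros(p_bins, dtype=int)
        else:
            self._template = np.zeros((n_channels, p_bins))
            self._seen = np.zeros(p_bins)
        self._phase = 0.0
        self._p_bins = p_bins

    def process(self, block: SampleBlock) -> SampleBlock:
        x = block.data
        out = np.empty_like(x)
        if self._integer:
            p = self._p_bins
            phase = int(self._phase)
            for j in range(x.shape[1]):
                ph = (phase + j) % p
                c = self._count[ph]
                if c > 0:
                    template = self._history[:, :c, ph].mean(axis=1)
                else:
                    template = 0.0
                out[:, j] = x[:, j] - template
                row = self._write_row[ph]
                self._history[:, row, ph] = x[:, j]
                self._write_row[ph] = (row + 1) % self.n_periods
                self._count[ph] = min(c + 1, self.n_periods)
            self._phase = (phase + x.shape[1]) % p
        else:
            alpha = 1.0 / self.n_periods
            for j in range(x.shape[1]):
                ph = self._phase
                i0 = int(ph) % self._p_bins
                i1 = (i0 + 1) % self._p_bins
                frac = ph - int(ph)
                w = (1 - frac) * min(self._seen[i0], 1.0) + frac * min(
                    self._seen[i1], 1.0
                )
                template = (1 - frac) * self._template[:, i0] + frac * self._template[
                    :, i1
                ]
                out[:, j] = x[:, j] - w * template
                for i, wt in ((i0, 1 - frac), (i1, frac)):
                    if self._seen[i] == 0:
                        self._template[:, i] = x[:, j]
                    else:
                        self._template[:, i] += wt * alpha * (
                            x[:, j] - self._template[:, i]
                        )
                    self._seen[i] = min(self._seen[i] + wt, self.n_periods)
                self._phase = (ph + 1.0) % self.period
        return SampleBlock(out, block.fs, block.start_index)

    def __call__(self, stream: Iterable[SampleBlock]) -> Iterator[SampleBlock]:
        for block in stream:
            yield self.process(block)


# --------------------------------------------------------------------------
# stateless per-block operators

@dataclass(frozen=True)
class ReferenceGroups:
    """Pairs of (target channel set, reference channel set).

    For each pair, every target channel gets the per-sample mean of the
    reference set subtracted.  Channels in no target set pass through.
    """

    groups: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[Sequence[int], Sequence[int]]]
    ) -> "ReferenceGroups":
        return cls(
            tuple(
                (tuple(int(t) for t in tg), tuple(int(r) for r in rf))
                for tg, rf in pairs
            )
        )

    @classmethod
    def all_to_all(cls, n_channels: int) -> "ReferenceGroups":
        chans = tuple(range(n_channels))
        return cls(((chans, chans),))

    def validate(self, n_channels: int) -> None:
        seen: set[int] = set()
        for targets, refs in self.groups:
            if not refs:
                raise ValueError("empty reference set")
            for c in (*targets, *refs):
                if not 0 <= c < n_channels:
                    raise ValueError(f"channel {c} out of range 0..{n_channels - 1}")
            dup = seen & set(targets)
            if dup:
                raise ValueError(f"channels {sorted(dup)} targeted by two groups")
            seen |= set(targets)


def common_average_reference(
    block: SampleBlock, groups: ReferenceGroups
) -> SampleBlock:
    """Subtract per-group common averages (shared-noise cancellation)."""
    groups.validate(block.n_channels)
    out = block.data.copy()
    for targets, refs in groups.groups:
        ref_mean = block.data[list(refs)].mean(axis=0)
        out[list(targets)] -= ref_mean
    return SampleBlock(out, block.fs, block.start_index)


def short_term_spectrum(
    x: np.ndarray,
    fs: float,
    window: int,
    overlap: float = 0.5,
    window_fn: str = "hann",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectral density of one channel.

    Parameters
    ----------
    x
        Single-channel signal (µV).
    window
        Segment length in samples.
    overlap
        Fractional overlap between consecutive segments, in [0, 1).

    Returns
    -------
    times, freqs, power
        ``power`` has shape (n_frames, n_freqs) in µV²/Hz; integrating a
        frame over frequency recovers that frame's signal power.
    """
    x = np.asarray(x, dtype=float).ravel()
    if window > x.size:
        raise ValueError("window longer than data")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    noverlap = int(round(window * overlap))
    freqs, times, sxx = scipy.signal.spectrogram(
        x,
        fs=fs,
        window=window_fn,
        nperseg=window,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return times, freqs, sxx.T


def band_power(
    freqs: np.ndarray,
    power: np.ndarray,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, np.ndarray]:
    """Integrate a (frames x freqs) PSD over named bands (µV² per frame)."""
    if bands is None:
        bands = EEG_BANDS
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    out = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        out[name] = power[:, mask].sum(axis=1) * df
    return out


def decimate_minmax(x: np.ndarray, n_buckets: int) -> tuple[np.ndarray, np.ndarray]:
    """Min/max envelope over ``n_buckets`` even partitions of one channel.

    Keeping both extrema per bucket guarantees that no spike is lost when a
    trace is thinned for display; the last bucket may be shorter when the
    length is not divisible.
    """
    x = np.asarray(x, dtype=float).ravel()
    if n_buckets <= 0:
        raise ValueError("n_buckets must be positive")
    if n_buckets > x.size:
        raise ValueError("n_buckets exceeds number of samples")
    size = int(np.ceil(x.size / n_buckets))
    edges = np.arange(0, x.size, size)
    mins = np.minimum.reduceat(x, edges)
    maxs = np.maximum.reduceat(x, edges)
    return mins, maxs


def audio_peak_mix(block: SampleBlock, selected: Sequence[int]) -> np.ndarray:
    """Mix selected channels into one trace by per-sample peak selection.

    At each sample the output takes the value (sign preserved) of whichever
    selected channel has the largest absolute value, so a spike on one
    channel is never averaged away by quiet neighbours.
    """
    sel = list(dict.fromkeys(int(c) for c in selected))
    if not sel:
        raise ValueError("empty channel selection")
    sub = block.data[sel]
    idx = np.argmax(np.abs(sub), axis=0)
    return sub[idx, np.arange(sub.shape[1])]
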