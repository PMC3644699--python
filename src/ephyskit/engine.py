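"""Trial-based streaming acquisition and on-disk raw format.

The engine pulls :class:`~ephyskit.dsp.SampleBlock` streams from a source
(simulated here; a real DAQ would sit behind the same iterator interface),
writes every sample to disk raw-first, and only then hands blocks to
processing/display callbacks.  Callbacks are protected: an exception in one
is logged and counted but never interrupts acquisition.  Disk-write
failures are *not* protected and abort the trial with an error status.

Raw files are int16, little-endian, channel-interleaved frames
(``<base>.i16raw``) with a JSON sidecar (``<base>.json``) carrying sampling
rate, channel count, µV-per-LSB scale and bookkeeping, so a recording is
readable with nothing but numpy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np
import scipy.fft

from .dsp import SampleBlock

__all__ = [
    "AcquisitionConfig",
    "TrialRecord",
    "SoftwareTrigger",
    "RawWriter",
    "read_raw",
    "iter_raw",
    "run_trial",
    "save_config",
    "load_config",
    "ReliabilityReport",
    "reliability_check",
]

log = logging.getLogger(__name__)

RAW_SUFFIX = ".i16raw"


@dataclass(frozen=True)
class AcquisitionConfig:
    """Everything needed to run and replay an acquisition session.

    ``scale_uv_per_lsb`` maps µV to int16 codes; the default of ``None``
    derives it from ``input_range_v`` so the full range fits int16.
    ``arrays`` holds geometry documents (see :mod:`ephyskit.geometry`);
    multiple simultaneous arrays occupy disjoint channel ranges.
    ``chain`` is the ordered processing-chain description: a list of stage
    dicts, each with a ``stage`` name, an ``enabled`` flag and parameters.
    """

    fs: float = 25_000.0
    n_channels: int = 16
    input_range_v: float = 5.0
    scale_uv_per_lsb: float | None = None
    save_dir: str = "."
    arrays: tuple = ()
    chain: tuple = ()
    channel_mask: tuple | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.input_range_v <= 0:
            raise ValueError("input_range_v must be positive")
        if self.scale_uv_per_lsb is not None and self.scale_uv_per_lsb <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "arrays", _freeze(self.arrays))
        object.__setattr__(self, "chain", _freeze(self.chain))
        if self.channel_mask is not None:
            object.__setattr__(
                self, "channel_mask", tuple(int(c) for c in self.channel_mask)
            )

    @property
    def scale(self) -> float:
        """Effective µV per least-significant bit."""
        if self.scale_uv_per_lsb is not None:
            return self.scale_uv_per_lsb
        return self.input_range_v * 1e6 / 32768.0


def _freeze(obj):
    """Recursively convert lists/dicts to hashable tuples for frozen configs."""
    if isinstance(obj, dict):
        return tuple(sorted((k, _freeze(v)) for k, v in obj.items()))
    if isinstance(obj, (list, tuple)):
        return tuple(_freeze(v) for v in obj)
    return obj


def _thaw(obj):
    """Inverse of :func:`_freeze` for JSON serialization."""
    if isinstance(obj, tuple):
        if obj and all(
            isinstance(e, tuple) and len(e) == 2 and isinstance(e[0], str)
            for e in obj
        ):
            return {k: _thaw(v) for k, v in obj}
        return [_thaw(v) for v in obj]
    return obj


@dataclass
class TrialRecord:
    """Outcome of one acquisition epoch."""

    index: int
    base_name: str
    raw_file: str
    event_file: str | None
    n_samples: int
    status: str  # 'prepared' | 'running' | 'stopped' | 'error'
    callback_errors: int = 0
    clip_count: int = 0


class SoftwareTrigger:
    """Stand-in for the hardware digital start line: fires once."""

    def __init__(self, fired: bool = True) -> None:
        self._fired = fired

    def fire(self) -> None:
        self._fired = True

    def is_set(self) -> bool:
        return self._fired


class RawWriter:
    """Incremental int16 raw-file writer with sidecar metadata.

    Values outside the representable range are clipped and counted, never
    raised: mid-trial an outlier must not abort acquisition.
    """

    def __init__(
        self,
        base: str | Path,
        fs: float,
        n_channels: int,
        scale_uv_per_lsb: float,
        geometry_name: str = "",
    ) -> None:
        if scale_uv_per_lsb <= 0:
            raise ValueError("scale must be positive")
        self.base = Path(base)
        self.raw_path = self.base.with_suffix(RAW_SUFFIX)
        self.meta_path = self.base.with_suffix(".json")
        self.fs = fs
        self.n_channels = n_channels
        self.scale = scale_uv_per_lsb
        self.geometry_name = geometry_name
        self.n_samples = 0
        self.clip_count = 0
        self.start_time = time.time()
        self._fh = open(self.raw_path, "wb")
        self._closed = False

    def write(self, block: SampleBlock) -> None:
        if block.n_channels != self.n_channels:
            raise ValueError(
                f"block has {block.n_channels} channels, expected {self.n_channels}"
            )
        codes = np.round(block.data / self.scale)
        clipped = np.clip(codes, -32768, 32767)
        self.clip_count += int(np.sum(clipped != codes))
        # channel-interleaved frames: transpose to (samples, channels)
        frames = clipped.astype("<i2").T
        self._fh.write(frames.tobytes())
        self.n_samples += block.n_samples

    def close(self) -> None:
        if self._closed:
            return
        self._fh.close()
        self.meta_path.write_text(json.dumps(
            {
                "format": "i16raw",
                "byte_order": "little",
                "layout": "channel-interleaved frames",
                "fs": self.fs,
                "n_channels": self.n_channels,
                "scale_uv_per_lsb": self.scale,
                "geometry": self.geometry_name,
                "start_time_unix": self.start_time,
                "n_samples": self.n_samples,
                "clip_count": self.clip_count,
            },
            indent=2,
        ))
        self._closed = True

    def __enter__(self) -> "RawWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _resolve_base(path: str | Path) -> Path:
    p = Path(path)
    if p.suffix in (RAW_SUFFIX, ".json"):
        p = p.with_suffix("")
    return p


def read_raw(path: str | Path) -> tuple[SampleBlock, dict]:
    """Read a whole raw recording back into µV plus its metadata."""
    base = _resolve_base(path)
    meta = json.loads(base.with_suffix(".json").read_text())
    codes = np.fromfile(base.with_suffix(RAW_SUFFIX), dtype="<i2")
    n_ch = meta["n_channels"]
    data = codes.reshape(-1, n_ch).T.astype(float) * meta["scale_uv_per_lsb"]
    return SampleBlock(data, meta["fs"]), meta


def iter_raw(
    path: str | Path, chunk_samples: int = 65536
) -> Iterator[SampleBlock]:
    """Stream a raw recording as SampleBlocks without loading it whole."""
    base = _resolve_base(path)
    meta = json.loads(base.with_suffix(".json").read_text())
    n_ch = meta["n_channels"]
    scale = meta["scale_uv_per_lsb"]
    start = 0
    with open(base.with_suffix(RAW_SUFFIX), "rb") as fh:
        while True:
            buf = fh.read(chunk_samples * n_ch * 2)
            if not buf:
                break
            codes = np.frombuffer(buf, dtype="<i2")
            data = codes.reshape(-1, n_ch).T.astype(float) * scale
            yield SampleBlock(data, meta["fs"], start)
            start += data.shape[1]


def run_trial(
    source: Iterable[SampleBlock],
    config: AcquisitionConfig,
    base_name: str | Path,
    callbacks: Iterable[Callable[[SampleBlock], None]] = (),
    trigger: SoftwareTrigger | None = None,
    index: int = 0,
    event_file: str | None = None,
) -> TrialRecord:
    """Acquire one trial: write raw-first, then run protected callbacks.

    Samples arriving before ``trigger`` fires are discarded (two-stage
    start: the trial is prepared, acquisition begins on the trigger).  The
    source ending stops the trial.  Callback exceptions are logged and
    counted; a disk-write failure aborts with status ``error``.
    """
    trigger = trigger or SoftwareTrigger(fired=True)
    callbacks = list(callbacks)
    base = Path(config.save_dir) / Path(base_name).name
    writer = RawWriter(base, config.fs, config.n_channels, config.scale)
    record = TrialRecord(
        index=index,
        base_name=str(base),
        raw_file=str(writer.raw_path),
        event_file=event_file,
        n_samples=0,
        status="prepared",
    )
    try:
        for block in source:
            if not trigger.is_set():
                continue
            record.status = "running"
            writer.write(block)  # raw-first, unprotected
            for cb in callbacks:
                try:
                    cb(block)
                except Exception as e:
                    record.callback_errors += 1
                    log.warning(
                        "protected callback failed (%s: %s); acquisition continues",
                        type(e).__name__, e,
                    )
    except OSError:
        writer.close()
        record.status = "error"
        record.n_samples = writer.n_samples
        return record
    writer.close()
    record.n_samples = writer.n_samples
    record.clip_count = writer.clip_count
    record.status = "stopped"
    return record


# --------------------------------------------------------------------------
# config persistence

def save_config(config: AcquisitionConfig) -> dict:
    """JSON-serializable document for an acquisition config."""
    doc = dataclasses.asdict(config)
    doc["arrays"] = _thaw(config.arrays)
    doc["chain"] = _thaw(config.chain)
    doc["channel_mask"] = (
        list(config.channel_mask) if config.channel_mask is not None else None
    )
    return doc


def load_config(doc: dict | str) -> AcquisitionConfig:
    """Inverse of :func:`save_config`; unknown fields are rejected by name."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    known = {f.name for f in dataclasses.fields(AcquisitionConfig)}
    for key in doc:
        if key not in known:
            raise ValueError(f"unknown config field: {key!r}")
    return AcquisitionConfig(**doc)


# --------------------------------------------------------------------------
# reliability check

@dataclass
class ReliabilityReport:
    """Outcome of a sample-integrity / synchronisation check."""

    mode: str  # 'periodic' | 'sinusoid'
    n_channels: int
    n_samples: int
    lags: np.ndarray  # cross-correlation peak lag vs channel 0 (samples)
    lag_mod_period: np.ndarray  # lags wrapped to one period (samples)
    ptp_deviation: float | None  # periodic mode: max |ptp - median| (µV)
    period_samples: float | None  # sinusoid mode: correlation period
    frequency_hz: float | None  # sinusoid mode: 1 / period
    passed: bool


def _cross_correlation_lags(data: np.ndarray) -> np.ndarray:
    """Peak lag of each channel's correlation with channel 0 (circular FFT)."""
    n = data.shape[1]
    nfft = scipy.fft.next_fast_len(2 * n - 1)
    ref = scipy.fft.rfft(data[0], nfft)
    lags = np.zeros(data.shape[0], dtype=int)
    for i in range(data.shape[0]):
        spec = scipy.fft.rfft(data[i], nfft) * np.conj(ref)
        # r[m] = sum_k x_i[k] x_0[k - m]: peak at +d when channel i is
        # delayed by d samples relative to channel 0
        r = scipy.fft.irfft(spec, nfft)
        m = int(np.argmax(r))
        lags[i] = m - nfft if m > nfft // 2 else m
    return lags


def _dominant_cross_frequency(data: np.ndarray, fs: float) -> float:
    """Dominant frequency of the channel-vs-channel-0 correlation functions.

    The cross-correlation of channel i with channel 0 has the same spectral
    support as the shared signal; its dominant frequency is located from
    the cross-spectrum magnitude (averaged over channels) with parabolic
    interpolation around the peak bin.
    """
    n = data.shape[1]
    nfft = scipy.fft.next_fast_len(2 * n - 1)
    ref = np.conj(scipy.fft.rfft(data[0], nfft))
    mag = np.zeros(nfft // 2 + 1)
    others = range(1, data.shape[0]) if data.shape[0] > 1 else [0]
    for i in others:
        mag += np.abs(scipy.fft.rfft(data[i], nfft) * ref)
    k = int(np.argmax(mag[1:])) + 1  # skip DC
    if 1 <= k < mag.size - 1 and mag[k] > 0:
        lm, lc, lp = mag[k - 1], mag[k], mag[k + 1]
        denom = lm - 2 * lc + lp
        delta = 0.5 * (lm - lp) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    return (k + delta) * fs / nfft


def reliability_check(
    recording: SampleBlock | np.ndarray,
    mode: str,
    period: float | None = None,
    freq: float | None = None,
    fs: float | None = None,
    jitter_tol_samples: float = 1.0,
) -> ReliabilityReport:
    """Verify that no samples were dropped and channels stayed in sync.

    ``periodic`` mode (repeating digital pattern): folds each channel into
    consecutive periods and computes the per-period peak-to-peak amplitude;
    the check passes only if the maximum deviation from the median
    peak-to-peak is exactly zero and every channel's correlation-peak lag
    against channel 0 is exactly zero.

    ``sinusoid`` mode (common sinusoid with per-channel gains): amplitudes
    are equalized per channel, correlation-peak lags must vanish modulo one
    period within ``jitter_tol_samples``, and the period of the
    cross-channel correlation is estimated (its reciprocal should recover
    the injected frequency).
    """
    if isinstance(recording, SampleBlock):
        data, fs = recording.data, recording.fs
    else:
        data = np.atleast_2d(np.asarray(recording, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if mode not in ("periodic", "sinusoid"):
        raise ValueError("mode must be 'periodic' or 'sinusoid'")

    if mode == "periodic":
        if period is None:
            raise ValueError("periodic mode requires the pattern period")
        p = int(period)
        n_per = data.shape[1] // p
        if n_per < 10:
            raise ValueError("recording shorter than 10 periods")
        folded = data[:, : n_per * p].reshape(data.shape[0], n_per, p)
        ptp = folded.max(axis=2) - folded.min(axis=2)
        deviation = float(np.max(np.abs(ptp - np.median(ptp, axis=1, keepdims=True))))
        lags = _cross_correlation_lags(data)
        lag_mod = lags.astype(float)
        passed = deviation == 0.0 and bool(np.all(lags == 0))
        return ReliabilityReport(
            mode=mode,
            n_channels=data.shape[0],
            n_samples=data.shape[1],
            lags=lags,
            lag_mod_period=lag_mod,
            ptp_deviation=deviation,
            period_samples=None,
            frequency_hz=None,
            passed=passed,
        )

    # sinusoid mode
    if freq is None and period is not None:
        freq = fs / period
    rms = np.sqrt(np.mean(data**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    eq = data / rms  # equalize per-channel gains (impedance differences)
    if freq is not None and data.shape[1] < 10 * fs / freq:
        raise ValueError("recording shorter than 10 periods")
    freq_est = _dominant_cross_frequency(eq, fs)
    p_est = fs / freq_est
    lags = _cross_correlation_lags(eq)
    lag_mod = (lags + p_est / 2) % p_est - p_est / 2
    passed = bool(np.all(np.abs(lag_mod) <= jitter_tol_samples))
    return ReliabilityReport(
        mode=mode,
        n_channels=data.shape[0],
        n_samples=data.shape[1],
        lags=lags,
        lag_mod_period=lag_mod,
        ptp_deviation=None,
        period_samples=p_est,
        frequency_hz=freq_est,
        passed=passed,
    )
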