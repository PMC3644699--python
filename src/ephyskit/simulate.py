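"""Surrogate multichannel recordings with ground truth, plus the two
reliability-test signals.

The surrogate generator emulates what an extracellular array sees: Gaussian
background noise, a slow cortical oscillation, mains hum, and extracellular
action potentials from several units per channel placed at Poisson times.
Ground truth (event times, unit identities, templates) is returned so that
detection and sorting can be scored.

Two deterministic test signals support end-to-end reliability checks of the
acquisition path: a repeating digital pattern (identical on every channel,
constant peak-to-peak per period) and a common sinusoid with per-channel
gains emulating electrode-impedance differences in a saline bath.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .dsp import SampleBlock, chunk_signal

__all__ = [
    "SimConfig",
    "GroundTruth",
    "spike_template",
    "generate_surrogate",
    "generate_bath_sinusoid",
    "generate_periodic_pattern",
]

#: enforced minimum inter-spike interval per unit (s)
REFRACTORY_S = 1e-3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the surrogate recording.

    Amplitudes are in µV.  ``units_per_channel`` is an inclusive integer
    range; the unit count of each channel is drawn from it.  ``spike_amp``
    is the range of per-unit trough amplitudes.  With a fixed ``seed`` the
    output is reproducible bit-for-bit.
    """

    n_channels: int = 16
    fs: float = 25_000.0
    duration: float = 10.0
    units_per_channel: tuple[int, int] = (1, 4)
    spike_rate: float = 5.0  # Hz per unit
    spike_amp: tuple[float, float] = (60.0, 150.0)
    spike_width_ms: float = 1.2
    noise_sd: float = 8.0
    slow_osc: tuple[float, float] = (2.0, 40.0)  # (freq Hz, amp µV)
    line_noise: tuple[float, float] = (60.0, 20.0)  # (freq Hz, amp µV)
    seed: int = 0
    #: explicit per-unit trough amplitudes (µV) applied to every channel;
    #: overrides units_per_channel/spike_amp draws for controlled scenarios
    unit_amps: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        lo, hi = self.units_per_channel
        if lo < 0 or hi < lo:
            raise ValueError("units_per_channel must be a non-negative range")
        for amp in (*self.spike_amp, self.noise_sd, self.slow_osc[1],
                    self.line_noise[1]):
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")


@dataclass
class GroundTruth:
    """True spike events and the templates that generated them."""

    #: (channel, unit_id, time_s) sorted by time; time marks the trough
    events: list[tuple[int, int, float]]
    #: (channel, unit_id) -> waveform (µV per sample)
    templates: dict[tuple[int, int], np.ndarray]
    fs: float

    def events_for_channel(self, channel: int) -> list[tuple[int, float]]:
        return [(u, t) for c, u, t in self.events if c == channel]


def spike_template(
    fs: float, width_ms: float = 1.2, amp_uV: float = 100.0
) -> tuple[np.ndarray, int]:
    """Biphasic extracellular spike template.

    Negative-then-positive sum of two Gaussians: a sharp trough of depth
    ``amp_uV`` followed by a broader positive afterwave.  Returns the
    waveform and the sample index of the trough (alignment point).
    """
    width_s = width_ms / 1e3
    n = max(int(round(width_s * fs)), 5)
    t = np.arange(n) / fs
    t_trough = 0.3 * width_s
    t_peak = 0.58 * width_s
    w = -np.exp(-0.5 * ((t - t_trough) / (0.09 * width_s)) ** 2)
    w += 0.2 * np.exp(-0.5 * ((t - t_peak) / (0.14 * width_s)) ** 2)
    w *= amp_uV / -w.min()  # trough depth exactly amp_uV
    return w, int(np.argmin(w))


def _poisson_times(
    rng: np.random.Generator, rate: float, duration: float, margin: float
) -> np.ndarray:
    """Homogeneous Poisson event times in [margin, duration-margin] with a
    refractory period enforced by thinning."""
    span = duration - 2 * margin
    if rate <= 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    times = np.sort(rng.uniform(margin, duration - margin, size=n))
    kept: list[float] = []
    last = -np.inf
    for t in times:
        if t - last >= REFRACTORY_S:
            kept.append(t)
            last = t
    return np.asarray(kept)


def generate_surrogate(
    config: SimConfig, chunk_samples: int | None = None
) -> tuple[Iterator[SampleBlock], GroundTruth]:
    """Generate a surrogate recording and its ground truth.

    Each channel is the sum of Gaussian background noise, one slow
    oscillation (random phase per channel), mains hum (common phase across
    channels, as line pickup is shared), and the channel's unit templates
    placed at Poisson times.  Randomness is split from the root seed per
    channel, so any channel is reproducible in isolation.

    Returns a block stream (chunked at ``chunk_samples``; one block if
    ``None``) and the :class:`GroundTruth`.
    """
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    data = np.zeros((config.n_channels, n))

    # mains hum: identical phase on all channels
    f_line, a_line = config.line_noise
    if a_line > 0:
        data += a_line * np.sin(2 * np.pi * f_line * t)

    root = np.random.SeedSequence(config.seed)
    channel_seeds = root.spawn(config.n_channels)
    events: list[tuple[int, int, float]] = []
    templates: dict[tuple[int, int], np.ndarray] = {}
    margin = 2 * config.spike_width_ms / 1e3

    for ch, ss in enumerate(channel_seeds):
        rng = np.random.default_rng(ss)
        if config.noise_sd > 0:
            data[ch] += rng.normal(0.0, config.noise_sd, size=n)
        f_slow, a_slow = config.slow_osc
        if a_slow > 0:
            phase = rng.uniform(0, 2 * np.pi)
            data[ch] += a_slow * np.sin(2 * np.pi * f_slow * t + phase)
        if config.unit_amps is not None:
            amps = np.sort(np.asarray(config.unit_amps, dtype=float))[::-1]
            n_units = amps.size
        else:
            n_units = int(rng.integers(config.units_per_channel[0],
                                       config.units_per_channel[1] + 1))
            amps = np.sort(
                rng.uniform(*config.spike_amp, size=n_units)
            )[::-1]  # unit 0 is the largest, matching sorter label order
        for unit in range(n_units):
            w, trough = spike_template(
                config.fs, config.spike_width_ms, float(amps[unit])
            )
            templates[(ch, unit)] = w
            for t_ev in _poisson_times(rng, config.spike_rate,
                                       config.duration, margin):
                i0 = int(round(t_ev * config.fs)) - trough
                if i0 < 0 or i0 + w.size > n:
                    continue
                data[ch, i0 : i0 + w.size] += w
                events.append((ch, unit, (i0 + trough) / config.fs))

    events.sort(key=lambda e: (e[2], e[0], e[1]))
    truth = GroundTruth(events=events, templates=templates, fs=config.fs)
    stream = chunk_signal(data, config.fs, chunk_samples or n)
    return stream, truth


def generate_bath_sinusoid(
    freq: float,
    gains: np.ndarray,
    fs: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    chunk_samples: int | None = None,
) -> Iterator[SampleBlock]:
    """Common sinusoid with per-channel gains plus independent noise.

    Emulates injecting one sinusoidal voltage into an electrode bath: every
    channel sees the same waveform scaled by its electrode's gain (the
    stand-in for impedance differences), plus its own noise.
    """
    if freq >= fs / 2:
        raise ValueError(f"frequency {freq} Hz is at or above Nyquist {fs / 2} Hz")
    gains = np.asarray(gains, dtype=float)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    common = np.sin(2 * np.pi * freq * t)
    data = gains[:, None] * common[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return chunk_signal(data, fs, chunk_samples or n)


def generate_periodic_pattern(
    period: int,
    n_channels: int,
    duration: float,
    fs: float,
    amplitude: float = 1000.0,
    chunk_samples: int | None = None,
) -> Iterator[SampleBlock]:
    """Deterministic repeating digital-style pattern, identical on all
    channels.

    One period is a linear ramp from ``-amplitude`` to ``+amplitude`` (each
    phase has a distinct level), so the peak-to-peak amplitude of every
    complete period is exactly ``2 * amplitude`` and any dropped or
    repeated sample shows up in a period-folded peak-to-peak scan and in
    cross-channel correlation lags.
    """
    if period < 2:
        raise ValueError("period must be >= 2 samples")
    n = int(round(duration * fs))
    one = np.linspace(-amplitude, amplitude, period)
    pattern = np.tile(one, n // period + 1)[:n]
    data = np.broadcast_to(pattern, (n_channels, n)).copy()
    return chunk_signal(data, fs, chunk_samples or n)
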