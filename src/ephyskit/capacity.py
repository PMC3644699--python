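"""Channel-capacity and data-rate planning for DAQ-card configurations.

Analog DAQ cards expose a fixed number of channels per card and are limited
by available PCI/PCIe or PXI slots.  Digital cards multiplex many channels
onto each digital line (one line per card is reserved for the trial
trigger), so a single card can serve over a thousand channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["CardSpec", "PRESETS", "max_channels", "data_rate", "capacity_table"]


@dataclass(frozen=True)
class CardSpec:
    """Capability of one DAQ-card configuration.

    For ``kind='analog'`` only ``channels_per_card`` applies; for
    ``kind='digital'`` a card offers ``lines_per_card`` usable digital lines
    carrying ``channels_per_line`` multiplexed channels each.
    """

    kind: str  # 'analog' | 'digital'
    max_fs: float  # Hz, per channel
    slots_available: int
    channels_per_card: int = 0
    lines_per_card: int = 0
    channels_per_line: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("analog", "digital"):
            raise ValueError(f"kind must be 'analog' or 'digital', got {self.kind!r}")
        if self.max_fs <= 0:
            raise ValueError("max_fs must be positive")
        if self.slots_available < 0:
            raise ValueError("slots_available must be >= 0")
        if self.kind == "analog" and self.channels_per_card <= 0:
            raise ValueError("analog cards need channels_per_card > 0")
        if self.kind == "digital" and (
            self.lines_per_card <= 0 or self.channels_per_line <= 0
        ):
            raise ValueError("digital cards need lines_per_card and channels_per_line > 0")


#: Named configurations for common National Instruments cards.  Digital
#: cards use 15 of 16 lines (the 16th is reserved for digital triggering).
PRESETS: dict[str, CardSpec] = {
    # 32-channel M-/X-series analog cards, internal PCI/PCIe slots
    "analog-pci": CardSpec(kind="analog", channels_per_card=32, max_fs=25_000.0,
                           slots_available=7),
    # same cards in a single 18-slot PXI chassis
    "analog-pxi": CardSpec(kind="analog", channels_per_card=32, max_fs=25_000.0,
                           slots_available=18),
    # 80-channel card for lower-rate field-potential work
    "analog-6255": CardSpec(kind="analog", channels_per_card=80, max_fs=9_375.0,
                            slots_available=7),
    # high-speed digital card reading multiplexed digital headstages
    "digital-6561": CardSpec(kind="digital", lines_per_card=15,
                             channels_per_line=96, max_fs=31_250.0,
                             slots_available=1),
}


def max_channels(spec: CardSpec) -> int:
    """Maximum simultaneous channels for a card configuration.

    Analog: slots x channels_per_card.  Digital: cards x usable lines x
    channels per line.
    """
    if spec.kind == "analog":
        return spec.slots_available * spec.channels_per_card
    return spec.slots_available * spec.lines_per_card * spec.channels_per_line


def data_rate(channels: int, fs: float, bytes_per_sample: int = 2) -> float:
    """Aggregate disk bandwidth in decimal MB/s (10^6 bytes per MB)."""
    if channels < 0 or fs < 0 or bytes_per_sample < 0:
        raise ValueError("all inputs must be >= 0")
    return channels * fs * bytes_per_sample / 1e6


def capacity_table(
    preset: str | CardSpec,
    slots: int | None = None,
    fs: float | None = None,
    bytes_per_sample: int = 2,
) -> dict:
    """Capacity summary for one configuration (used by the CLI planner)."""
    spec = PRESETS[preset] if isinstance(preset, str) else preset
    if slots is not None:
        spec = replace(spec, slots_available=int(slots))
    use_fs = float(fs) if fs is not None else spec.max_fs
    if use_fs > spec.max_fs:
        raise ValueError(f"fs {use_fs} exceeds card capability {spec.max_fs}")
    n = max_channels(spec)
    return {
        "kind": spec.kind,
        "slots": spec.slots_available,
        "max_channels": n,
        "fs_hz": use_fs,
        "data_rate_mb_s": data_rate(n, use_fs, bytes_per_sample),
    }
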