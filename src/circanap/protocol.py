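"""Multiple-nap protocol schedules.

The protocol places short sleep-wake cycles (an 80-min nap opportunity
followed by 160 min of scheduled wakefulness) between a baseline and a
recovery night, on a time axis of minutes since the scheduled wake-up
from the baseline night.  All downstream alignment (melatonin sampling,
hypnogram windows, circadian timestamps) hangs on this scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

__all__ = [
    "ConfigurationError",
    "ProtocolConfig",
    "Window",
    "ProtocolSchedule",
    "generate_protocol",
    "melatonin_sample_times",
]


class ConfigurationError(ValueError):
    """Raised for internally inconsistent protocol configurations."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Design constants of the multiple-nap protocol.

    Defaults encode the standard 40-h design: ten 80-min nap
    opportunities alternating with 160 min of wakefulness, the first
    cycle starting 130 min after scheduled wake-up, the last wake block
    cut to 40 min, bracketed by two 8-h nights, with 30 melatonin
    samples every 80 min starting 50 min after wake-up.
    """

    habitual_wake_time: float = 7.0      # clock hours
    n_cycles: int = 10
    nap_duration: float = 80.0           # minutes
    wake_duration: float = 160.0         # minutes
    first_cycle_offset: float = 130.0    # minutes after baseline wake-up
    last_cycle_wake: float = 40.0        # minutes
    night_duration: float = 8.0          # hours
    epoch_length: float = 30.0           # seconds
    melatonin_interval: float = 80.0     # minutes
    n_melatonin_samples: int = 30
    melatonin_first_offset: float = 50.0  # minutes after wake-up

    def __post_init__(self) -> None:
        durations = (
            self.nap_duration, self.wake_duration, self.first_cycle_offset,
            self.last_cycle_wake, self.night_duration, self.epoch_length,
            self.melatonin_interval,
        )
        if any(d <= 0 for d in durations):
            raise ConfigurationError("all durations must be positive")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if self.n_melatonin_samples < 1:
            raise ConfigurationError("n_melatonin_samples must be >= 1")
        n_epochs = self.nap_duration * 60.0 / self.epoch_length
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise ConfigurationError(
                f"epoch_length ({self.epoch_length}s) must divide the nap "
                f"duration ({self.nap_duration} min)"
            )

    @property
    def habitual_sleep_time_min(self) -> float:
        """Habitual bedtime, minutes after wake-up (= 24 h − night)."""
        return (24.0 - self.night_duration) * 60.0

    @property
    def nap_day_span_min(self) -> float:
        """Wake-up to recovery-night lights-off, in minutes."""
        return (
            self.first_cycle_offset
            + self.n_cycles * self.nap_duration
            + (self.n_cycles - 1) * self.wake_duration
            + self.last_cycle_wake
        )

    def with_overrides(self, **kwargs) -> "ProtocolConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Window:
    """Half-open protocol window [start, end) in minutes since wake-up."""

    start: float
    end: float
    kind: str  # 'nap' | 'wake' | 'night'
    label: str = ""

    @property
    def duration_min(self) -> float:
        return self.end - self.start

    @property
    def midpoint_min(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class ProtocolSchedule:
    """Contiguous, non-overlapping tiling of the protocol by windows."""

    windows: tuple[Window, ...]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.windows, self.windows[1:]):
            if abs(prev.end - cur.start) > 1e-9:
                raise ConfigurationError(
                    f"windows not contiguous at t={prev.end} / {cur.start}"
                )

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)

    @property
    def naps(self) -> tuple[Window, ...]:
        return tuple(w for w in self.windows if w.kind == "nap")

    @property
    def nights(self) -> tuple[Window, ...]:
        return tuple(w for w in self.windows if w.kind == "night")

    @property
    def start_min(self) -> float:
        return self.windows[0].start

    @property
    def end_min(self) -> float:
        return self.windows[-1].end

    def __contains__(self, window: Window) -> bool:
        return any(
            abs(w.start - window.start) < 1e-9
            and abs(w.end - window.end) < 1e-9
            and w.kind == window.kind
            for w in self.windows
        )


def generate_protocol(config: ProtocolConfig | None = None) -> ProtocolSchedule:
    """Build the deterministic window tiling of the protocol.

    Layout: baseline night, a wake block of ``first_cycle_offset``, then
    ``n_cycles`` nap-then-wake cycles whose final wake block is cut to
    ``last_cycle_wake``, then the recovery night.
    """
    cfg = config or ProtocolConfig()
    night_min = cfg.night_duration * 60.0
    windows: list[Window] = [
        Window(-night_min, 0.0, "night", "baseline_night"),
        Window(0.0, cfg.first_cycle_offset, "wake", "wake_pre"),
    ]
    t = cfg.first_cycle_offset
    for i in range(cfg.n_cycles):
        windows.append(Window(t, t + cfg.nap_duration, "nap", f"nap_{i:02d}"))
        t += cfg.nap_duration
        wake = cfg.last_cycle_wake if i == cfg.n_cycles - 1 else cfg.wake_duration
        windows.append(Window(t, t + wake, "wake", f"wake_{i:02d}"))
        t += wake
    windows.append(Window(t, t + night_min, "night", "recovery_night"))
    return ProtocolSchedule(tuple(windows))


def melatonin_sample_times(config: ProtocolConfig | None = None):
    """Scheduled saliva sampling times (minutes since wake-up).

    A regular grid every ``melatonin_interval`` minutes starting
    ``melatonin_first_offset`` after wake-up; the default yields 30
    samples spanning the whole nap day.
    """
    import numpy as np

    cfg = config or ProtocolConfig()
    times = cfg.melatonin_first_offset + cfg.melatonin_interval * np.arange(
        cfg.n_melatonin_samples, dtype=float
    )
    if times[-1] > cfg.nap_day_span_min:
        raise ConfigurationError(
            "melatonin sampling scheme extends beyond the protocol"
        )
    return times
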