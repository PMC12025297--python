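"""Breathing waveforms, spike contamination, and the sweep protocols.

The study conditions simulated here: a 16-electrode recording of 600 frames
at 20 frames/s (30 s of tidal breathing), lung conductivity modulated by a
normalised periodic waveform in (0, 1], and multiplicative spike
contamination of controllable magnitude (x1..x100), temporal width (5..100
frames) and channel extent (5..192 channels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import VoltageMatrix
from .mesh import PhantomSpec, make_phantom

__all__ = [
    "BreathingWaveform",
    "SpikeSpec",
    "synth_breathing",
    "inject_spikes",
    "protocol_sweep",
    "heterogeneous_case",
    "DEFAULT_N_FRAMES",
    "DEFAULT_FRAME_RATE",
]

DEFAULT_N_FRAMES = 600
DEFAULT_FRAME_RATE = 20.0
DEFAULT_RATE_BPM = 15.0
DEFAULT_DEPTH = 0.5
#: documented default seed for the random channel draw of the heterogeneous
#: comparison case (the original draw is unpublished).
HETERO_CASE_SEED = 20240402


@dataclass(frozen=True)
class BreathingWaveform:
    """Normalised conductivity modulation of the lung regions, in (0, 1].

    The value 1 corresponds to end-expiration (lungs least aerated, most
    conductive); the minimum ``1 - depth`` to end-inspiration.
    """

    values: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if np.any(vals <= 0) or np.any(vals > 1):
            raise ValueError("waveform values must lie in (0, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SpikeSpec:
    """Multiplicative spike contamination.

    channels : 1-based channel indices to corrupt.
    frame_window : inclusive 1-based (start, end) frame range.
    magnitude : factor applied to every affected voltage (>= 1; 1 is a
        no-op, matching the weakest rung of the magnitude protocol).
    """

    channels: frozenset
    frame_window: tuple[int, int]
    magnitude: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", frozenset(int(c) for c in self.channels))
        if not self.channels:
            raise ValueError("spike spec needs at least one channel")
        if min(self.channels) < 1:
            raise ValueError("channel indices are 1-based")
        a, b = self.frame_window
        if a < 1 or b < a:
            raise ValueError("frame_window must be 1-based and non-empty")
        if self.magnitude < 1:
            raise ValueError("magnitude must be >= 1")

    @property
    def width(self) -> int:
        return self.frame_window[1] - self.frame_window[0] + 1

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean (channels x frames) mask of affected entries (0-based)."""
        m = np.zeros(shape, dtype=bool)
        rows = np.array(sorted(self.channels)) - 1
        a, b = self.frame_window
        m[rows, a - 1 : b] = True
        return m

    def summary(self) -> dict:
        return {
            "n_channels": len(self.channels),
            "first_channel": min(self.channels),
            "frame_window": list(self.frame_window),
            "width": self.width,
            "magnitude": self.magnitude,
        }


def synth_breathing(
    n_frames: int = DEFAULT_N_FRAMES,
    frame_rate: float = DEFAULT_FRAME_RATE,
    rate_bpm: float = DEFAULT_RATE_BPM,
    depth: float = DEFAULT_DEPTH,
    seed: int | None = None,
    jitter: float = 0.0,
) -> BreathingWaveform:
    """Raised-cosine tidal-breathing surrogate.

        w(t) = 1 - depth * (1 - cos(2 pi f t)) / 2,  f = rate_bpm / 60

    so w stays in [1 - depth, 1] with maxima (end-expiration) at cycle
    starts.  ``jitter`` > 0 adds seeded cycle-to-cycle variation of the
    instantaneous rate, emulating spontaneous breathing irregularity.
    """
    if not 6 <= rate_bpm <= 60:
        raise ValueError("rate_bpm must lie in [6, 60]")
    if not 0 < depth < 1:
        raise ValueError("depth must lie in (0, 1)")
    t = np.arange(n_frames) / frame_rate
    f = rate_bpm / 60.0
    phase = 2 * np.pi * f * t
    if jitter > 0:
        rng = np.random.default_rng(seed)
        # smooth random phase modulation, small relative to one cycle
        n_knots = max(int(np.ceil(n_frames / frame_rate * f)) + 2, 4)
        knots = rng.normal(0.0, jitter, n_knots)
        phase = phase + 2 * np.pi * np.interp(
            t, np.linspace(t[0], t[-1], n_knots), knots
        )
    values = 1.0 - depth * (1.0 - np.cos(phase)) / 2.0
    return BreathingWaveform(values=np.clip(values, 1.0 - depth, 1.0), frame_rate=frame_rate)


def inject_spikes(v: VoltageMatrix, spec: SpikeSpec) -> VoltageMatrix:
    """Multiply the entries selected by ``spec`` by its magnitude."""
    if max(spec.channels) > v.n_channels:
        raise ValueError("spike channel beyond the recording's channel count")
    if spec.frame_window[1] > v.n_frames:
        raise ValueError("spike window beyond the recording length")
    out = v.data.copy()
    m = spec.mask(out.shape)
    out[m] *= spec.magnitude
    return v.with_data(out)


#: published sweep-protocol grids.
MAGNITUDES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
WIDTHS = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
CHANNEL_COUNTS = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150, 190, 192)
SPIKE_CHANNEL = 35
SPIKE_FRAME = 299
CHANNEL_SWEEP_WINDOW = (300, 350)
SWEEP_MAGNITUDE = 50


def protocol_sweep(kind: str) -> list[SpikeSpec]:
    """The published spike-injection protocols.

    * ``magnitude``: 19 factors (1..10, 20..100) on channel 35, frame 299.
    * ``width``: 11 widths (5..100 consecutive frames) on channel 35,
      magnitude 50, windows centred on frame 299.
    * ``channels``: 14 channel counts (5..100, 150, 190, 192) starting at
      channel 1, frames 300-350, magnitude 50.
    """
    if kind == "magnitude":
        return [
            SpikeSpec(channels=frozenset({SPIKE_CHANNEL}),
                      frame_window=(SPIKE_FRAME, SPIKE_FRAME), magnitude=m)
            for m in MAGNITUDES
        ]
    if kind == "width":
        return [
            SpikeSpec(channels=frozenset({SPIKE_CHANNEL}),
                      frame_window=(SPIKE_FRAME, SPIKE_FRAME + w - 1),
                      magnitude=SWEEP_MAGNITUDE)
            for w in WIDTHS
        ]
    if kind == "channels":
        return [
            SpikeSpec(channels=frozenset(range(1, k + 1)),
                      frame_window=CHANNEL_SWEEP_WINDOW, magnitude=SWEEP_MAGNITUDE)
            for k in CHANNEL_COUNTS
        ]
    raise ValueError(f"unknown sweep kind {kind!r}")


def heterogeneous_case(
    style: str = "thorax", seed: int = HETERO_CASE_SEED
) -> tuple[PhantomSpec, SpikeSpec]:
    """The heterogeneous-lung comparison case: left lung split into two
    conductivity sub-regions, contaminated on 50 seeded-random channels over
    a 61-frame window with magnitude 27."""
    phantom = make_phantom(style=style, heterogeneous_left=True)
    rng = np.random.default_rng(seed)
    channels = frozenset(int(c) + 1 for c in rng.choice(192, size=50, replace=False))
    width = 61
    spec = SpikeSpec(channels=channels,
                     frame_window=(SPIKE_FRAME, SPIKE_FRAME + width - 1),
                     magnitude=27)
    return phantom, spec
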