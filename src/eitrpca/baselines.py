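"""Per-channel temporal filters used as denoising baselines.

Both filters act on each channel's time course independently: a zero-phase
Butterworth low-pass (order 3, cutoff 60 breaths/min by default) and a
running median (window 21 frames for the nominal order 20).  Neither exploits
the cross-channel structure of the recording, which is why wide or large
spikes survive them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .datamodel import VoltageMatrix

__all__ = ["FilterConfig", "lowpass_filter", "median_filter", "apply_filter"]


@dataclass(frozen=True)
class FilterConfig:
    kind: str                   # "lowpass" | "median"
    order: int
    cutoff_bpm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "median"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.kind == "lowpass" and (self.cutoff_bpm is None or self.cutoff_bpm <= 0):
            raise ValueError("lowpass filter needs a positive cutoff_bpm")


def lowpass_filter(
    v: VoltageMatrix, order: int = 3, cutoff_bpm: float = 60.0
) -> VoltageMatrix:
    """Zero-phase Butterworth low-pass along time, per channel.

    The cutoff is given in breaths per minute (60 bpm = 1 Hz).  Forward-
    backward application (filtfilt) avoids group delay so the baseline
    comparison is not confounded by a time shift.
    """
    cutoff_hz = cutoff_bpm / 60.0
    nyq = v.frame_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({nyq} Hz)"
        )
    sos = scipy.signal.butter(order, cutoff_hz, btype="low", fs=v.frame_rate,
                              output="sos")
    out = scipy.signal.sosfiltfilt(sos, v.data, axis=1)
    return v.with_data(out)


def median_filter(v: VoltageMatrix, order: int = 20) -> VoltageMatrix:
    """Running median along time, per channel; reflected edges.

    A centred median needs odd support, so the window is the nearest odd
    length >= ``order`` (order 20 -> window 21).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order > v.n_frames:
        raise ValueError("median window longer than the recording")
    window = order if order % 2 == 1 else order + 1
    out = scipy.ndimage.median_filter(v.data, size=(1, window), mode="reflect")
    return v.with_data(out)


def apply_filter(v: VoltageMatrix, cfg: FilterConfig) -> VoltageMatrix:
    if cfg.kind == "lowpass":
        return lowpass_filter(v, order=cfg.order, cutoff_bpm=cfg.cutoff_bpm)
    return median_filter(v, order=cfg.order)
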