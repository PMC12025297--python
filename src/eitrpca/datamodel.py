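"""EIT voltage-matrix data model.

A thoracic EIT recording with a 16-electrode belt under the *opposite current
excitation / adjacent voltage measurement* scheme yields 12 measurement pairs
for each of the 16 drive pairs, i.e. 192 voltage channels per frame.  A
recording of T frames is organised as a 192 x T matrix whose rows are
channels and whose columns are frames; all respiratory signal processing in
this package operates on that matrix.

Channel ordering convention (documented, used everywhere): drive-pair major —
all 12 measurements of drive pair 1 first, then drive pair 2, and so on.
Drive pair k (1-based) injects current between electrodes k and k+8 (mod 16).
Within a drive pair, measurement pairs are adjacent electrode pairs (c, c+1
mod 16) in ascending order of c, skipping the four pairs that contain a drive
electrode.  Electrode and channel indices are 1-based at the user surface,
0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "VoltageMatrix",
    "ChannelMap",
    "SingularSpectrum",
    "build_channel_map",
    "load_voltage_matrix",
    "save_voltage_matrix",
    "singular_spectrum",
    "saturate_bad_electrodes",
    "sum_waveform",
]

#: Row counts accepted for 16-electrode systems: 192 for opposite drive,
#: 208 for adjacent drive.
VALID_CHANNEL_COUNTS = (192, 208)


class ProtocolError(ValueError):
    """Raised when a matrix does not match a known measurement protocol."""


@dataclass(frozen=True)
class VoltageMatrix:
    """Boundary-voltage recording: channels x frames.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_frames)``; volts on any
        consistent scale.
    frame_rate
        Acquisition rate in frames per second.
    n_electrodes
        Electrode count of the belt (16 supported).
    protocol_id
        Label of the excitation/measurement scheme.
    """

    data: np.ndarray
    frame_rate: float
    n_electrodes: int = 16
    protocol_id: str = "opposite-adjacent-16"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={data.ndim}")
        if data.shape[1] < 2:
            raise ValueError("a recording needs at least 2 frames")
        if not np.all(np.isfinite(data)):
            raise ValueError("voltage matrix contains non-finite entries")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "VoltageMatrix":
        """Same metadata, new samples."""
        return VoltageMatrix(
            data=data,
            frame_rate=self.frame_rate,
            n_electrodes=self.n_electrodes,
            protocol_id=self.protocol_id,
        )


@dataclass(frozen=True)
class ChannelEntry:
    """One measurement channel: 0-based electrode indices."""

    channel: int
    drive: tuple[int, int]
    measure: tuple[int, int]


@dataclass(frozen=True)
class ChannelMap:
    """Enumeration of the 192 channels of the opposite/adjacent scheme."""

    entries: tuple[ChannelEntry, ...]
    n_electrodes: int = 16

    def __len__(self) -> int:
        return len(self.entries)

    def channels_driven_by(self, electrode: int) -> list[int]:
        """0-based channel indices whose drive pair contains ``electrode``
        (0-based)."""
        return [e.channel for e in self.entries if electrode in e.drive]


def build_channel_map(n_electrodes: int = 16) -> ChannelMap:
    """Enumerate drive/measure pairs for opposite excitation, adjacent
    measurement.

    Drive pair k = (k, k+n/2 mod n) for k = 0..n-1; within each drive pair the
    measurement pairs are (c, c+1 mod n) for ascending c, skipping pairs that
    touch a drive electrode.  For n=16 this yields 16 x 12 = 192 channels.
    """
    if n_electrodes != 16:
        raise ProtocolError("only 16-electrode belts are supported")
    n = n_electrodes
    entries = []
    ch = 0
    for k in range(n):
        drive = (k, (k + n // 2) % n)
        for c in range(n):
            meas = (c, (c + 1) % n)
            if drive[0] in meas or drive[1] in meas:
                continue
            entries.append(ChannelEntry(channel=ch, drive=drive, measure=meas))
            ch += 1
    return ChannelMap(entries=tuple(entries), n_electrodes=n)


@dataclass(frozen=True)
class SingularSpectrum:
    """Singular values of a recording and each value's share of the total."""

    singular_values: np.ndarray
    energy_fractions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        sv = np.asarray(self.singular_values, dtype=float)
        if np.any(sv < -1e-12) or np.any(np.diff(sv) > 1e-12):
            raise ValueError("singular values must be non-negative, descending")
        object.__setattr__(self, "singular_values", sv)
        object.__setattr__(self, "energy_fractions", sv / sv.sum())


def singular_spectrum(v: VoltageMatrix) -> SingularSpectrum:
    """SVD spectrum of the recording.

    The first energy fraction (sigma_1 / sum sigma_i) quantifies how close the
    matrix is to rank one; clean tidal breathing concentrates nearly all
    energy in the leading singular value.
    """
    sv = scipy.linalg.svdvals(v.data)
    return SingularSpectrum(singular_values=sv)


# ---------------------------------------------------------------------------
# File I/O: headerless CSV, or a .npy array with a JSON sidecar.
# ---------------------------------------------------------------------------

def load_voltage_matrix(
    path: str | Path,
    frame_rate: float | None = None,
    n_electrodes: int = 16,
) -> VoltageMatrix:
    """Read a recording from CSV (rows = channels, no header) or ``.npy``.

    For ``.npy`` files a JSON sidecar ``<stem>.json`` supplies ``frame_rate``
    (and optionally ``n_electrodes``, ``protocol``); an explicit
    ``frame_rate`` argument overrides it.
    """
    path = Path(path)
    protocol = "opposite-adjacent-16"
    if path.suffix == ".npy":
        data = np.load(path, allow_pickle=False)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            frame_rate = frame_rate if frame_rate is not None else meta.get("frame_rate")
            n_electrodes = meta.get("n_electrodes", n_electrodes)
            protocol = meta.get("protocol", protocol)
    else:
        try:
            data = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if frame_rate is None:
        raise ValueError("frame_rate not given and no sidecar metadata found")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains NaN/Inf entries")
    if data.shape[0] not in VALID_CHANNEL_COUNTS:
        raise ProtocolError(
            f"{data.shape[0]} rows does not match a 16-electrode protocol "
            f"(expected one of {VALID_CHANNEL_COUNTS})"
        )
    return VoltageMatrix(
        data=data, frame_rate=float(frame_rate), n_electrodes=n_electrodes,
        protocol_id=protocol,
    )


def save_voltage_matrix(v: VoltageMatrix, path: str | Path) -> None:
    """Write CSV (for ``.csv``) or ``.npy`` plus JSON sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, v.data)
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "frame_rate": v.frame_rate,
                    "n_electrodes": v.n_electrodes,
                    "protocol": v.protocol_id,
                }
            )
        )
    else:
        np.savetxt(path, v.data, delimiter=",")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def saturate_bad_electrodes(
    v: VoltageMatrix,
    bad_electrodes: Sequence[int] | set[int],
    saturation_level: float | None = None,
) -> VoltageMatrix:
    """Replace measurements driven through poor-contact electrodes by the
    amplifier saturation level.

    When an electrode loses contact, no current is injected while it is part
    of the drive pair, so the affected channels read near zero and break the
    low-rank structure the decomposition relies on.  Forcing those channels to
    a constant rail restores a rank-one block that the low-rank component can
    absorb.

    Parameters
    ----------
    bad_electrodes
        1-based electrode ids in ``1..16``.
    saturation_level
        Rail value; defaults to ``10 * max|data|``.  Must exceed ``max|data|``.
    """
    bad = set(int(b) for b in bad_electrodes)
    if not bad:
        return v.with_data(v.data.copy())
    if not bad <= set(range(1, v.n_electrodes + 1)):
        raise ValueError(f"unknown electrode ids: {sorted(bad - set(range(1, 17)))}")
    peak = np.abs(v.data).max()
    if saturation_level is None:
        saturation_level = 10.0 * peak
    # idempotence: rows already at the rail do not raise the peak test
    off_rail = v.data[np.abs(v.data) != saturation_level]
    if off_rail.size and saturation_level <= np.abs(off_rail).max():
        raise ValueError("saturation_level must exceed the current voltage peak")
    cmap = build_channel_map(v.n_electrodes)
    rows = sorted({ch for b in bad for ch in cmap.channels_driven_by(b - 1)})
    out = v.data.copy()
    out[rows, :] = saturation_level
    return v.with_data(out)


def sum_waveform(v: VoltageMatrix) -> np.ndarray:
    """Per-frame sum over all channels — the global respiration waveform."""
    return v.data.sum(axis=0)
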