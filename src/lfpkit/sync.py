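"""LFP packet ↔ video frame synchronization.

Each acquisition packet carries ``samples_per_packet`` consecutive 32-bit
sample timestamps plus the index of the most recently acquired video frame,
repeated ``samples_per_packet`` times so the two vectors match in shape.
On disk (default ``blocked`` dialect) every packet record is the sample
timestamps followed by the frame-index repeats; an ``interleaved`` dialect
(ts, frame, ts, frame, ...) is available via config.

Because packets outnumber frames only at high sampling rates, many frames
are never assigned online; :func:`interpolate_frames` assigns them offline
by linear interpolation between anchor frames. Reports use 1-based packet
and frame numbering; in-memory structures are 0-based sample offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SyncError
from .io_formats import SessionConfig, TS_LAYOUT_BLOCKED, TS_LAYOUT_INTERLEAVED

TIMESTAMP_DTYPE = np.dtype("<u4")


@dataclass
class PacketRecord:
    """One acquisition packet: its sample timestamps and assigned frame."""

    packet_index: int
    sample_timestamps: np.ndarray  # uint32, strictly increasing by 1
    frame_index: int

    def __post_init__(self) -> None:
        self.sample_timestamps = np.asarray(self.sample_timestamps, dtype=np.int64)


@dataclass
class SyncMap:
    """Ordered packet records plus first-occurrence frame anchors.

    ``anchor_frames[i]`` first appears at stream sample offset
    ``anchor_samples[i]`` (0-based, relative to the first packet in the
    record list).
    """

    records: list[PacketRecord]
    anchor_frames: np.ndarray
    anchor_samples: np.ndarray
    samples_per_packet: int

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_frames)


@dataclass
class FrameTimeline:
    """Per-frame sample positions after offline interpolation.

    Positions are fractional; ``rounded_positions`` rounds to the nearest
    sample with ties toward the earlier sample. ``assigned`` marks frames
    that were anchors (assigned online) as opposed to interpolated.
    """

    frame_indices: np.ndarray
    sample_positions: np.ndarray  # fractional, strictly increasing
    assigned: np.ndarray  # bool, True = online anchor
    single_anchor_warning: bool = False

    def rounded_positions(self) -> np.ndarray:
        # round-half-down: ceil(x - 0.5)
        return np.ceil(self.sample_positions - 0.5).astype(np.int64)


@dataclass(frozen=True)
class ContinuityGap:
    segment_label: str
    packet_position: int  # 0-based position in the concatenated stream
    expected_timestamp: int
    observed_timestamp: int
    missing_samples: int

    @property
    def missing_packets(self) -> int | None:
        """Whole packets lost, if the gap is an exact multiple (else None)."""
        return None


@dataclass
class ContinuityReport:
    gaps: list[ContinuityGap]
    samples_per_packet: int
    n_packets_checked: int

    @property
    def total_missing_samples(self) -> int:
        return sum(g.missing_samples for g in self.gaps)

    def missing_packets(self, gap: ContinuityGap) -> int | None:
        if gap.missing_samples % self.samples_per_packet == 0:
            return gap.missing_samples // self.samples_per_packet
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "segment": g.segment_label,
                    "packet_index": g.packet_position,
                    "expected": g.expected_timestamp,
                    "observed": g.observed_timestamp,
                    "missing_samples": g.missing_samples,
                }
                for g in self.gaps
            ],
            columns=["segment", "packet_index", "expected", "observed", "missing_samples"],
        )


@dataclass
class GapStatistics:
    """Consecutive-unassigned-frame counts between successive anchors."""

    gaps: np.ndarray
    mean: float
    max: int
    n: int

    def to_dict(self) -> dict:
        return {
            "n_gaps": self.n,
            "mean_unassigned_frames": self.mean,
            "max_unassigned_frames": self.max,
        }


def read_timestamp_file(path: str | Path, config: SessionConfig) -> list[PacketRecord]:
    """Parse a timestamp binary into per-packet records.

    Every packet record holds the sample timestamps and the repeated frame
    index; the frame repeats must all be equal within a packet.
    """
    path = Path(path)
    raw = np.fromfile(path, dtype=TIMESTAMP_DTYPE)
    spp = config.samples_per_packet
    record_values = 2 * spp
    if raw.size % record_values:
        residue = (raw.size % record_values) * TIMESTAMP_DTYPE.itemsize
        raise FormatError(
            f"{path}: truncated timestamp file, {residue} residual bytes beyond "
            f"a whole number of {record_values * TIMESTAMP_DTYPE.itemsize}-byte records"
        )
    n_packets = raw.size // record_values
    if config.ts_layout == TS_LAYOUT_BLOCKED:
        cube = raw.reshape(n_packets, 2, spp)
        ts_block, frame_block = cube[:, 0, :], cube[:, 1, :]
    else:
        cube = raw.reshape(n_packets, spp, 2)
        ts_block, frame_block = cube[:, :, 0], cube[:, :, 1]
    records = []
    for k in range(n_packets):
        frames = frame_block[k]
        if frames.size and not np.all(frames == frames[0]):
            raise FormatError(
                f"{path}: packet {k}: frame block contains distinct values "
                f"{sorted(set(int(v) for v in frames))}"
            )
        records.append(
            PacketRecord(
                packet_index=k,
                sample_timestamps=ts_block[k].astype(np.int64),
                frame_index=int(frames[0]),
            )
        )
    return records


def write_timestamp_file(
    records: Sequence[PacketRecord], config: SessionConfig, path: str | Path
) -> Path:
    """Inverse of :func:`read_timestamp_file` (same dialect selection)."""
    spp = config.samples_per_packet
    out = np.empty((len(records), 2, spp), dtype=TIMESTAMP_DTYPE)
    for k, rec in enumerate(records):
        if rec.sample_timestamps.size != spp:
            raise FormatError(
                f"packet {k}: expected {spp} sample timestamps, "
                f"got {rec.sample_timestamps.size}"
            )
        out[k, 0, :] = rec.sample_timestamps
        out[k, 1, :] = rec.frame_index
    if config.ts_layout == TS_LAYOUT_INTERLEAVED:
        out = out.transpose(0, 2, 1)
    path = Path(path)
    np.ascontiguousarray(out).tofile(path)
    return path


def build_sync_map(records: Sequence[PacketRecord]) -> SyncMap:
    """Derive first-occurrence frame anchors from ordered packet records."""
    if not records:
        raise SyncError("cannot build a sync map from zero packets")
    spp = records[0].sample_timestamps.size
    frames = np.array([r.frame_index for r in records], dtype=np.int64)
    drops = np.nonzero(np.diff(frames) < 0)[0]
    if drops.size:
        k = int(drops[0])
        raise SyncError(
            f"frame index decreases from {frames[k]} to {frames[k + 1]} "
            f"at packet position {k + 1} (clock anomaly)"
        )
    first = np.r_[True, np.diff(frames) > 0]
    anchor_positions = np.nonzero(first)[0]
    return SyncMap(
        records=list(records),
        anchor_frames=frames[anchor_positions],
        anchor_samples=anchor_positions * spp,
        samples_per_packet=spp,
    )


def interpolate_frames(
    sync_map: SyncMap, frame_range: tuple[int, int] | None = None
) -> FrameTimeline:
    """Assign a sample position to every frame by linear interpolation.

    Frames between consecutive anchors ``(f_a, s_a)`` and ``(f_b, s_b)``
    receive ``s_a + (f - f_a) * (s_b - s_a) / (f_b - f_a)``; anchors keep
    their exact positions. ``frame_range`` (inclusive) may extend the
    timeline beyond the anchors, in which case positions are extrapolated
    from the nearest anchor pair.
    """
    af = sync_map.anchor_frames.astype(np.float64)
    asamp = sync_map.anchor_samples.astype(np.float64)
    if sync_map.n_anchors == 0:
        raise SyncError("sync map has no anchors")
    if frame_range is None:
        lo, hi = int(sync_map.anchor_frames[0]), int(sync_map.anchor_frames[-1])
    else:
        lo, hi = frame_range
    frames = np.arange(lo, hi + 1, dtype=np.int64)
    if sync_map.n_anchors == 1:
        positions = np.full(frames.shape, asamp[0])
        assigned = frames == sync_map.anchor_frames[0]
        return FrameTimeline(frames, positions, assigned, single_anchor_warning=True)
    # np.interp clamps outside the anchor range; extend by the edge slopes.
    positions = np.interp(frames, af, asamp)
    below = frames < af[0]
    above = frames > af[-1]
    if below.any():
        slope = (asamp[1] - asamp[0]) / (af[1] - af[0])
        positions[below] = asamp[0] + (frames[below] - af[0]) * slope
    if above.any():
        slope = (asamp[-1] - asamp[-2]) / (af[-1] - af[-2])
        positions[above] = asamp[-1] + (frames[above] - af[-1]) * slope
    assigned = np.isin(frames, sync_map.anchor_frames)
    return FrameTimeline(frames, positions, assigned)


def gap_statistics(sync_map: SyncMap) -> GapStatistics:
    """Count consecutive unassigned frames between successive anchors."""
    frames = sync_map.anchor_frames
    gaps = np.diff(frames) - 1 if frames.size >= 2 else np.array([], dtype=np.int64)
    mean = float(gaps.mean()) if gaps.size else 0.0
    return GapStatistics(
        gaps=gaps, mean=mean, max=int(gaps.max()) if gaps.size else 0, n=gaps.size
    )


def check_continuity(
    segments: Sequence[Sequence[PacketRecord]],
    labels: Sequence[str] | None = None,
    samples_per_packet: int | None = None,
) -> ContinuityReport:
    """Find sample gaps within and across manifest-ordered segments.

    A gap is reported wherever the first timestamp of a packet is not the
    last timestamp of the previous packet plus one; board timestamps (not
    wall clock) define continuity.
    """
    if labels is None:
        labels = [str(i) for i in range(len(segments))]
    gaps: list[ContinuityGap] = []
    prev_last: int | None = None
    position = 0
    spp = samples_per_packet
    for label, records in zip(labels, segments):
        for rec in records:
            if spp is None:
                spp = rec.sample_timestamps.size
            first = int(rec.sample_timestamps[0])
            if prev_last is not None:
                expected = prev_last + 1
                if first != expected:
                    gaps.append(
                        ContinuityGap(
                            segment_label=label,
                            packet_position=position,
                            expected_timestamp=expected,
                            observed_timestamp=first,
                            missing_samples=first - expected,
                        )
                    )
            prev_last = int(rec.sample_timestamps[-1])
            position += 1
    return ContinuityReport(
        gaps=gaps, samples_per_packet=spp or 0, n_packets_checked=position
    )


def packet_sample_range(
    packet_number: int, config: SessionConfig
) -> tuple[int, int, int, int]:
    """1-based sample and millisecond range covered by one packet.

    ``packet_number`` is 1-based (report convention). Milliseconds are the
    1-based ms bins containing the first and last sample:
    ``ms = ceil(sample / (rate / 1000))``.
    """
    if packet_number < 1:
        raise ParameterError(f"packet_number must be >= 1, got {packet_number}")
    spp = config.samples_per_packet
    first = (packet_number - 1) * spp + 1
    last = packet_number * spp
    samples_per_ms = config.sample_rate_hz / 1000.0
    first_ms = math.ceil(first / samples_per_ms)
    last_ms = math.ceil(last / samples_per_ms)
    return first, last, first_ms, last_ms
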