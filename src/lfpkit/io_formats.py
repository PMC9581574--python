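"""Binary session file formats.

Amplifier files hold 16-bit unsigned little-endian samples written as one
long vector. The default dialect is *packet-blocked, channel-major*: the
file is a sequence of packets, and within each packet channel 0's
``samples_per_packet`` values come first, then channel 1's, and so on —
matching the acquisition buffer shape. A ``sample_interleaved`` dialect
(all channels for sample 0, then sample 1, ...) is supported via the
config ``layout`` key because the original writer's serialization order is
not documented.

Raw values convert to microvolts as ``(raw - raw_offset_bits) * scale_uv_per_bit``
with a default scale of 0.195 µV/bit and a default offset of 0.

Session directories contain hour-long segments named
``<label>_<suffix>.<ext>`` with suffix ``amplifier``, ``ts`` or ``vid``;
labels sort chronologically.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, FormatError, ManifestError, ValidationError

AMPLIFIER_DTYPE = np.dtype("<u2")

LAYOUT_PACKET_BLOCKED = "packet_blocked"
LAYOUT_SAMPLE_INTERLEAVED = "sample_interleaved"

TS_LAYOUT_BLOCKED = "blocked"
TS_LAYOUT_INTERLEAVED = "interleaved"

#: ``<label>_<suffix>.<ext>`` — label is any sortable string without the
#: ``_suffix`` tail; suffix identifies the stream.
SEGMENT_FILE_PATTERN = re.compile(
    r"^(?P<label>.+)_(?P<suffix>amplifier|ts|vid)\.(?P<ext>[A-Za-z0-9]+)$"
)


@dataclass(frozen=True)
class AnimalChannels:
    """Mapping from one animal to its pair of recorded channels (0-based)."""

    animal_id: str
    left_channel: int
    right_channel: int

    def __post_init__(self) -> None:
        if self.left_channel < 0 or self.right_channel < 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: channel indices must be >= 0"
            )
        if self.left_channel == self.right_channel:
            raise ValidationError(
                f"animal {self.animal_id!r}: left_channel == right_channel "
                f"({self.left_channel})"
            )

    @property
    def channels(self) -> tuple[int, int]:
        return (self.left_channel, self.right_channel)


@dataclass
class SessionConfig:
    """Acquisition constants and the animal→channel map for one session."""

    num_channels: int
    animals: list[AnimalChannels] = field(default_factory=list)
    sample_rate_hz: float = 2000.0
    samples_per_packet: int = 256
    scale_uv_per_bit: float = 0.195
    raw_offset_bits: int = 0
    nominal_frame_rate_hz: float = 30.0
    layout: str = LAYOUT_PACKET_BLOCKED
    ts_layout: str = TS_LAYOUT_BLOCKED

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.num_channels < 1:
            raise ValidationError("num_channels must be >= 1")
        if self.samples_per_packet < 1:
            raise ValidationError("samples_per_packet must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.scale_uv_per_bit <= 0:
            raise ValidationError("scale_uv_per_bit must be positive")
        if self.raw_offset_bits < 0:
            raise ValidationError("raw_offset_bits must be >= 0")
        if self.nominal_frame_rate_hz <= 0:
            raise ValidationError("nominal_frame_rate_hz must be positive")
        if self.layout not in (LAYOUT_PACKET_BLOCKED, LAYOUT_SAMPLE_INTERLEAVED):
            raise ValidationError(f"unknown layout {self.layout!r}")
        if self.ts_layout not in (TS_LAYOUT_BLOCKED, TS_LAYOUT_INTERLEAVED):
            raise ValidationError(f"unknown ts_layout {self.ts_layout!r}")
        seen: set[str] = set()
        for animal in self.animals:
            if animal.animal_id in seen:
                raise ConfigError(f"duplicate animal id {animal.animal_id!r}")
            seen.add(animal.animal_id)
            for ch in animal.channels:
                if ch >= self.num_channels:
                    raise ConfigError(
                        f"animal {animal.animal_id!r} references channel {ch} "
                        f"but num_channels is {self.num_channels}"
                    )

    @property
    def packet_stride_bytes(self) -> int:
        """Bytes occupied by one packet across all channels."""
        return AMPLIFIER_DTYPE.itemsize * self.num_channels * self.samples_per_packet

    def animal(self, animal_id: str) -> AnimalChannels:
        for a in self.animals:
            if a.animal_id == animal_id:
                return a
        raise KeyError(animal_id)

    def to_dict(self) -> dict:
        return {
            "num_channels": self.num_channels,
            "sample_rate_hz": self.sample_rate_hz,
            "samples_per_packet": self.samples_per_packet,
            "scale_uv_per_bit": self.scale_uv_per_bit,
            "raw_offset_bits": self.raw_offset_bits,
            "nominal_frame_rate_hz": self.nominal_frame_rate_hz,
            "layout": self.layout,
            "ts_layout": self.ts_layout,
            "animals": [
                {
                    "animal_id": a.animal_id,
                    "left_channel": a.left_channel,
                    "right_channel": a.right_channel,
                }
                for a in self.animals
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SessionConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a JSON object")
        if "num_channels" not in doc:
            raise ConfigError("missing required field 'num_channels'")
        if "animals" not in doc:
            raise ConfigError("missing required field 'animals'")
        animals = []
        for i, entry in enumerate(doc["animals"]):
            for key in ("animal_id", "left_channel", "right_channel"):
                if key not in entry:
                    raise ConfigError(f"animals[{i}]: missing required field {key!r}")
            animals.append(
                AnimalChannels(
                    animal_id=str(entry["animal_id"]),
                    left_channel=int(entry["left_channel"]),
                    right_channel=int(entry["right_channel"]),
                )
            )
        kwargs = {}
        for key, cast in (
            ("sample_rate_hz", float),
            ("samples_per_packet", int),
            ("scale_uv_per_bit", float),
            ("raw_offset_bits", int),
            ("nominal_frame_rate_hz", float),
            ("layout", str),
            ("ts_layout", str),
        ):
            if key in doc:
                kwargs[key] = cast(doc[key])
        return cls(num_channels=int(doc["num_channels"]), animals=animals, **kwargs)


def parse_config(path: str | Path) -> SessionConfig:
    """Read and validate the session config JSON file."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
    return SessionConfig.from_dict(doc)


def write_config(config: SessionConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    return path


@dataclass
class RawAmplifierBlock:
    """De-blocked raw amplifier data: ``data[channel, sample]`` in raw bits."""

    data: np.ndarray  # [num_channels x num_samples], uint16 range
    first_packet_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("RawAmplifierBlock.data must be 2-D")
        if self.first_packet_index < 0:
            raise ValidationError("first_packet_index must be >= 0")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 0xFFFF):
            raise ValidationError("raw values must lie in [0, 65535]")

    @property
    def num_channels(self) -> int:
        return self.data.shape[0]

    @property
    def num_samples(self) -> int:
        return self.data.shape[1]


def read_amplifier(path: str | Path, config: SessionConfig) -> RawAmplifierBlock:
    """Read an amplifier binary file into a [channels x samples] matrix.

    The file must contain a whole number of packets; a trailing residue is
    reported as a :class:`FormatError` in bytes.
    """
    path = Path(path)
    raw = np.fromfile(path, dtype=AMPLIFIER_DTYPE)
    stride_values = config.num_channels * config.samples_per_packet
    residue = (raw.size * AMPLIFIER_DTYPE.itemsize) % config.packet_stride_bytes
    if residue:
        raise FormatError(
            f"{path}: truncated amplifier file, {residue} residual bytes beyond "
            f"a whole number of {config.packet_stride_bytes}-byte packets"
        )
    n_packets = raw.size // stride_values
    data = _deblock(raw, n_packets, config)
    return RawAmplifierBlock(data=data, first_packet_index=0)


def _deblock(raw: np.ndarray, n_packets: int, config: SessionConfig) -> np.ndarray:
    nch, spp = config.num_channels, config.samples_per_packet
    if config.layout == LAYOUT_PACKET_BLOCKED:
        # packet -> channel -> sample
        cube = raw.reshape(n_packets, nch, spp)
        return np.ascontiguousarray(cube.transpose(1, 0, 2).reshape(nch, -1))
    # sample-interleaved: sample -> channel
    return np.ascontiguousarray(raw.reshape(n_packets * spp, nch).T)


def _reblock(data: np.ndarray, config: SessionConfig) -> np.ndarray:
    nch, spp = config.num_channels, config.samples_per_packet
    n_packets = data.shape[1] // spp
    if config.layout == LAYOUT_PACKET_BLOCKED:
        return data.reshape(nch, n_packets, spp).transpose(1, 0, 2).ravel()
    return data.T.ravel()


def write_amplifier(
    block: RawAmplifierBlock | np.ndarray, config: SessionConfig, path: str | Path
) -> Path:
    """Write a raw matrix to disk in the configured amplifier dialect."""
    data = block.data if isinstance(block, RawAmplifierBlock) else np.asarray(block)
    if data.ndim != 2 or data.shape[0] != config.num_channels:
        raise FormatError(
            f"expected [num_channels={config.num_channels} x samples] matrix, "
            f"got shape {data.shape}"
        )
    if data.shape[1] % config.samples_per_packet:
        raise FormatError(
            f"sample count {data.shape[1]} is not a multiple of "
            f"samples_per_packet={config.samples_per_packet}"
        )
    if data.size and (data.min() < 0 or data.max() > 0xFFFF):
        raise ValidationError("raw values must lie in [0, 65535]")
    flat = _reblock(data.astype(AMPLIFIER_DTYPE), config)
    path = Path(path)
    flat.astype(AMPLIFIER_DTYPE).tofile(path)
    return path


def scale_to_microvolts(
    raw: RawAmplifierBlock | np.ndarray, config: SessionConfig
) -> np.ndarray:
    """Convert raw amplifier bits to µV: ``(raw - offset) * scale``."""
    data = raw.data if isinstance(raw, RawAmplifierBlock) else np.asarray(raw)
    return (data.astype(np.float64) - config.raw_offset_bits) * config.scale_uv_per_bit


def microvolts_to_raw(signal_uv: np.ndarray, config: SessionConfig) -> np.ndarray:
    """Quantize a µV signal back to raw bits (round-to-nearest, clipped)."""
    raw = np.rint(np.asarray(signal_uv) / config.scale_uv_per_bit) + config.raw_offset_bits
    return np.clip(raw, 0, 0xFFFF).astype(AMPLIFIER_DTYPE)


@dataclass(frozen=True)
class SegmentEntry:
    segment_label: str
    amplifier_path: Path
    timestamp_path: Path
    video_path: Path | None = None


@dataclass
class SessionManifest:
    """Chronologically ordered hour-segment file triples for one session."""

    segments: list[SegmentEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    @property
    def labels(self) -> list[str]:
        return [s.segment_label for s in self.segments]


def discover_session(
    directory: str | Path, config: SessionConfig | None = None
) -> SessionManifest:
    """Scan a session directory for ``<label>_{amplifier,ts,vid}`` triples.

    Entries are sorted by label regardless of filesystem listing order; an
    amplifier file without its timestamp file (or vice versa) raises
    :class:`ManifestError` listing every orphan.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ManifestError(f"{directory} is not a directory")
    by_label: dict[str, dict[str, Path]] = {}
    for entry in directory.iterdir():
        if not entry.is_file():
            continue
        m = SEGMENT_FILE_PATTERN.match(entry.name)
        if m is None:
            continue
        by_label.setdefault(m.group("label"), {})[m.group("suffix")] = entry
    orphans = [
        f"{label}: has {sorted(files)} but needs both 'amplifier' and 'ts'"
        for label, files in sorted(by_label.items())
        if "amplifier" not in files or "ts" not in files
    ]
    if orphans:
        raise ManifestError("orphan segment files: " + "; ".join(orphans))
    segments = [
        SegmentEntry(
            segment_label=label,
            amplifier_path=files["amplifier"],
            timestamp_path=files["ts"],
            video_path=files.get("vid"),
        )
        for label, files in sorted(by_label.items())
    ]
    return SessionManifest(segments=segments)


def segment_paths(directory: str | Path, label: str) -> dict[str, Path]:
    """Canonical file paths for one segment label inside a session directory."""
    directory = Path(directory)
    return {
        "amplifier": directory / f"{label}_amplifier.bin",
        "ts": directory / f"{label}_ts.bin",
        "vid": directory / f"{label}_vid.avi",
    }
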