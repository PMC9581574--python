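"""Synthetic multianimal session generator.

Produces µV signals (1/f background noise, interictal spikes, seizure
spike trains, movement artifacts), simulates the asynchronous packet/frame
assignment, and writes the full on-disk session footprint (amplifier +
timestamp files, config, ground-truth sidecar) so every downstream module
can run without recorded data.

All randomness flows from ``SimulationSpec.seed`` through independent
child streams (signal noise, spike times, frame jitter), so the same seed
reproduces the session bit for bit. Schedules are evaluated in a fixed
order: background, interictal spikes, seizures, artifacts.

Because the raw format is unsigned, signals are offset to mid-range
(32768 bits) before quantization and the offset is recorded in the
emitted config.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import fft as scipy_fft

from .errors import ValidationError
from .io_formats import (
    AnimalChannels,
    SessionConfig,
    microvolts_to_raw,
    segment_paths,
    write_amplifier,
    write_config,
)
from .sync import PacketRecord, write_timestamp_file

RAW_MIDPOINT = 32768


def _load_json_source(source) -> dict:
    """Accept a JSON string or a path to a JSON file."""
    if isinstance(source, Path):
        return json.loads(source.read_text())
    text = str(source)
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        return json.loads(Path(text).read_text())


@dataclass
class BackgroundSpec:
    noise_sd_uv: float = 50.0
    one_over_f_exponent: float = 1.0


@dataclass
class InterictalSpec:
    rate_hz: float = 0.0
    amplitude_uv: float = 300.0
    width_ms: float = 30.0


@dataclass
class SeizureSchedule:
    animal: int
    start_s: float
    duration_s: float
    spike_rate_hz: float = 8.0
    amplitude_uv: float = 600.0
    bilateral: bool = True


@dataclass
class ArtifactSchedule:
    start_s: float
    duration_s: float
    kind: str = "grooming"  # grooming | eating
    amplitude_uv: float = 200.0
    animal: int | None = None  # None = all animals


@dataclass
class TimingSpec:
    frame_period_ms: float = 33.3
    packet_emit_latency_ms: float = 0.0
    frame_latency_jitter_ms: float = 0.0


@dataclass
class SimulationSpec:
    seed: int
    duration_s: float
    n_animals: int = 1
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    shared_source_mixing: float = 0.5
    interictal: InterictalSpec = field(default_factory=InterictalSpec)
    seizures: list[SeizureSchedule] = field(default_factory=list)
    artifacts: list[ArtifactSchedule] = field(default_factory=list)
    timing: TimingSpec = field(default_factory=TimingSpec)
    sample_rate_hz: float = 2000.0
    samples_per_packet: int = 256
    scale_uv_per_bit: float = 0.195

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if not (0.0 <= self.shared_source_mixing <= 1.0):
            raise ValidationError("shared_source_mixing must lie in [0, 1]")
        for sz in self.seizures:
            if not (0 <= sz.start_s and sz.start_s + sz.duration_s <= self.duration_s):
                raise ValidationError(
                    f"seizure [{sz.start_s}, {sz.start_s + sz.duration_s}] s falls "
                    f"outside the session [0, {self.duration_s}] s"
                )
            if not (0 <= sz.animal < self.n_animals):
                raise ValidationError(f"seizure references unknown animal {sz.animal}")
        for ar in self.artifacts:
            if not (0 <= ar.start_s and ar.start_s + ar.duration_s <= self.duration_s):
                raise ValidationError("artifact schedule falls outside the session")
        # overlapping seizures on one animal are ambiguous ground truth
        by_animal: dict[int, list[tuple[float, float]]] = {}
        for sz in self.seizures:
            iv = (sz.start_s, sz.start_s + sz.duration_s)
            for other in by_animal.get(sz.animal, []):
                if iv[0] < other[1] and other[0] < iv[1]:
                    raise ValidationError(
                        f"overlapping seizure schedules on animal {sz.animal}: "
                        f"{other} and {iv}"
                    )
            by_animal.setdefault(sz.animal, []).append(iv)

    @property
    def n_channels(self) -> int:
        return 2 * self.n_animals

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationSpec":
        doc = dict(doc)
        if "background" in doc:
            doc["background"] = BackgroundSpec(**doc["background"])
        if "interictal" in doc:
            doc["interictal"] = InterictalSpec(**doc["interictal"])
        if "timing" in doc:
            doc["timing"] = TimingSpec(**doc["timing"])
        doc["seizures"] = [SeizureSchedule(**s) for s in doc.get("seizures", [])]
        doc["artifacts"] = [ArtifactSchedule(**a) for a in doc.get("artifacts", [])]
        return cls(**doc)

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationSpec":
        return cls.from_dict(_load_json_source(source))


@dataclass
class GroundTruth:
    """Exact schedules realized in a generated session, per channel."""

    seizure_intervals: dict[int, list[tuple[float, float]]]
    artifact_intervals: dict[int, list[tuple[float, float]]]
    interictal_spike_times: dict[int, list[float]]
    frame_table: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seizure_intervals": {
                str(k): [list(iv) for iv in v] for k, v in self.seizure_intervals.items()
            },
            "artifact_intervals": {
                str(k): [list(iv) for iv in v] for k, v in self.artifact_intervals.items()
            },
            "interictal_spike_times": {
                str(k): list(v) for k, v in self.interictal_spike_times.items()
            },
            "frame_table": [list(t) for t in self.frame_table],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        p = Path(source)
        doc = json.loads(p.read_text() if p.is_file() else str(source))
        return cls(
            seizure_intervals={
                int(k): [tuple(iv) for iv in v]
                for k, v in doc["seizure_intervals"].items()
            },
            artifact_intervals={
                int(k): [tuple(iv) for iv in v]
                for k, v in doc["artifact_intervals"].items()
            },
            interictal_spike_times={
                int(k): list(v) for k, v in doc["interictal_spike_times"].items()
            },
            frame_table=[tuple(t) for t in doc.get("frame_table", [])],
        )


def _spectral_shaping(n: int, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    return shaping


def _one_over_f_noise(
    rng: np.random.Generator,
    n: int,
    exponent: float,
    shaping: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    if exponent == 0.0 or n < 4:
        return white
    if shaping is None:
        shaping = _spectral_shaping(n, exponent)
    spec = scipy_fft.rfft(white)
    spec *= shaping
    x = scipy_fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def spike_waveform(
    amplitude_uv: float, width_ms: float, sample_rate_hz: float
) -> np.ndarray:
    """Biphasic epileptiform spike: sharp positive lobe, slower negative lobe."""
    n = max(3, int(round(width_ms / 1000.0 * sample_rate_hz)))
    t = np.linspace(0.0, 1.0, n)
    pos = np.exp(-(((t - 0.3) / 0.1) ** 2))
    neg = np.exp(-(((t - 0.65) / 0.2) ** 2))
    w = pos - 0.5 * neg
    return amplitude_uv * w / w.max()


def _add_spikes(
    channel: np.ndarray, times_s: Sequence[float], waveform: np.ndarray, fs: float
) -> None:
    n = channel.size
    w = waveform.size
    for t in times_s:
        i = int(round(t * fs))
        if i >= n:
            continue
        j = min(i + w, n)
        channel[i:j] += waveform[: j - i]


def generate_signals(spec: SimulationSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the µV signal matrix ``[2 * n_animals x n_samples]`` plus truth."""
    fs = spec.sample_rate_hz
    n = spec.n_samples
    signals = np.zeros((spec.n_channels, n))
    noise_rng = np.random.default_rng([spec.seed, 0])
    event_rng = np.random.default_rng([spec.seed, 1])

    m = spec.shared_source_mixing
    sd = spec.background.noise_sd_uv
    expo = spec.background.one_over_f_exponent
    shaping = _spectral_shaping(n, expo) if expo != 0.0 and n >= 4 else None
    for a in range(spec.n_animals):
        common = _one_over_f_noise(noise_rng, n, expo, shaping)
        for side in range(2):
            own = _one_over_f_noise(noise_rng, n, expo, shaping)
            # sqrt mixing keeps the marginal SD at noise_sd_uv and the
            # expected L/R correlation at shared_source_mixing
            signals[2 * a + side] = sd * (
                math.sqrt(m) * common + math.sqrt(1.0 - m) * own
            )

    truth = GroundTruth(
        seizure_intervals={c: [] for c in range(spec.n_channels)},
        artifact_intervals={c: [] for c in range(spec.n_channels)},
        interictal_spike_times={c: [] for c in range(spec.n_channels)},
    )

    if spec.interictal.rate_hz > 0:
        iw = spike_waveform(spec.interictal.amplitude_uv, spec.interictal.width_ms, fs)
        for c in range(spec.n_channels):
            n_spikes = event_rng.poisson(spec.interictal.rate_hz * spec.duration_s)
            times = np.sort(event_rng.uniform(0.0, spec.duration_s, n_spikes))
            _add_spikes(signals[c], times, iw, fs)
            truth.interictal_spike_times[c] = [float(t) for t in times]

    for sz in spec.seizures:
        w = spike_waveform(sz.amplitude_uv, spec.interictal.width_ms, fs)
        times = np.arange(sz.start_s, sz.start_s + sz.duration_s, 1.0 / sz.spike_rate_hz)
        channels = (2 * sz.animal, 2 * sz.animal + 1) if sz.bilateral else (2 * sz.animal,)
        for c in channels:
            _add_spikes(signals[c], times, w, fs)
            truth.seizure_intervals[c].append(
                (float(sz.start_s), float(sz.start_s + sz.duration_s))
            )

    for ar in spec.artifacts:
        i0 = int(round(ar.start_s * fs))
        i1 = min(int(round((ar.start_s + ar.duration_s) * fs)), n)
        if i1 <= i0:
            continue
        channels = (
            range(spec.n_channels)
            if ar.animal is None
            else (2 * ar.animal, 2 * ar.animal + 1)
        )
        for c in channels:
            signals[c, i0:i1] += ar.amplitude_uv * event_rng.standard_normal(i1 - i0)
            truth.artifact_intervals[c].append(
                (float(ar.start_s), float(ar.start_s + ar.duration_s))
            )
    return signals, truth


def simulate_frame_assignment(spec: SimulationSpec) -> list[PacketRecord]:
    """Assign each packet the most recent video frame at its emission time.

    Packet k (0-based) is emitted when its last sample has been acquired,
    at ``(k + 1) * P / rate + latency``. Frame j (1-based) is acquired at
    ``j * frame_period + jitter``. The assigned index is the count of
    frames acquired no later than the packet emission — non-decreasing by
    construction.
    """
    spp = spec.samples_per_packet
    fs = spec.sample_rate_hz
    n_packets = spec.n_samples // spp
    packet_period = spp / fs
    latency = spec.timing.packet_emit_latency_ms / 1000.0
    emit_times = (np.arange(1, n_packets + 1) * packet_period) + latency

    frame_period = spec.timing.frame_period_ms / 1000.0
    n_frames = int(math.ceil((emit_times[-1] if n_packets else 0.0) / frame_period)) + 2
    frame_times = np.arange(1, n_frames + 1) * frame_period
    if spec.timing.frame_latency_jitter_ms > 0:
        jitter_rng = np.random.default_rng([spec.seed, 2])
        frame_times = frame_times + jitter_rng.uniform(
            0.0, spec.timing.frame_latency_jitter_ms / 1000.0, n_frames
        )
        frame_times = np.sort(frame_times)

    assigned = np.searchsorted(frame_times, emit_times, side="right")
    records = []
    for k in range(n_packets):
        records.append(
            PacketRecord(
                packet_index=k,
                sample_timestamps=np.arange(k * spp, (k + 1) * spp, dtype=np.int64),
                frame_index=int(assigned[k]),
            )
        )
    return records


def session_config_for(spec: SimulationSpec) -> SessionConfig:
    return SessionConfig(
        num_channels=spec.n_channels,
        animals=[
            AnimalChannels(animal_id=f"m{a}", left_channel=2 * a, right_channel=2 * a + 1)
            for a in range(spec.n_animals)
        ],
        sample_rate_hz=spec.sample_rate_hz,
        samples_per_packet=spec.samples_per_packet,
        scale_uv_per_bit=spec.scale_uv_per_bit,
        raw_offset_bits=RAW_MIDPOINT,
        nominal_frame_rate_hz=1000.0 / spec.timing.frame_period_ms,
    )


def _segment_label(index: int, segment_length_s: float) -> str:
    start = _dt.datetime(2000, 1, 1) + _dt.timedelta(seconds=index * segment_length_s)
    return start.strftime("%Y-%m-%dT%H-%M-%S")


def write_session(
    signals: np.ndarray,
    records: Sequence[PacketRecord],
    spec: SimulationSpec,
    out_dir: str | Path,
    segment_length_s: float = 3600.0,
    drop_packets: Sequence[int] = (),
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write hourly amplifier/timestamp segments plus config and sidecars.

    ``drop_packets`` removes the listed global packet indices from both
    streams (continuity-gap injection).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = session_config_for(spec)
    spp = spec.samples_per_packet
    n_packets = min(len(records), signals.shape[1] // spp)
    drops = set(int(d) for d in drop_packets)
    raw = microvolts_to_raw(signals, config)

    packets_per_segment = max(1, int(round(segment_length_s * spec.sample_rate_hz / spp)))
    n_segments = max(1, math.ceil(n_packets / packets_per_segment))
    for s in range(n_segments):
        kept = [
            k
            for k in range(s * packets_per_segment, min((s + 1) * packets_per_segment, n_packets))
            if k not in drops
        ]
        if not kept:
            continue
        label = _segment_label(s, segment_length_s)
        paths = segment_paths(out_dir, label)
        seg_raw = np.concatenate(
            [raw[:, k * spp : (k + 1) * spp] for k in kept], axis=1
        )
        write_amplifier(seg_raw, config, paths["amplifier"])
        write_timestamp_file([records[k] for k in kept], config, paths["ts"])

    write_config(config, out_dir / "config.json")
    spec.to_json(out_dir / "simulation_spec.json")
    if ground_truth is not None:
        ground_truth.frame_table = [
            (r.packet_index, r.frame_index) for r in records
        ]
        ground_truth.to_json(out_dir / "ground_truth.json")
    return out_dir


def generate_session(
    spec: SimulationSpec,
    out_dir: str | Path,
    segment_length_s: float = 3600.0,
    drop_packets: Sequence[int] = (),
) -> tuple[Path, GroundTruth]:
    """Generate signals + frame assignment and write the full session."""
    signals, truth = generate_signals(spec)
    records = simulate_frame_assignment(spec)
    path = write_session(
        signals,
        records,
        spec,
        out_dir,
        segment_length_s=segment_length_s,
        drop_packets=drop_packets,
        ground_truth=truth,
    )
    return path, truth
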