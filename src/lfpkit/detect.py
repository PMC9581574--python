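"""Seizure detection: amplitude-threshold and spectral algorithms.

Both algorithms share the same back end. The detection trace (bandpassed
voltage for the amplitude method, sliding-window FFT band power for the
spectral method) is thresholded at ``mean + N * SD``; supra-threshold
peaks are grouped into bursts when consecutive peaks fire at or above a
minimum frequency, bursts closer than a merge window are concatenated,
and merged bursts shorter than a minimum duration are discarded.

Conventions (documented because the reference description leaves them
open):

* Downsampling is anti-aliased by default — zero-phase low-pass at 0.45x
  the target rate, then every k-th sample; ``plain_decimation`` skips the
  filter.
* The bandpass is a 4th-order Butterworth applied zero-phase (filtfilt),
  so peak timing carries no group delay.
* Peaks are positive-going local maxima strictly above threshold; plateau
  peaks report their first sample. Negative-going events are handled by
  ``sign_multiplier = -1``.
* Burst grouping uses inter-peak interval <= 1/min_burst_freq_hz
  (3 Hz => 333.3 ms inclusive); merging uses last-peak -> first-peak gap
  <= merge_window_s inclusive.
* Spectral band power is the mean of |DFT|^2 over bins whose center
  frequency lies in [band_low, band_high] inclusive, rectangular window,
  window hop 1 sample, timestamped at the window start. At 500 Hz with a
  128-point window (3.90625 Hz resolution) the 4-40 Hz band selects bins
  2-10.
* The spectral path downsamples but does not bandpass before the FFT;
  ``spectral_prefilter = True`` enables the bandpass.
* Event onset/offset are the first/last peak times of the merged burst;
  no boundary refinement is attempted.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ParameterError

METHOD_AMPLITUDE = "amplitude"
METHOD_SPECTRAL = "spectral"


@dataclass
class DetectionSettings:
    """All detector parameters; ``threshold_n_sd`` and ``min_duration_s``
    are the user-set knobs, the rest default to the platform values."""

    threshold_n_sd: float
    min_duration_s: float
    method: str = METHOD_AMPLITUDE
    downsample_hz: float = 500.0
    band_low_hz: float = 3.0
    band_high_hz: float = 50.0
    sign_multiplier: int = 1
    min_burst_freq_hz: float = 3.0
    merge_window_s: float = 2.5
    spectral_window_n: int = 128
    spectral_band_low_hz: float = 4.0
    spectral_band_high_hz: float = 40.0
    plain_decimation: bool = False
    spectral_prefilter: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.method not in (METHOD_AMPLITUDE, METHOD_SPECTRAL):
            raise ParameterError(f"unknown method {self.method!r}")
        if self.sign_multiplier not in (1, -1):
            raise ParameterError("sign_multiplier must be +1 or -1")
        if self.threshold_n_sd <= 0:
            raise ParameterError("threshold_n_sd must be positive")
        if self.min_duration_s < 0:
            raise ParameterError("min_duration_s must be >= 0")
        if self.merge_window_s < 0:
            raise ParameterError("merge_window_s must be >= 0")
        if self.min_burst_freq_hz <= 0:
            raise ParameterError("min_burst_freq_hz must be positive")
        nyq = self.downsample_hz / 2.0
        if not (0 < self.band_low_hz < self.band_high_hz < nyq):
            raise ParameterError(
                f"bandpass edges must satisfy 0 < low < high < {nyq} Hz, "
                f"got [{self.band_low_hz}, {self.band_high_hz}]"
            )
        if not (0 <= self.spectral_band_low_hz < self.spectral_band_high_hz <= nyq):
            raise ParameterError("spectral band must lie within [0, Nyquist]")
        if self.spectral_window_n < 1:
            raise ParameterError("spectral_window_n must be >= 1")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DetectionSettings":
        if isinstance(source, Path):
            doc = json.loads(source.read_text())
        else:
            try:
                doc = json.loads(str(source))
            except json.JSONDecodeError:
                doc = json.loads(Path(str(source)).read_text())
        return cls(**doc)

    def settings_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


@dataclass
class SeizureEvent:
    """One detected event; times are seconds relative to segment start."""

    onset_s: float
    offset_s: float
    peak_times_s: np.ndarray
    channel: int
    method: str
    threshold_used: float

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=np.float64)
        if self.peak_times_s.size < 1:
            raise ParameterError("an event must contain at least one peak")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times_s.size)


def preprocess(
    trace: np.ndarray, settings: DetectionSettings, sample_rate_hz: float
) -> np.ndarray:
    """Downsample to ``downsample_hz`` then zero-phase bandpass and sign-flip."""
    x = _downsample(np.asarray(trace, dtype=np.float64), settings, sample_rate_hz)
    sos = signal.butter(
        4,
        [settings.band_low_hz, settings.band_high_hz],
        btype="bandpass",
        fs=settings.downsample_hz,
        output="sos",
    )
    return settings.sign_multiplier * signal.sosfiltfilt(sos, x)


def _downsample(
    x: np.ndarray, settings: DetectionSettings, sample_rate_hz: float
) -> np.ndarray:
    if settings.downsample_hz > sample_rate_hz:
        raise ParameterError(
            f"downsample_hz ({settings.downsample_hz}) exceeds the input "
            f"sample rate ({sample_rate_hz})"
        )
    ratio = sample_rate_hz / settings.downsample_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ParameterError(
            f"sample rate {sample_rate_hz} is not an integer multiple of "
            f"downsample_hz {settings.downsample_hz}"
        )
    if q == 1:
        return x.copy()
    n_out = x.size // q
    if n_out < 64:
        raise ParameterError(
            f"trace too short: {x.size} samples decimate to {n_out} < 64 "
            "(filter warm-up minimum)"
        )
    if not settings.plain_decimation:
        cutoff = 0.45 * settings.downsample_hz
        sos = signal.butter(4, cutoff, btype="low", fs=sample_rate_hz, output="sos")
        x = signal.sosfiltfilt(sos, x)
    return x[: n_out * q : q]


def compute_threshold(detection_trace: np.ndarray, n_sd: float) -> float:
    """``mean + N * SD`` over the full analyzed trace (population SD)."""
    x = np.asarray(detection_trace, dtype=np.float64)
    if x.size == 0:
        raise ParameterError("cannot threshold an empty trace")
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn("constant detection trace: SD is zero, threshold = mean")
    return float(x.mean()) + n_sd * sd


def find_peaks_above(
    detection_trace: np.ndarray, threshold: float, downsample_hz: float
) -> np.ndarray:
    """Times (s) of local maxima strictly above threshold.

    Plateau peaks report their first sample; trace endpoints are never peaks.
    """
    x = np.asarray(detection_trace, dtype=np.float64)
    _, props = signal.find_peaks(x, plateau_size=1)
    idx = props["left_edges"]
    idx = idx[x[idx] > threshold]
    return idx / downsample_hz


def group_peaks_to_bursts(
    peak_times: np.ndarray, min_burst_freq_hz: float
) -> list[np.ndarray]:
    """Split sorted peak times into bursts at gaps > 1/min_burst_freq_hz."""
    t = np.asarray(peak_times, dtype=np.float64)
    if t.size == 0:
        return []
    max_gap = 1.0 / min_burst_freq_hz
    cuts = np.nonzero(np.diff(t) > max_gap)[0] + 1
    return np.split(t, cuts)


def merge_bursts(
    bursts: Sequence[np.ndarray], merge_window_s: float
) -> list[np.ndarray]:
    """Concatenate consecutive bursts whose last->first gap <= merge_window_s.

    One left-to-right pass over time-ordered bursts reaches the fixed
    point, so the operation is idempotent.
    """
    merged: list[np.ndarray] = []
    for burst in bursts:
        if merged and burst[0] - merged[-1][-1] <= merge_window_s:
            merged[-1] = np.concatenate([merged[-1], burst])
        else:
            merged.append(np.asarray(burst, dtype=np.float64))
    return merged


def filter_by_duration(
    bursts: Sequence[np.ndarray],
    min_duration_s: float,
    *,
    channel: int = 0,
    method: str = METHOD_AMPLITUDE,
    threshold_used: float = float("nan"),
) -> list[SeizureEvent]:
    """Keep merged bursts spanning >= min_duration_s as seizure events."""
    events = []
    for burst in bursts:
        if burst[-1] - burst[0] >= min_duration_s:
            events.append(
                SeizureEvent(
                    onset_s=float(burst[0]),
                    offset_s=float(burst[-1]),
                    peak_times_s=burst,
                    channel=channel,
                    method=method,
                    threshold_used=threshold_used,
                )
            )
    return events


def sliding_band_power(
    detection_trace: np.ndarray,
    spectral_window_n: int,
    band: tuple[float, float],
    downsample_hz: float,
) -> np.ndarray:
    """Mean |DFT|^2 over in-band bins in a rectangular window sliding by 1.

    Output has ``len - window + 1`` elements, each timestamped at its
    window start. Band bins are those k with ``k * fs / W`` inside the
    band, inclusive at both edges.
    """
    x = np.asarray(detection_trace, dtype=np.float64)
    w = int(spectral_window_n)
    if x.size < w:
        raise ParameterError(
            f"trace of {x.size} samples is shorter than the {w}-point window"
        )
    bins = band_bins(w, band, downsample_hz)
    if bins.size == 0:
        raise ParameterError(f"no DFT bins fall inside the band {band}")
    power = np.zeros(x.size - w + 1)
    n = np.arange(w)
    for k in bins:
        # correlation of x with e^{-i 2 pi k n / W}: valid-mode sliding DFT bin
        kernel = np.exp(-2j * np.pi * k * n / w)[::-1]
        xk = signal.fftconvolve(x, kernel, mode="valid")
        power += np.abs(xk) ** 2
    return power / bins.size


def band_bins(
    spectral_window_n: int, band: tuple[float, float], downsample_hz: float
) -> np.ndarray:
    """DFT bin indices whose center frequency lies in the band (inclusive)."""
    k = np.arange(spectral_window_n // 2 + 1)
    freqs = k * downsample_hz / spectral_window_n
    lo, hi = band
    return k[(freqs >= lo) & (freqs <= hi)]


def detect_amplitude(
    trace: np.ndarray,
    settings: DetectionSettings,
    sample_rate_hz: float,
    channel: int = 0,
) -> list[SeizureEvent]:
    """Full amplitude algorithm: preprocess -> threshold -> peaks -> bursts."""
    det = preprocess(trace, settings, sample_rate_hz)
    threshold = compute_threshold(det, settings.threshold_n_sd)
    peaks = find_peaks_above(det, threshold, settings.downsample_hz)
    bursts = group_peaks_to_bursts(peaks, settings.min_burst_freq_hz)
    merged = merge_bursts(bursts, settings.merge_window_s)
    return filter_by_duration(
        merged,
        settings.min_duration_s,
        channel=channel,
        method=METHOD_AMPLITUDE,
        threshold_used=threshold,
    )


def detect_spectral(
    trace: np.ndarray,
    settings: DetectionSettings,
    sample_rate_hz: float,
    channel: int = 0,
) -> list[SeizureEvent]:
    """Spectral algorithm: downsample -> sliding band power -> same back end."""
    x = _downsample(np.asarray(trace, dtype=np.float64), settings, sample_rate_hz)
    if settings.spectral_prefilter:
        sos = signal.butter(
            4,
            [settings.band_low_hz, settings.band_high_hz],
            btype="bandpass",
            fs=settings.downsample_hz,
            output="sos",
        )
        x = signal.sosfiltfilt(sos, x)
    power = sliding_band_power(
        x,
        settings.spectral_window_n,
        (settings.spectral_band_low_hz, settings.spectral_band_high_hz),
        settings.downsample_hz,
    )
    threshold = compute_threshold(power, settings.threshold_n_sd)
    peaks = find_peaks_above(power, threshold, settings.downsample_hz)
    bursts = group_peaks_to_bursts(peaks, settings.min_burst_freq_hz)
    merged = merge_bursts(bursts, settings.merge_window_s)
    return filter_by_duration(
        merged,
        settings.min_duration_s,
        channel=channel,
        method=METHOD_SPECTRAL,
        threshold_used=threshold,
    )


def detect(
    trace: np.ndarray,
    settings: DetectionSettings,
    sample_rate_hz: float,
    channel: int = 0,
) -> list[SeizureEvent]:
    """Dispatch on ``settings.method``."""
    fn = detect_amplitude if settings.method == METHOD_AMPLITUDE else detect_spectral
    return fn(trace, settings, sample_rate_hz, channel=channel)


def events_to_dataframe(
    events: Sequence[SeizureEvent], settings: DetectionSettings | None = None
) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "event_id": i,
                "channel": ev.channel,
                "method": ev.method,
                "onset_s": ev.onset_s,
                "offset_s": ev.offset_s,
                "duration_s": ev.duration_s,
                "n_peaks": ev.n_peaks,
                "threshold_n_sd": settings.threshold_n_sd if settings else np.nan,
                "settings_hash": settings.settings_hash() if settings else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "channel",
            "method",
            "onset_s",
            "offset_s",
            "duration_s",
            "n_peaks",
            "threshold_n_sd",
            "settings_hash",
        ],
    )
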