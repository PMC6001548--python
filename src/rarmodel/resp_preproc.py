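"""Respiratory preprocessing: from raw chest-belt traces to amplitude time series.

A raw single-channel respiration trace (bellows or MRI-compatible pressure
cushion) is converted to a uniformly sampled respiration-amplitude time
series in four steps:

1. inspiration-onset detection on a smoothed copy of the trace,
2. per-cycle amplitude extraction (peak-to-trough between onsets),
3. linear interpolation of the cycle amplitudes onto a uniform grid,
4. zero-phase Butterworth band-pass filtering (0.01-2 Hz).

The detection chain mean-centers the trace, band-pass filters it between
0.01 and 0.6 Hz, and median-filters it over 1 s. For bellows devices
(inspiratory pressure drop) the negative zero crossings of the smoothed
trace mark inspiration onsets; for cushion devices the local minima do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RespirationTrace",
    "CycleSeries",
    "AmplitudeTimeseries",
    "InsufficientDataError",
    "NoCyclesError",
    "detect_inspiration_onsets",
    "extract_cycle_amplitudes",
    "interpolate_amplitude",
    "bandpass_amplitude",
    "butter_bandpass_filtfilt",
]

DEVICES = ("bellows", "cushion")

#: minimum trace duration (s) for meaningful cycle detection
MIN_DETECT_DURATION_S = 30.0

#: detection pre-filter band (Hz) and median-filter window (s)
DETECT_BAND_HZ = (0.01, 0.6)
DETECT_MEDIAN_S = 1.0

#: amplitude-series band-pass (Hz)
AMPLITUDE_BAND_HZ = (0.01, 2.0)

#: default grid rate (Hz) for the interpolated amplitude series; ample for a
#: signal band-limited at 2 Hz
DEFAULT_GRID_SR = 10.0

#: minimum inter-breath interval (s); crossings closer than this to the
#: previously kept onset are discarded
REFRACTORY_S = 1.0


class InsufficientDataError(ValueError):
    """Trace too short for the filter settling window."""


class NoCyclesError(ValueError):
    """No respiratory cycles detected."""


@dataclass
class RespirationTrace:
    """Raw sampled respiration signal.

    Parameters
    ----------
    samples : array-like
        Pressure/displacement samples in arbitrary, device-dependent units.
    sampling_rate : float
        Sampling rate in Hz.
    device : {"bellows", "cushion"}
        Transducer type. Bellows traces show a sharp inspiratory pressure
        drop; cushion traces have their minima at inspiration onset.
    """

    samples: np.ndarray
    sampling_rate: float
    device: str = "bellows"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.device not in DEVICES:
            raise ValueError(f"unknown device {self.device!r}; expected one of {DEVICES}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class CycleSeries:
    """Inspiration onsets with one amplitude per complete inter-onset cycle."""

    inspiration_onsets: np.ndarray
    cycle_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.inspiration_onsets = np.asarray(self.inspiration_onsets, dtype=float)
        self.cycle_amplitudes = np.asarray(self.cycle_amplitudes, dtype=float)
        if self.inspiration_onsets.size < 2 or np.any(np.diff(self.inspiration_onsets) <= 0):
            raise ValueError("invalid cycle series: onsets must be strictly increasing")
        if self.cycle_amplitudes.size != self.inspiration_onsets.size - 1:
            raise ValueError("invalid cycle series: need one amplitude per inter-onset interval")
        if np.any(self.cycle_amplitudes < 0):
            raise ValueError("invalid cycle series: amplitudes must be non-negative")


@dataclass
class AmplitudeTimeseries:
    """Respiration-amplitude signal on a uniform grid."""

    values: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("amplitude series contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sampling_rate

    def __len__(self) -> int:
        return self.values.size


def butter_bandpass_filtfilt(
    x: np.ndarray,
    sampling_rate: float,
    low_hz: float,
    high_hz: float,
    order: int = 1,
    demean: bool = False,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass.

    ``order`` is the order of each pass, so the effective magnitude response
    is the squared single-pass response. With ``demean=True`` the residual
    mean left by the finite-length transient is subtracted afterwards.
    """
    nyq = sampling_rate / 2.0
    if high_hz >= nyq:
        raise ValueError(
            f"sampling rate too low for {high_hz:g} Hz low-pass (Nyquist {nyq:g} Hz)"
        )
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    # pad well past the high-pass time constant (~1/(2 pi low_hz)) so the
    # edge transients of the bidirectional pass stay negligible
    padlen = min(x.size - 1, int(round(3.0 / low_hz * sampling_rate)))
    y = signal.sosfiltfilt(sos, x, padlen=padlen)
    if demean:
        y = y - y.mean()
    return y


def _rolling_median(x: np.ndarray, window_samples: int) -> np.ndarray:
    w = max(3, int(window_samples) | 1)  # odd, >= 3
    return (
        pd.Series(x).rolling(w, center=True, min_periods=1).median().to_numpy()
    )


def _apply_refractory(onsets: np.ndarray, refractory: float) -> np.ndarray:
    """Drop onsets closer than ``refractory`` to the last kept one (keep earliest)."""
    kept: list[float] = []
    for t in onsets:
        if not kept or t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def detect_inspiration_onsets(
    trace: RespirationTrace, refractory: float = REFRACTORY_S
) -> np.ndarray:
    """Detect inspiration-onset times (seconds from trace start).

    The trace is mean-centered, band-pass filtered (0.01-0.6 Hz, order-1
    bidirectional Butterworth) and median-filtered over 1 s. For bellows
    devices, onsets are the negative zero crossings of the smoothed trace;
    for cushion devices, onsets are its local minima (positive zero
    crossings of the first difference). Crossings falling exactly on zero
    are assigned to the first sample at/after the sign change; onsets
    within the refractory window of the previously kept onset are dropped.

    Raises
    ------
    InsufficientDataError
        If the trace is shorter than the settling window (30 s).
    NoCyclesError
        If fewer than two onsets survive.
    """
    sr = trace.sampling_rate
    if trace.duration < MIN_DETECT_DURATION_S:
        raise InsufficientDataError(
            f"insufficient data: need at least {MIN_DETECT_DURATION_S:g} s, "
            f"got {trace.duration:.1f} s"
        )
    x = trace.samples - trace.samples.mean()
    x = butter_bandpass_filtfilt(x, sr, *DETECT_BAND_HZ, order=1)
    x = _rolling_median(x, round(DETECT_MEDIAN_S * sr))

    if trace.device == "cushion":
        d = np.diff(x)
        # first sample of a minimum (or of a plateau run at the minimum)
        idx = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    else:
        idx = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)) + 1

    onsets = _apply_refractory(idx / sr, refractory)
    if onsets.size < 2:
        raise NoCyclesError("no respiratory cycles detected")
    return onsets


def extract_cycle_amplitudes(trace: RespirationTrace, onsets: np.ndarray) -> CycleSeries:
    """Peak-to-trough amplitude of the raw (mean-centered) trace per cycle.

    For each inter-onset interval the amplitude is max - min of the raw
    trace within the interval (endpoints inclusive). Amplitudes are
    measured on the unfiltered trace so that they are monotone in the
    tidal excursion and unaffected by the detection filter.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 2 or np.any(np.diff(onsets) <= 0):
        raise ValueError("invalid cycle series: onsets must be strictly increasing")
    sr = trace.sampling_rate
    x = trace.samples - trace.samples.mean()
    n = x.size
    amps = np.empty(onsets.size - 1)
    for i, (a, b) in enumerate(zip(onsets[:-1], onsets[1:])):
        i0 = max(0, int(round(a * sr)))
        i1 = min(n - 1, int(round(b * sr)))
        seg = x[i0 : i1 + 1]
        amps[i] = seg.max() - seg.min()
    return CycleSeries(onsets, amps)


def interpolate_amplitude(
    cycles: CycleSeries,
    sampling_rate: float = DEFAULT_GRID_SR,
    duration: float | None = None,
) -> AmplitudeTimeseries:
    """Linearly interpolate cycle amplitudes onto a uniform grid.

    Each cycle amplitude is anchored at its cycle's inspiration onset;
    values before the first / after the last anchor are held constant.
    The grid spans [0, duration]; ``duration`` defaults to the last
    detected onset.
    """
    amps = cycles.cycle_amplitudes
    if amps.size < 2:
        raise ValueError("need at least 2 cycle amplitudes to interpolate")
    anchors = cycles.inspiration_onsets[:-1]
    if duration is None:
        duration = float(cycles.inspiration_onsets[-1])
    if duration < anchors[-1]:
        warnings.warn(
            f"truncation: duration {duration:g} s ends before the last cycle "
            f"anchor at {anchors[-1]:g} s",
            stacklevel=2,
        )
    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    values = np.interp(t, anchors, amps)
    return AmplitudeTimeseries(values, sampling_rate, t0=0.0)


def bandpass_amplitude(ts: AmplitudeTimeseries) -> AmplitudeTimeseries:
    """Band-pass filter the amplitude series (0.01-2 Hz, zero-phase).

    Removes high-frequency noise and slow drift of the recording device.
    The residual mean left by the finite-length transient is subtracted so
    the output is zero-mean to machine precision.
    """
    if ts.sampling_rate <= 2 * AMPLITUDE_BAND_HZ[1]:
        raise ValueError(
            f"sampling rate too low for {AMPLITUDE_BAND_HZ[1]:g} Hz low-pass"
        )
    values = butter_bandpass_filtfilt(
        ts.values, ts.sampling_rate, *AMPLITUDE_BAND_HZ, order=1, demean=True
    )
    return AmplitudeTimeseries(values, ts.sampling_rate, t0=ts.t0)


def preprocess_trace(
    trace: RespirationTrace,
    grid_sampling_rate: float = DEFAULT_GRID_SR,
    duration: float | None = None,
) -> tuple[np.ndarray, CycleSeries, AmplitudeTimeseries]:
    """Full preprocessing chain: detect, extract, interpolate, filter.

    Returns (onsets, cycle series, filtered amplitude series). The grid
    duration defaults to the full trace duration.
    """
    onsets = detect_inspiration_onsets(trace)
    cycles = extract_cycle_amplitudes(trace, onsets)
    if duration is None:
        duration = trace.duration
    ts = interpolate_amplitude(cycles, grid_sampling_rate, duration)
    return onsets, cycles, bandpass_amplitude(ts)
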