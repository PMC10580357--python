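"""Patch-clamp feature extraction: spontaneous PSC events, action-potential
waveform features from ramp protocols, and cell-attached firing rates.

Conventions
-----------
* Voltage clamp: signal in pA.  sEPSCs are inward (negative deflections,
  holding −70 mV); sIPSCs are outward (positive deflections, holding 0 mV).
* Current clamp: signal in mV.  Spikes are detected by an upward dV/dt
  crossing (default 20 mV/ms); amplitude is measured from the
  threshold-crossing voltage to the peak, rise time is the 10–90% interval
  of that excursion, half-width is the interpolated full width at
  half-amplitude, and area is the integral above the threshold-crossing
  voltage between onset and return.  RMP is reported separately so the
  from-RMP amplitude convention stays recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EphysSweep",
    "PscEvent",
    "PscStats",
    "ApFeatures",
    "detect_psc",
    "psc_stats",
    "ap_features",
    "firing_rate",
]

MODES = ("voltage_clamp", "current_clamp", "cell_attached")


@dataclass
class EphysSweep:
    """A single recorded sweep: evenly sampled signal plus acquisition metadata."""

    signal: np.ndarray
    sampling_rate: float
    mode: str
    holding_mv: float | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1 or self.signal.size == 0:
            raise ValueError("signal must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def duration(self) -> float:
        return self.signal.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.sampling_rate


@dataclass
class PscEvent:
    time: float
    amplitude: float  # positive magnitude, pA
    polarity: str

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.polarity not in ("EPSC", "IPSC"):
            raise ValueError("polarity must be EPSC or IPSC")


@dataclass
class PscStats:
    frequency_hz: float
    mean_amplitude_pa: float
    intervals_s: np.ndarray
    interval_cdf: pd.DataFrame
    amplitude_cdf: pd.DataFrame


@dataclass
class ApFeatures:
    rmp: float
    amplitude: float
    half_width: float  # ms
    rise_time: float  # ms
    area: float  # mV*ms
    spike_count: int

    def __post_init__(self) -> None:
        if self.spike_count > 0 and self.half_width <= 0:
            raise ValueError("half_width must be positive when spikes present")


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return float(1.4826 * mad)


def detect_psc(
    sweep: EphysSweep,
    polarity: str = "EPSC",
    k_sigma: float = 4.0,
    min_interval_ms: float = 20.0,
) -> list[PscEvent]:
    """Threshold-based detection of spontaneous postsynaptic currents.

    The sweep is median-subtracted; crossings of ``k_sigma`` times the
    robust SD in the polarity's direction mark candidate events, whose
    amplitude is the peak deviation within the suprathreshold region.
    Detection uses hysteresis: once triggered, an event extends until
    the signal falls back below half-threshold, so noise dithering on a
    slow decay tail does not retrigger.  Peaks closer than
    ``min_interval_ms`` are merged (the larger wins).  Adding any
    constant offset to the sweep leaves the output unchanged.
    """
    if sweep.mode != "voltage_clamp":
        raise ValueError("PSC detection requires a voltage_clamp sweep")
    if polarity not in ("EPSC", "IPSC"):
        raise ValueError("polarity must be EPSC or IPSC")
    sign = -1.0 if polarity == "EPSC" else 1.0
    y = sign * (sweep.signal - np.median(sweep.signal))
    sd = _robust_sd(y)
    peak_abs = float(np.max(np.abs(y))) if y.size else 0.0
    sd = max(sd, 1e-3 * peak_abs)  # numerical floor for noiseless sweeps
    if sd == 0:
        return []
    th = k_sigma * sd
    above = y > th
    if not above.any():
        return []
    padded = np.r_[False, above, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    peaks: list[int] = []
    last_end = -1
    for s, e in zip(starts, ends):
        if s < last_end:  # swallowed by the previous event's hysteresis
            continue
        # hysteresis: hold until the signal is back in the noise band,
        # so a slow decay tail cannot retrigger the detector
        j = e
        while j < y.size and y[j] > 0.5 * sd:
            j += 1
        peaks.append(s + int(np.argmax(y[s:j])))
        last_end = j
    min_gap = min_interval_ms / 1000.0 * sweep.sampling_rate
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < min_gap:
            if y[p] > y[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    return [
        PscEvent(time=p / sweep.sampling_rate, amplitude=float(y[p]), polarity=polarity)
        for p in merged
    ]


def _ecdf(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(np.asarray(values, dtype=float))
    q = np.arange(1, v.size + 1) / v.size if v.size else np.array([])
    return pd.DataFrame({"value": v, "quantile": q})


def psc_stats(events: list[PscEvent], duration: float) -> PscStats:
    """Frequency, mean amplitude, inter-event intervals, and empirical CDFs."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    times = np.array(sorted(ev.time for ev in events))
    amps = np.array([ev.amplitude for ev in events])
    intervals = np.diff(times)
    return PscStats(
        frequency_hz=len(events) / duration,
        mean_amplitude_pa=float(np.mean(amps)) if len(events) else float("nan"),
        intervals_s=intervals,
        interval_cdf=_ecdf(intervals),
        amplitude_cdf=_ecdf(amps),
    )


def _interp_crossing(t: np.ndarray, v: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where v crosses `level` between samples i-1 and i."""
    if i == 0 or v[i] == v[i - 1]:
        return float(t[i])
    frac = (level - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def measure_spike(
    v: np.ndarray,
    sampling_rate: float,
    dvdt_threshold: float = 20.0,
    start: int = 0,
    max_width_ms: float = 10.0,
) -> tuple[dict, int] | None:
    """Measure the first spike in ``v[start:]`` by the dV/dt-threshold convention.

    Returns a dict of waveform features (amplitude mV, half_width ms,
    rise_time ms, area mV*ms, onset/peak sample indices) and the sample
    index where the spike region ends, or None if no spike is found.
    The spike region runs from the dV/dt crossing until the voltage
    returns to the crossing value, capped at ``max_width_ms`` — on a
    depolarizing ramp the baseline keeps climbing, so without the cap a
    waveform that ends marginally above its onset voltage would swallow
    the rest of the sweep.  Shared between the extractor and the sweep
    generator so simulated ground truth uses the same measurement
    definitions.
    """
    fs = sampling_rate
    dt_ms = 1000.0 / fs
    dvdt = np.diff(v) * fs / 1000.0  # mV/ms, forward difference
    idx = np.flatnonzero((dvdt[start:] >= dvdt_threshold))
    if idx.size == 0:
        return None
    onset = start + int(idx[0])
    v_thr = float(v[onset])
    # peak: maximum before the trace next returns to the crossing voltage
    cap = onset + max(2, int(round(max_width_ms / dt_ms)))
    j = onset + 1
    while j < min(v.size, cap) and v[j] > v_thr:
        j += 1
    region_end = j
    if region_end <= onset + 1:
        return None
    peak = onset + 1 + int(np.argmax(v[onset + 1 : region_end]))
    v_peak = float(v[peak])
    amplitude = v_peak - v_thr
    if amplitude <= 0:
        return None
    t = np.arange(v.size) * dt_ms  # ms
    half = v_thr + amplitude / 2.0
    lo10 = v_thr + 0.1 * amplitude
    hi90 = v_thr + 0.9 * amplitude
    # rising-limb crossings (between onset and peak)
    rise_seg = slice(onset, peak + 1)

    def _rise_cross(level: float) -> float:
        seg = v[rise_seg]
        k = int(np.flatnonzero(seg >= level)[0])
        return _interp_crossing(t[rise_seg], seg, k, level)

    t10, t90 = _rise_cross(lo10), _rise_cross(hi90)
    t_half_up = _rise_cross(half)
    # falling-limb half crossing
    fall = v[peak:region_end + 1] if region_end < v.size else v[peak:]
    below = np.flatnonzero(fall <= half)
    if below.size:
        k = int(below[0])
        t_half_down = _interp_crossing(t[peak:][: fall.size], fall, k, half)
    else:
        t_half_down = t[min(region_end, v.size - 1)]
    # area above threshold-crossing voltage, onset -> return (trapezoid,
    # with interpolated end segment)
    seg_v = v[onset:region_end] - v_thr
    area = float(np.trapezoid(seg_v, dx=dt_ms))
    if region_end < v.size:
        # partial trapezoid to the interpolated return-to-threshold point
        t_ret = _interp_crossing(
            t[region_end - 1 : region_end + 1],
            v[region_end - 1 : region_end + 1],
            1,
            v_thr,
        )
        area += 0.5 * seg_v[-1] * (t_ret - t[region_end - 1])
    return (
        {
            "amplitude": amplitude,
            "half_width": t_half_down - t_half_up,
            "rise_time": t90 - t10,
            "area": area,
            "onset": onset,
            "peak": peak,
            "threshold_voltage": v_thr,
        },
        region_end,
    )


def ap_features(
    sweep: EphysSweep,
    pre_window_s: float = 0.2,
    dvdt_threshold: float = 20.0,
) -> ApFeatures:
    """Action-potential features from a current-clamp ramp sweep.

    RMP is the median of the first ``pre_window_s`` seconds (pre-stimulus);
    spikes are counted over the whole sweep; waveform features (amplitude,
    10–90% rise time, half-width, area) are those of the first spike.
    """
    if sweep.mode != "current_clamp":
        raise ValueError("AP analysis requires a current_clamp sweep")
    n_pre = int(round(pre_window_s * sweep.sampling_rate))
    if n_pre < 1:
        raise ValueError("no pre-stimulus window")
    rmp = float(np.median(sweep.signal[:n_pre]))
    spikes = []
    pos = 0
    while True:
        out = measure_spike(sweep.signal, sweep.sampling_rate, dvdt_threshold, start=pos)
        if out is None:
            break
        feats, end = out
        spikes.append(feats)
        pos = end + 1
    if not spikes:
        return ApFeatures(rmp=rmp, amplitude=0.0, half_width=0.0, rise_time=0.0,
                          area=0.0, spike_count=0)
    f = spikes[0]
    return ApFeatures(
        rmp=rmp,
        amplitude=f["amplitude"],
        half_width=f["half_width"],
        rise_time=f["rise_time"],
        area=f["area"],
        spike_count=len(spikes),
    )


def firing_rate(
    sweep: EphysSweep,
    k_sigma: float = 5.0,
    refractory_ms: float = 2.0,
) -> tuple[float, np.ndarray]:
    """Spontaneous firing rate (Hz) and spike amplitudes from a cell-attached sweep.

    Spikes are deflections exceeding ``k_sigma`` robust SDs in either
    direction (cell-attached spike polarity depends on seal geometry);
    deflections within ``refractory_ms`` are counted once.
    """
    if sweep.mode != "cell_attached":
        raise ValueError("firing-rate analysis requires a cell_attached sweep")
    y = np.abs(sweep.signal - np.median(sweep.signal))
    sd = _robust_sd(sweep.signal - np.median(sweep.signal))
    sd = max(sd, 1e-6 * float(np.max(y))) if y.size else sd
    if sd == 0:
        return 0.0, np.array([])
    th = k_sigma * sd
    above = y > th
    if not above.any():
        return 0.0, np.array([])
    padded = np.r_[False, above, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    peaks = [s + int(np.argmax(y[s:e])) for s, e in zip(starts, ends)]
    min_gap = refractory_ms / 1000.0 * sweep.sampling_rate
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < min_gap:
            if y[p] > y[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    amps = np.array([y[p] for p in merged])
    return len(merged) / sweep.duration, amps
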