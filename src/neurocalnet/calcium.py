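"""ΔF/F computation, calcium-transient detection, and per-neuron activity
summaries.

The central signal object is :class:`DffMatrix`: ΔF/F in percent, computed
against a running-percentile baseline F0.  Transients are detected as
excursions above ``k_sigma`` times a robust per-neuron noise estimate, with
the waveform constraint that a genuine calcium transient shows a sharp rise
followed by a slower decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TraceMatrix",
    "DffMatrix",
    "TransientEvent",
    "MetricSeries",
    "compute_dff",
    "detect_transients",
    "transient_stats",
    "normalize_to_baseline",
]

#: canonical longitudinal timepoint labels (pre-injury baseline + days post)
TIMEPOINTS = ("pre", "d1", "d3", "d7", "d14", "d21", "d28")


def running_percentile(
    x: np.ndarray, pct: float, window: int, stride: int = 10
) -> np.ndarray:
    """Centered running percentile along the last axis of a 2-D array.

    Evaluated exactly on a strided grid of centers and linearly
    interpolated in between — the baseline this estimates varies on the
    window timescale, far slower than the stride, so interpolation
    error is negligible while the cost drops by the stride factor.
    Edges replicate the boundary value (nearest-window behavior).

    The grid phase is dithered per row: a grid shared by every neuron
    would imprint one common periodic variance profile on all traces,
    which biases any alignment-sensitive statistic computed across
    neurons (e.g. correlations against time-shifted surrogates).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    window = min(window, n if n % 2 else n - 1)
    half = window // 2
    padded = np.pad(x, [(0, 0), (half, half)], mode="edge")
    win_view = sliding_window_view(padded, window, axis=-1)
    out = np.empty_like(x)
    grid = np.arange(n)
    for i in range(x.shape[0]):
        phase = (i * 7) % stride
        centers = np.arange(phase, n, stride)
        if centers[0] != 0:
            centers = np.r_[0, centers]
        if centers[-1] != n - 1:
            centers = np.r_[centers, n - 1]
        vals = np.percentile(win_view[i, centers, :], pct, axis=-1)
        out[i] = np.interp(grid, centers, vals)
    return out


@dataclass
class TraceMatrix:
    """Raw fluorescence traces, neurons x frames.

    Parameters
    ----------
    values : ndarray, shape (n_neurons, n_frames)
        Mean somatic fluorescence per ROI per frame (arbitrary units,
        background-subtracted upstream if requested).
    frame_rate : float
        Acquisition rate in Hz (30 Hz for resonant two-photon streaming).
    labels : list of str, optional
        Neuron/ROI identifiers; defaults to ``roi000, roi001, ...``.
    """

    values: np.ndarray
    frame_rate: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (neurons x frames)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite fluorescence values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.labels is None:
            self.labels = [f"roi{i:03d}" for i in range(self.values.shape[0])]
        elif len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels)


@dataclass
class DffMatrix:
    """ΔF/F in percent with its baseline provenance.

    ``dff[i, t] = 100 * (F[i, t] - F0[i, t]) / F0[i, t]``
    """

    dff: np.ndarray
    baseline_f0: np.ndarray
    frame_rate: float
    labels: list[str] | None = None
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.baseline_f0 = np.asarray(self.baseline_f0, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be 2-D")
        if np.any(self.baseline_f0 <= 0):
            raise ValueError("baseline_f0 must be positive wherever defined")
        if self.labels is None:
            self.labels = [f"roi{i:03d}" for i in range(self.dff.shape[0])]

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class TransientEvent:
    """One detected calcium transient.

    ``amplitude`` is peak ΔF/F minus the ΔF/F at onset (percent); the
    alternative "peak ΔF/F" convention is recoverable as
    ``amplitude + onset_value``.
    """

    neuron: int
    onset_frame: int
    peak_frame: int
    amplitude: float
    rise_time: float
    decay_time: float
    onset_value: float = 0.0
    shape_ok: bool = True

    def __post_init__(self) -> None:
        if self.onset_frame > self.peak_frame:
            raise ValueError("onset must not follow peak")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class MetricSeries:
    """A group-level metric tracked across longitudinal timepoints."""

    values: dict[str, float]
    name: str = "metric"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = dict(self.values)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def compute_dff(
    traces: TraceMatrix,
    percentile: float = 20.0,
    window_s: float = 30.0,
) -> DffMatrix:
    """Convert raw traces to percent ΔF/F against a running-percentile F0.

    F0 is the ``percentile``-th percentile of the raw trace in a centered
    window of ``window_s`` seconds (edge frames use the nearest full
    window).  A low percentile tracks slow drift while staying below the
    sparse transients, so the baseline is not inflated by activity.

    Raises
    ------
    ValueError
        If the resulting F0 is non-positive anywhere, naming the offending
        neuron(s) — ΔF/F is meaningless against a non-positive baseline.
    """
    f = traces.values
    if np.any(f <= 0):
        warnings.warn(
            "non-positive raw fluorescence found; baseline may be invalid "
            "(check background subtraction)",
            stacklevel=2,
        )
    win = max(3, int(round(window_s * traces.frame_rate)))
    if win % 2 == 0:
        win += 1
    f0 = running_percentile(f, percentile, win)
    bad = np.where(np.any(f0 <= 0, axis=1))[0]
    if bad.size:
        names = ", ".join(traces.labels[i] for i in bad)
        raise ValueError(f"non-positive baseline F0 for neuron(s): {names}")
    dff = 100.0 * (f - f0) / f0
    return DffMatrix(
        dff=dff,
        baseline_f0=f0,
        frame_rate=traces.frame_rate,
        labels=list(traces.labels),
        method={"baseline": "running_percentile", "percentile": percentile,
                "window_s": window_s},
    )


def robust_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD of a trace: 1.4826 * MAD of the first difference,
    rescaled by 1/sqrt(2) to undo the variance doubling of differencing.

    Differencing removes both slow drift and the transients themselves
    (their frame-to-frame increments are small relative to their peaks),
    so the estimate reflects the additive noise floor, not activity.
    """
    d = np.diff(np.asarray(x, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_transients(
    dff: DffMatrix,
    k_sigma: float = 3.0,
    min_separation_s: float = 1.0,
    shape_check: bool = True,
    min_duration_frames: int = 2,
    baseline_window_s: float = 30.0,
    smooth_frames: int = 7,
    onset_foot_frac: float = 0.3,
) -> list[TransientEvent]:
    """Detect calcium transients as suprathreshold excursions of ΔF/F.

    Per neuron, a local baseline (running median over
    ``baseline_window_s``) is subtracted first — the running-percentile
    F0 sits below the noise median by construction, so raw ΔF/F carries
    a small positive offset that would otherwise eat into the threshold.
    The threshold is then ``k_sigma`` times the robust noise SD
    (:func:`robust_noise_sd`).  A candidate event is a run of at least
    ``min_duration_frames`` frames above threshold; its peak is the maximum
    before the trace first returns below half-threshold.  Events whose
    onsets fall within ``min_separation_s`` of the previous peak are merged.
    With ``shape_check`` on, events whose rise time is not shorter than
    their decay time are discarded — a calcium transient rises sharply and
    decays slowly, so symmetric or inverted bumps are treated as artifacts.

    Detection (thresholding) runs on the raw ΔF/F so the false-positive
    rate is governed by the stated noise model; event *geometry* (onset,
    rise, decay) is measured on a ``smooth_frames``-frame boxcar-smoothed
    copy, because single-frame noise at 30 Hz would otherwise dominate
    interval measurements a few frames long.  Amplitude is the raw peak
    minus the smoothed onset value.
    """
    if not np.all(np.isfinite(dff.dff)):
        raise ValueError("dff must be finite")
    fs = dff.frame_rate
    min_sep = int(round(min_separation_s * fs))
    win = max(3, int(round(baseline_window_s * fs)))
    if win % 2 == 0:
        win += 1
    local_base = running_percentile(dff.dff, 50.0, win)
    events: list[TransientEvent] = []
    for i in range(dff.n_neurons):
        x = dff.dff[i] - local_base[i]
        xs = uniform_filter1d(x, size=max(1, smooth_frames), mode="nearest")
        sd = robust_noise_sd(x)
        if sd == 0.0:
            sd = float(np.std(x)) or np.inf
        th = k_sigma * sd
        above = x > th
        if not above.any():
            continue
        # runs of consecutive suprathreshold frames
        padded = np.r_[False, above, False]
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        raw: list[tuple[int, int, int]] = []  # (run start, raw peak, end)
        for s, e in zip(starts, ends):
            if e - s < min_duration_frames:
                continue
            # extend forward until trace drops below half-threshold
            j = e
            while j < x.size and x[j] > th / 2.0:
                j += 1
            peak = s + int(np.argmax(x[s:j]))
            raw.append((s, peak, j))
        # merge events closer than min_separation
        merged: list[tuple[int, int, int]] = []
        for s, p, e in raw:
            if merged and s - merged[-1][1] < min_sep:
                ps, pp, pe = merged[-1]
                best = pp if x[pp] >= x[p] else p
                merged[-1] = (ps, best, max(pe, e))
            else:
                merged.append((s, p, e))
        for s, p, e in merged:
            # event geometry lives on the smoothed trace: peak location,
            # onset at the foot of the rise (last sample below 20% of the
            # smoothed peak — a level above the smoothed noise band, so
            # noise runs cannot drag the onset backwards; capped at 1 s),
            # and decay as the half-return toward the local baseline
            p_s = s + int(np.argmax(xs[s:e])) if e > s else p
            foot = onset_foot_frac * xs[p_s]
            o = min(s, p_s)
            while o > 0 and xs[o - 1] > foot and min(s, p_s) - o < fs:
                o -= 1
            # amplitude baseline: the pre-event level just before the
            # foot (median of a short window), so an event riding the
            # tail of its predecessor is measured from that tail
            lo, hi = max(o - 8, 0), max(o - 1, 1)
            base_val = float(np.median(xs[lo:hi])) if hi > lo else float(xs[0])
            amplitude = float(x[p] - base_val)
            if amplitude <= 0 or o > p:
                continue
            rise = (p_s - o) / fs
            half = 0.5 * xs[p_s]
            below = np.flatnonzero(xs[p_s:] <= half)
            decay = (float(below[0]) if below.size else float(x.size - 1 - p_s)) / fs
            ok = rise < decay
            if shape_check and not ok:
                continue
            events.append(
                TransientEvent(
                    neuron=i,
                    onset_frame=int(o),
                    peak_frame=int(p),
                    amplitude=amplitude,
                    rise_time=float(rise),
                    decay_time=float(decay),
                    onset_value=base_val,
                    shape_ok=ok,
                )
            )
    return events


def transient_stats(
    events: list[TransientEvent],
    n_neurons: int,
    duration: float,
) -> pd.DataFrame:
    """Per-neuron transient frequency (events/min) and mean amplitude (%ΔF/F).

    Neurons with no events get frequency 0, amplitude NaN (missing, never
    zero — a zero would bias group amplitude means), and ``silent=True``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    counts = np.zeros(n_neurons, dtype=int)
    amps: list[list[float]] = [[] for _ in range(n_neurons)]
    for ev in events:
        if not 0 <= ev.neuron < n_neurons:
            raise ValueError(f"event neuron {ev.neuron} out of range")
        counts[ev.neuron] += 1
        amps[ev.neuron].append(ev.amplitude)
    freq = 60.0 * counts / duration
    mean_amp = np.array([np.mean(a) if a else np.nan for a in amps])
    return pd.DataFrame(
        {
            "n_events": counts,
            "frequency_per_min": freq,
            "mean_amplitude_pct": mean_amp,
            "silent": counts == 0,
        },
        index=pd.RangeIndex(n_neurons, name="neuron"),
    )


def normalize_to_baseline(series: MetricSeries, baseline: str = "pre") -> MetricSeries:
    """Divide each timepoint by the pre-injury baseline value.

    The baseline timepoint maps to exactly 1; the result is a unitless
    ratio series suitable for longitudinal comparison across animals.
    """
    if baseline not in series.values:
        raise ValueError(f"baseline timepoint {baseline!r} missing")
    base = series.values[baseline]
    if base == 0 or not np.isfinite(base):
        raise ValueError("baseline value must be finite and nonzero")
    vals = {k: v / base for k, v in series.values.items()}
    vals[baseline] = 1.0
    return MetricSeries(values=vals, name=f"{series.name}_normalized", units="ratio")
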