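"""Ground-truth synthetic data for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* **Calcium traces** — each neuron's raw fluorescence is a baseline F0
  plus Poisson-timed transients convolved with a GCaMP6f-like
  difference-of-exponentials kernel (sharp rise, slower decay), plus
  white noise.  Pairwise coupling is planted with a single global shared
  Poisson source of rate ``r``: neuron *i* keeps each shared event with
  probability ``w_i`` (its shared-drive weight; shared events carry one
  common amplitude across neurons) and adds a private train of rate
  ``(1 - w_i) * r``, so every neuron fires at rate ``r`` regardless of
  coupling.  ``w = 0`` gives independent populations, ``w = 1``
  identical ones; the model-expected trace correlation of a pair is
  ``w_i * w_j`` times the signal-variance fraction
  (:meth:`CalciumSimConfig.expected_coupling`), and per-neuron weights
  plant a full gradient of pairwise connectivity.
* **Movies** — traces rendered onto non-overlapping disk ROIs on a
  background, with pixelwise noise.
* **PSC sweeps** — Poisson-timed biexponential currents (inward for
  EPSCs, outward for IPSCs) on a noisy baseline.
* **AP ramp sweeps** — a current-clamp ramp-response with parameterized
  spike templates whose waveform features are known analytically (or
  measured on the ideal high-resolution template with the same
  conventions as the extractor).
* **Up-down sessions** — staircase responses drawn from a logistic
  psychometric with known 50% threshold.

All randomness flows from one integer seed through named substreams
(:func:`split_rng`), so every generator is independently reproducible
and bit-identical on rerun.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt
from scipy.special import expit

from neurocalnet.behavior import UpDownSession
from neurocalnet.calcium import TraceMatrix
from neurocalnet.ephys import ApFeatures, EphysSweep, measure_spike
from neurocalnet.roi import FluorescenceMovie

__all__ = [
    "CalciumSimConfig",
    "RoiLayout",
    "GroundTruth",
    "split_rng",
    "calcium_kernel",
    "gen_calcium_traces",
    "gen_calcium_movie",
    "gen_psc_trace",
    "gen_ap_sweep",
    "gen_updown_session",
    "DEFAULT_FILAMENTS",
]

#: von Frey filament forces (grams) typically used for mice
DEFAULT_FILAMENTS = (0.02, 0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0)


def split_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent generator for a named substream of ``seed``.

    Counter-based splitting: the stream name is hashed (CRC-32, stable
    across runs and platforms) into the spawn key, so generators for
    different purposes never share state and adding a new stream never
    perturbs existing ones.
    """
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(key,)))


@dataclass
class CalciumSimConfig:
    """Forward-model parameters for a simulated imaging session.

    Defaults describe a sparsely active GCaMP6f population imaged at
    30 Hz: 2 transients/min/neuron, 25% ΔF/F mean transient amplitude
    against a 5% ΔF/F noise floor (peak SNR 5), kernel rise 50 ms and
    decay 500 ms.
    """

    n_neurons: int = 25
    duration: float = 300.0
    frame_rate: float = 30.0
    event_rate: float = 2.0  # events/min per neuron
    kernel_rise: float = 0.05  # s
    kernel_decay: float = 0.5  # s
    amplitude_mean: float = 0.25  # ΔF/F fraction at transient peak
    amplitude_cv: float = 0.0  # fractional spread of amplitudes
    shared_drive_weight: float | tuple = 0.0  # scalar or per-neuron, in [0, 1]
    noise_sd: float = 0.05  # ΔF/F fraction
    baseline_f: float = 100.0  # raw-fluorescence baseline (a.u.)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "frame_rate", "event_rate", "kernel_rise",
                     "kernel_decay", "amplitude_mean", "amplitude_cv",
                     "noise_sd", "baseline_f"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        w = self.weights()
        if not np.all(np.isfinite(w)):
            raise ValueError("shared_drive_weight must be finite")
        if np.any(w < 0.0) or np.any(w > 1.0):
            raise ValueError("shared_drive_weight must lie in [0, 1]")
        if np.ndim(self.shared_drive_weight) == 1 and w.size != self.n_neurons:
            raise ValueError("per-neuron weights must have length n_neurons")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        if self.event_rate < 0 or self.noise_sd < 0 or self.amplitude_mean < 0:
            raise ValueError("rates, noise and amplitudes must be non-negative")
        if not self.kernel_decay > self.kernel_rise > 0:
            raise ValueError("require kernel_decay > kernel_rise > 0")
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")

    def weights(self) -> np.ndarray:
        """Per-neuron shared-drive weights (scalar broadcast to all)."""
        w = np.asarray(self.shared_drive_weight, dtype=float)
        if w.ndim == 0:
            return np.full(self.n_neurons, float(w))
        return w

    def signal_variance_fraction(self) -> float:
        """Fraction of trace variance carried by transients (vs noise).

        From Campbell's theorem, the stationary variance of the transient
        component is ``rate * E[A^2] * ∫k(u)^2 du`` for the unit-peak
        kernel; the fraction of total variance it represents sets the
        ceiling of attainable pairwise correlation.
        """
        lam = self.event_rate / 60.0
        a2 = self.amplitude_mean ** 2 * (1.0 + self.amplitude_cv ** 2)
        r, d = self.kernel_rise, self.kernel_decay
        t_peak = r * d / (d - r) * np.log(d / r)
        peak = np.exp(-t_peak / d) - np.exp(-t_peak / r)
        i2 = (d / 2.0 + r / 2.0 - 2.0 * d * r / (d + r)) / peak ** 2
        s = lam * a2 * i2
        denom = s + self.noise_sd ** 2
        return float(s / denom) if denom > 0 else 0.0

    def expected_coupling(self) -> np.ndarray:
        """Model-expected pairwise trace correlation: ``w_i w_j`` times the
        signal-variance fraction, with unit diagonal."""
        w = self.weights()
        rho = self.signal_variance_fraction()
        m = np.outer(w, w) * rho
        np.fill_diagonal(m, 1.0)
        return m


@dataclass
class RoiLayout:
    """Disk-ROI arrangement for movie rendering: a regular grid of
    non-overlapping disks, 25 cells per field of view by default."""

    frame_shape: tuple[int, int] = (512, 512)
    n_rois: int = 25
    radius: int = 6
    background_level: float = 20.0  # a.u.
    pixel_noise_sd: float = 5.0  # a.u., i.i.d. per pixel per frame

    def centers(self) -> list[tuple[int, int]]:
        side = int(np.ceil(np.sqrt(self.n_rois)))
        H, W = self.frame_shape
        rs = np.round(np.linspace(H / (side + 1), H * side / (side + 1), side))
        cs = np.round(np.linspace(W / (side + 1), W * side / (side + 1), side))
        pts = [(int(r), int(c)) for r in rs for c in cs]
        return pts[: self.n_rois]


@dataclass
class GroundTruth:
    """Planted truth accompanying each simulated dataset."""

    spike_times: list[np.ndarray] | None = None
    event_amplitudes: list[np.ndarray] | None = None
    coupling_matrix: np.ndarray | None = None
    roi_masks: list[np.ndarray] | None = None
    psc_times: np.ndarray | None = None
    psc_amplitudes: np.ndarray | None = None
    true_threshold: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coupling_matrix is not None:
            m = np.asarray(self.coupling_matrix, dtype=float)
            if not np.allclose(m, m.T):
                raise ValueError("coupling_matrix must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("coupling_matrix must have unit diagonal")
            self.coupling_matrix = m


def calcium_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient kernel, normalized to unit peak."""
    t = np.asarray(t, dtype=float)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    tp = np.clip(t, 0.0, None)
    out = (np.exp(-tp / decay) - np.exp(-tp / rise)) / peak
    return np.where(t >= 0, out, 0.0)


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def gen_calcium_traces(config: CalciumSimConfig) -> tuple[TraceMatrix, GroundTruth]:
    """Simulate a population of raw fluorescence traces with planted events.

    Returns the trace matrix plus ground truth: per-neuron event times,
    peak amplitudes (ΔF/F fraction), and the model-expected coupling
    matrix (:meth:`CalciumSimConfig.expected_coupling`).
    """
    cfg = config
    rate_hz = cfg.event_rate / 60.0
    w = cfg.weights()
    rng_shared = split_rng(cfg.seed, "calcium/shared")
    rng_private = split_rng(cfg.seed, "calcium/private")
    rng_noise = split_rng(cfg.seed, "calcium/noise")

    # one global source at the full event rate; neuron i keeps each shared
    # event with probability w_i and tops up with a private train, so the
    # per-neuron rate is w_i*r + (1-w_i)*r = r independent of coupling
    shared_times = _poisson_times(rng_shared, rate_hz, cfg.duration)
    shared_amps = _draw_amplitudes(rng_shared, shared_times.size,
                                   cfg.amplitude_mean, cfg.amplitude_cv)

    n_frames = int(round(cfg.duration * cfg.frame_rate))
    frame_t = np.arange(n_frames) / cfg.frame_rate
    kernel_span = int(np.ceil(8.0 * cfg.kernel_decay * cfg.frame_rate))

    traces = np.empty((cfg.n_neurons, n_frames))
    spike_times: list[np.ndarray] = []
    amplitudes: list[np.ndarray] = []
    for i in range(cfg.n_neurons):
        if w[i] == 1.0:
            keep = np.ones(shared_times.size, dtype=bool)
        elif w[i] == 0.0:
            keep = np.zeros(shared_times.size, dtype=bool)
        else:
            keep = rng_private.uniform(size=shared_times.size) < w[i]
        private_times = _poisson_times(
            rng_private, (1.0 - w[i]) * rate_hz, cfg.duration
        )
        private_amps = _draw_amplitudes(rng_private, private_times.size,
                                        cfg.amplitude_mean, cfg.amplitude_cv)
        times = np.concatenate([shared_times[keep], private_times])
        amps = np.concatenate([shared_amps[keep], private_amps])
        order = np.argsort(times)
        times, amps = times[order], amps[order]
        dff = np.zeros(n_frames)
        for t0, a in zip(times, amps):
            start = int(np.ceil(t0 * cfg.frame_rate))
            stop = min(start + kernel_span, n_frames)
            if start >= n_frames:
                continue
            dff[start:stop] += a * calcium_kernel(
                frame_t[start:stop] - t0, cfg.kernel_rise, cfg.kernel_decay
            )
        noise = rng_noise.normal(0.0, cfg.noise_sd, size=n_frames) if cfg.noise_sd else 0.0
        traces[i] = cfg.baseline_f * (1.0 + dff + noise)
        spike_times.append(times)
        amplitudes.append(amps)

    coupling = cfg.expected_coupling()
    tm = TraceMatrix(values=traces, frame_rate=cfg.frame_rate)
    gt = GroundTruth(
        spike_times=spike_times,
        event_amplitudes=amplitudes,
        coupling_matrix=coupling,
        extras={"config": cfg},
    )
    return tm, gt


def _draw_amplitudes(
    rng: np.random.Generator, n: int, mean: float, cv: float
) -> np.ndarray:
    if mean == 0 or n == 0:
        return np.zeros(n)
    a = rng.normal(mean, cv * mean, size=n)
    return np.clip(a, 0.1 * mean, None)


def gen_calcium_movie(
    traces: TraceMatrix,
    layout: RoiLayout | None = None,
    seed: int = 0,
) -> tuple[FluorescenceMovie, GroundTruth]:
    """Render a trace matrix onto disk ROIs in a noisy movie.

    Every pixel of ROI *i* carries trace *i* plus i.i.d. pixel noise;
    background pixels carry ``background_level`` plus noise.  Raises if
    the requested disks overlap or leave the frame.
    """
    layout = layout or RoiLayout()
    H, W = layout.frame_shape
    centers = layout.centers()
    if len(centers) < layout.n_rois:
        raise ValueError("layout cannot place the requested number of ROIs")
    if traces.n_neurons != layout.n_rois:
        raise ValueError("trace count must match layout n_rois")
    rr, cc = np.mgrid[0:H, 0:W]
    masks: list[np.ndarray] = []
    occupancy = np.zeros((H, W), dtype=np.int8)
    for (r0, c0) in centers:
        if not (layout.radius <= r0 < H - layout.radius
                and layout.radius <= c0 < W - layout.radius):
            raise ValueError("ROI disk leaves the frame")
        m = (rr - r0) ** 2 + (cc - c0) ** 2 <= layout.radius ** 2
        occupancy += m
        masks.append(m)
    if occupancy.max() > 1:
        raise ValueError("ROI disks overlap")

    rng = split_rng(seed, "movie/pixel-noise")
    T = traces.n_frames
    movie = np.full((T, H, W), float(layout.background_level))
    for m, trace in zip(masks, traces.values):
        movie[:, m] = trace[:, None]
    if layout.pixel_noise_sd > 0:
        movie += rng.normal(0.0, layout.pixel_noise_sd, size=movie.shape)
    return (
        FluorescenceMovie(data=movie, frame_rate=traces.frame_rate),
        GroundTruth(roi_masks=masks, extras={"layout": layout}),
    )


def gen_psc_trace(
    rate: float,
    amp_mean: float,
    polarity: str = "EPSC",
    duration: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    sampling_rate: float = 10_000.0,
    tau_rise: float = 0.001,
    tau_decay: float = 0.008,
    amp_cv: float = 0.2,
    baseline_pa: float = 0.0,
    filter_khz: float | None = 1.0,
) -> tuple[EphysSweep, GroundTruth]:
    """Simulate a voltage-clamp sweep with Poisson-timed biexponential PSCs.

    EPSCs deflect negative (inward current at −70 mV holding), IPSCs
    positive (outward at 0 mV).  Truth amplitudes are stored as positive
    magnitudes.  The assembled sweep is low-pass filtered at
    ``filter_khz`` (zero-phase Butterworth), mirroring the acquisition
    chain (hardware-filtered at 1 kHz, digitized at 10 kHz) — without
    it the noise would be unrealistically white at the sample rate.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if amp_mean < 0:
        raise ValueError("amp_mean must be non-negative")
    if polarity not in ("EPSC", "IPSC"):
        raise ValueError("polarity must be EPSC or IPSC")
    rng_ev = split_rng(seed, "psc/events")
    rng_noise = split_rng(seed, "psc/noise")
    times = _poisson_times(rng_ev, rate, duration)
    amps = _draw_amplitudes(rng_ev, times.size, amp_mean, amp_cv)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    sign = -1.0 if polarity == "EPSC" else 1.0
    signal = np.full(n, baseline_pa)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    span = int(np.ceil(8.0 * tau_decay * sampling_rate))
    for t0, a in zip(times, amps):
        start = int(np.ceil(t0 * sampling_rate))
        stop = min(start + span, n)
        if start >= n:
            continue
        tt = t[start:stop] - t0
        signal[start:stop] += sign * a * (
            np.exp(-tt / tau_decay) - np.exp(-tt / tau_rise)
        ) / peak
    if noise_sd > 0:
        signal = signal + rng_noise.normal(0.0, noise_sd, size=n)
    if filter_khz is not None and filter_khz * 1000.0 < sampling_rate / 2.0:
        sos = butter(4, filter_khz * 1000.0, btype="low", fs=sampling_rate,
                     output="sos")
        signal = sosfiltfilt(sos, signal)
    sweep = EphysSweep(
        signal=signal,
        sampling_rate=sampling_rate,
        mode="voltage_clamp",
        holding_mv=-70.0 if polarity == "EPSC" else 0.0,
    )
    return sweep, GroundTruth(psc_times=times, psc_amplitudes=amps)


@dataclass
class RampProtocol:
    """Current-clamp excitability protocol: pre-stimulus baseline, a
    hyperpolarizing step, then a depolarizing ramp (0.14 pA/ms)."""

    pre_s: float = 0.5
    hyper_pa: float = -60.0
    hyper_s: float = 1.0
    ramp_slope_pa_per_ms: float = 0.14
    ramp_s: float = 1.5
    rmp_mv: float = -65.0
    input_resistance_mohm: float = 100.0
    membrane_tau_ms: float = 20.0
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.ramp_slope_pa_per_ms <= 0:
            raise ValueError("ramp slope must be positive")


@dataclass
class SpikeTemplate:
    """Parameterized spike waveform with closed-form feature truth.

    ``gaussian``: height h, width parameter sigma_ms — FWHM is
    2*sqrt(2 ln 2)*sigma.  ``rect``: height h, width w — area is h*w.
    """

    kind: str = "gaussian"
    height_mv: float = 80.0
    sigma_ms: float = 0.5
    width_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "rect"):
            raise ValueError("kind must be 'gaussian' or 'rect'")
        if self.height_mv <= 0:
            raise ValueError("height must be positive")

    def waveform(self, t_ms: np.ndarray, center_ms: float) -> np.ndarray:
        if self.kind == "gaussian":
            return self.height_mv * np.exp(
                -((t_ms - center_ms) ** 2) / (2.0 * self.sigma_ms ** 2)
            )
        half = self.width_ms / 2.0
        return np.where(
            np.abs(t_ms - center_ms) <= half, self.height_mv, 0.0
        )

    def support_ms(self) -> float:
        return 8.0 * self.sigma_ms if self.kind == "gaussian" else self.width_ms

    def truth_features(self, dvdt_threshold: float = 20.0) -> dict:
        """Waveform-feature truth measured on the ideal template.

        The template is evaluated at 1 MHz on a flat baseline and passed
        through the same dV/dt-threshold measurement the extractor uses
        (:func:`neurocalnet.ephys.measure_spike`), so the truth shares
        the extractor's conventions without sharing its sampled data.
        For a rectangular template the discontinuity makes closed forms
        exact: amplitude h, area h*w.
        """
        if self.kind == "rect":
            return {
                "amplitude": self.height_mv,
                "half_width": self.width_ms,
                "rise_time": 0.0,
                "area": self.height_mv * self.width_ms,
            }
        fs = 1_000_000.0
        span = self.support_ms() * 4.0
        t_ms = np.arange(int(span * fs / 1000.0)) / fs * 1000.0
        v = self.waveform(t_ms, span / 2.0)
        out = measure_spike(v, fs, dvdt_threshold=dvdt_threshold)
        if out is None:
            raise ValueError("template never crosses the dV/dt threshold")
        feats, _ = out
        return {k: feats[k] for k in ("amplitude", "half_width", "rise_time", "area")}


def gen_ap_sweep(
    protocol: RampProtocol | None = None,
    template: SpikeTemplate | None = None,
    spike_times_s: list[float] | None = None,
    n_spikes: int = 3,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> tuple[EphysSweep, ApFeatures]:
    """Simulate a current-clamp ramp sweep with inserted spike templates.

    The subthreshold voltage is a passive response (RMP + R*I).  Spikes
    are template waveforms placed in the ramp segment (evenly spaced by
    default).  Returns the sweep and the ground-truth features of the
    inserted template (with ``spike_count`` = number inserted and
    ``rmp`` = the protocol RMP).
    """
    protocol = protocol or RampProtocol()
    template = template or SpikeTemplate()
    p = protocol
    fs = p.sampling_rate
    total_s = p.pre_s + p.hyper_s + p.ramp_s
    if template.support_ms() / 1000.0 > total_s:
        raise ValueError("template wider than sweep")
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    current = np.zeros(n)
    hyper = (t >= p.pre_s) & (t < p.pre_s + p.hyper_s)
    ramp = t >= p.pre_s + p.hyper_s
    current[hyper] = p.hyper_pa
    current[ramp] = p.ramp_slope_pa_per_ms * (t[ramp] - (p.pre_s + p.hyper_s)) * 1000.0
    # passive subthreshold response: RMP + R*I low-pass filtered by the
    # membrane time constant (so current steps do not produce instantaneous
    # voltage jumps, which would masquerade as dV/dt spike onsets)
    alpha = (1.0 / fs) / (p.membrane_tau_ms / 1000.0)
    v_inf = current * p.input_resistance_mohm * 1e-3  # pA*MΩ = µV -> mV
    v_sub = lfilter([alpha], [1.0, -(1.0 - alpha)], v_inf)
    v = p.rmp_mv + v_sub

    if spike_times_s is None:
        if n_spikes > 0:
            ramp_start = p.pre_s + p.hyper_s
            spike_times_s = list(
                ramp_start + (np.arange(1, n_spikes + 1) / (n_spikes + 1)) * p.ramp_s
            )
        else:
            spike_times_s = []
    t_ms = t * 1000.0
    for ts in spike_times_s:
        if not 0 <= ts < total_s:
            raise ValueError("spike time outside sweep")
        v += template.waveform(t_ms, ts * 1000.0)
    if noise_sd_mv > 0:
        v = v + split_rng(seed, "ap/noise").normal(0.0, noise_sd_mv, size=n)

    truth = template.truth_features()
    features = ApFeatures(
        rmp=p.rmp_mv,
        amplitude=truth["amplitude"] if spike_times_s else 0.0,
        half_width=truth["half_width"] if spike_times_s else 0.0,
        rise_time=truth["rise_time"] if spike_times_s else 0.0,
        area=truth["area"] if spike_times_s else 0.0,
        spike_count=len(spike_times_s),
    )
    sweep = EphysSweep(signal=v, sampling_rate=fs, mode="current_clamp")
    return sweep, features


def gen_updown_session(
    true_threshold: float,
    filament_set=DEFAULT_FILAMENTS,
    n_trials: int = 15,
    seed: int = 0,
    slope_log10: float = 0.05,
    n_after_first_reversal: int = 4,
) -> UpDownSession:
    """Simulate a von Frey up-down staircase.

    Responses are Bernoulli draws from a logistic psychometric on the
    log10-force axis centered at ``true_threshold`` with slope parameter
    ``slope_log10`` (small = steep).  Testing starts at the middle
    filament; a positive response steps down, a negative steps up; the
    session ends ``n_after_first_reversal`` responses after the first
    reversal (standard practice), at ``n_trials``, or at a range
    boundary that cannot be stepped past.
    """
    fs = sorted(float(f) for f in filament_set)
    if len(fs) < 2:
        raise ValueError("need at least 2 filaments")
    if true_threshold <= 0:
        raise ValueError("true_threshold must be positive")
    if not (fs[0] <= true_threshold <= fs[-1]):
        warnings.warn(
            "true_threshold outside the filament span; the staircase will "
            "pin at a range boundary",
            stacklevel=2,
        )
    rng = split_rng(seed, "updown")
    log_th = np.log10(true_threshold)
    idx = len(fs) // 2
    forces: list[float] = []
    responses: list[bool] = []
    first_reversal_at: int | None = None
    while len(forces) < n_trials:
        f = fs[idx]
        p = expit((np.log10(f) - log_th) / slope_log10)
        resp = bool(rng.uniform() < p)
        forces.append(f)
        responses.append(resp)
        k = len(responses)
        if first_reversal_at is None and k >= 2 and responses[-1] != responses[-2]:
            first_reversal_at = k
        if first_reversal_at is not None and k - first_reversal_at >= n_after_first_reversal:
            break
        if resp:
            if idx == 0:
                break  # positive at the weakest filament: pinned at floor
            idx -= 1
        else:
            if idx == len(fs) - 1:
                break  # negative at the strongest filament: pinned at ceiling
            idx += 1
    return UpDownSession(forces=forces, responses=responses, filament_set=fs)
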