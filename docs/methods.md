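# Methods

This note documents the models, estimators, and numerical conventions
behind `neurocalnet`, and what the synthetic validation does and does
not establish about real data.

## Scope

The package reimplements, as reusable and tested code, the quantitative
chain of a longitudinal spinal-cord-hemisection neuropathic-pain study:

1. two-photon GCaMP6f population imaging → somatic ROIs → ΔF/F →
   calcium-transient detection → per-neuron frequency/amplitude and
   population network metrics (functional connectivity, network
   synchronization), tracked across timepoints (pre, d1 … d28) and
   normalized to the pre-injury baseline;
2. slice patch-clamp sweeps → sEPSC/sIPSC events, action-potential
   waveform features from a depolarizing-ramp protocol, cell-attached
   firing rates;
3. behavioral estimators: Dixon up-down 50% mechanical withdrawal
   threshold and tail-immersion latency summaries;
4. the normality-driven statistical dispatch used to compare groups.

Motion correction, gait analysis, immunofluorescence quantification, and
all biological interpretation are out of scope.

## Synthetic data as ground truth

No public recordings accompany the study, so every estimator is
validated against a forward model with known truth
(`neurocalnet.synthetic`). All randomness derives from one integer seed
through named CRC-keyed substreams, so any piece can be regenerated
independently and every run is bit-identical for a given seed.

### Calcium forward model

A neuron's raw fluorescence is

    F_i(t) = F0 · (1 + Σ_k a_k · κ(t − t_k) + ε_i(t)),

with κ a difference-of-exponentials kernel normalized to unit peak
(rise 0.05 s, decay 0.5 s — GCaMP6f-like; the indicator's constants are
conventions, not measured values) and ε white Gaussian noise.
Defaults: 25 neurons, 300 s at 30 Hz, 2 transients/min/neuron,
amplitude 0.25 ΔF/F against noise SD 0.05 ΔF/F — i.e. transients peak
at 5× the noise floor, the operating point at which the detector is
specified to reach ≥0.9 recall and precision. Amplitude spread
(`amplitude_cv`) defaults to 0 so that the planted peak signal-to-noise
is exact; it is a knob for robustness studies.

Coupling is planted with a single global Poisson source at the full
event rate: neuron *i* keeps each shared event with probability `w_i`
(its shared-drive weight; a shared event carries one common amplitude
across all neurons) and adds an independent private train at rate
`(1 − w_i)·r`, so the per-neuron rate is `r` regardless of coupling.
The model-expected pairwise correlation is `w_i·w_j·ρ`, where ρ — the
fraction of trace variance carried by transients — follows from
Campbell's theorem: `ρ = r·E[A²]·∫κ²/(r·E[A²]·∫κ² + σ²)`. `w = 1`
with zero noise yields exactly unit pairwise correlation; heterogeneous
per-neuron weights plant a full gradient of connectivity for
rank-recovery tests (a single scalar weight makes every pair equally
coupled, so rank recovery would be undefined).

Movies render traces onto non-overlapping disks (25 cells per field by
default, mirroring the manual outlining practice) on a uniform
background, with i.i.d. pixel noise (SD 5 a.u. against an ~100 a.u.
soma). No optics, motion, or neuropil model — consequently, ROI
recovery scores here bound what segmentation achieves on ideal data,
not on real movies with contamination and drift.

### Electrophysiology forward models

PSC sweeps: Poisson-timed biexponential currents (rise 1 ms, decay
8 ms; EPSCs inward/negative, IPSCs outward/positive) on a baseline with
white noise, then low-pass filtered at 1 kHz (zero-phase Butterworth) —
matching an acquisition chain filtered at 1 kHz and digitized at
10 kHz. The filter matters: unfiltered 10 kHz white noise produces
single-sample threshold crossings no realistic detector should face.

AP ramp sweeps: the subthreshold voltage is a passive response
(RMP + R·I low-passed by a 20 ms membrane time constant, so current
steps do not produce instantaneous voltage jumps that would read as
dV/dt onsets) with parameterized spike templates added in the ramp
segment. Gaussian templates have closed-form FWHM (2√(2 ln 2)·σ);
rectangular templates have exact amplitude and area (h, h·w). Template
truth for measured-convention features is computed on the ideal
waveform at 1 MHz using the *same* measurement routine as the
extractor, so generator truth and extractor share definitions but not
sampled data.

### Behavioral sessions

Up-down staircases draw responses from a logistic psychometric on the
log10-force axis (slope 0.05 log10 units by default — a steep,
well-behaved animal) over the standard mouse von Frey set
{0.02 … 2.0 g}, start at the middle filament, and stop four responses
after the first reversal (standard practice), at a trial cap, or
pinned at a range boundary.

## Estimators and conventions

### ΔF/F and baseline

`F0` is a running 20th percentile in a centered 30 s window (robust to
sparse transients); ΔF/F is reported in percent. The percentile is
evaluated on a strided grid and interpolated (the baseline varies on
the window timescale, so the approximation is inconsequential), with
the grid phase dithered per neuron: a common grid imprints one shared
periodic variance profile on all traces, which any alignment-sensitive
cross-neuron statistic would pick up.

### Transient detection

Detection thresholds the ΔF/F (after subtracting a running-median local
baseline — the percentile F0 sits below the noise median by
construction, which would otherwise shift the operating point) at
`k_sigma = 3` times a robust noise SD (1.4826·MAD of the first
difference, rescaled by 1/√2). A candidate is ≥2 consecutive
suprathreshold frames; the event extends to the half-threshold return;
events within 1 s merge.

Event *geometry* is measured on a 7-frame boxcar-smoothed copy because
single-frame noise at 30 Hz dominates intervals a few frames long:
onset is the foot of the rise (last smoothed sample below 30% of the
smoothed peak, capped one second back), rise time runs foot→smoothed
peak, decay time runs smoothed peak→half-return toward the local
baseline. Amplitude is the raw peak minus the pre-onset level (median
of a short window before the foot), so an event riding its
predecessor's tail is measured from that tail; with zero noise the
planted amplitude is recovered to <1% (grid discretization only). The
reported amplitude convention is peak-minus-onset; peak ΔF/F is
recoverable as `amplitude + onset_value`.

The shape check (discard events whose rise is not shorter than their
decay — a calcium transient is asymmetric) is a waveform-purity filter.
For *counting* (frequency estimation) it should be off: it removes a
known ~5% of true events at the 5σ operating point. Even in counting
mode a threshold detector carries sub-percent systematics (dead-time
merging versus occasional false positives roughly cancel), so frequency
recovery is validated as the 20-seed mean landing within two standard
errors of the planted rate, not as exact unbiasedness — a paired test
across seeds resolves arbitrarily small systematic components and no
threshold detector passes it.

### ROI extraction

The correlation image is each pixel's mean temporal Pearson correlation
with its 8-neighborhood (z-scored traces, so per-pixel affine gain and
offset cancel; constant pixels contribute 0). Region growing from a
seed adds 8-connected neighbors whose trace correlates with the running
ROI mean above 0.3 (row-major visit order, ≤400 px). Masks from
different seeds merge above Jaccard 0.5; residual overlaps go to the
seed with the higher correlation-image value, ties broken row-major —
making the output independent of seed-list order. Background
subtraction uses a dilation annulus (2 px gap, 3 px wide) excluding all
ROIs, falling back to the global non-ROI median with a warning.

### Network metrics

Functional connectivity is the zero-lag Pearson matrix of ΔF/F traces;
silent (constant) neurons contribute zeros, never NaNs, and are listed
in metadata. Significance comes from a circular-shift surrogate null
(1000 surrogates, α = 0.05): shifting each trace by an independent
uniform offset preserves every single-neuron property including
indicator autocorrelation, while destroying cross-neuron timing. Both
observed and null correlations exclude 15 s (one baseline half-window)
at each end of the recording: the running baseline leaves an edge
transient common to every neuron, and aligning those transients
inflates the observed correlation relative to any time-shifted null
(measured false-positive rate 0.075 without the exclusion, 0.050 with
it). The scalar connectivity summary is the mean significant
off-diagonal correlation (0 with a flag when no pair is significant);
the significant-pair density is available from the mask for the
alternative convention.

Network synchronization has two readouts. The pairwise matrix is the
Pearson correlation of transient-onset trains binarized at 0.5 s. The
synchrony index compares per-bin co-active neuron counts to a null
built by circularly jittering each neuron's train, and reports the
fraction of *active* bins (≥1 onset) whose count strictly exceeds the
95th percentile of surrogate active-bin counts. Conditioning on active
bins is deliberate: with sparse trains the unconditional fraction is
capped by event density itself and stops tracking coupling (measured
non-monotone in the shared-drive weight), while the active-bin version
is calibrated near/below 0.05 for independent populations, reaches ~1
for fully co-active ones, and rises monotonically with coupling.
Because co-activity counts are integers, the strictly-exceeds rule is
conservatively sized at or below the nominal 5% under the null.

### Patch-clamp features

PSC detection is threshold-based (4× robust SD in the polarity's
direction after median subtraction) with hysteresis — an event holds
until the signal returns to half the noise SD, so a slow decay tail
cannot retrigger — and 20 ms peak merging. Template matching was
deliberately avoided: a threshold is transparent and directly
calibratable on the generator. AP analysis: RMP is the pre-stimulus
median; spikes are upward dV/dt crossings of 20 mV/ms; per spike,
amplitude is peak minus the threshold-crossing voltage (RMP is reported
separately so the from-RMP convention stays recoverable), rise time is
the interpolated 10–90% interval, half-width the interpolated full
width at half-amplitude, and area the integral above the
threshold-crossing voltage, the region capped at 10 ms (on a ramp the
baseline climbs, so a waveform ending marginally above its onset
voltage would otherwise never "return"). Cell-attached firing uses
two-sided threshold detection (spike polarity depends on seal
geometry) with a 2 ms refractory merge.

### Behavioral estimators

The up-down 50% threshold uses Dixon's construction
`10^(Xf + k·δ)` on the log10-force axis, with δ the mean log-spacing of
the filament set and k the adjustment for the realized response
pattern. Instead of transcribing the printed k-table, k is recomputed
exactly as the maximum-likelihood location of a cumulative-normal
psychometric with SD fixed at one step (the assumption under which the
table was originally tabulated); this reproduces the classical values
(±0.5 for the two-trial patterns) for arbitrary sequences and filament
sets and makes the estimator exactly scale-equivariant. Sessions that
never (or always) elicit withdrawal return the maximum (minimum)
filament force. An independent logistic-psychometric MLE
(`logistic_mle_threshold`) ships as the validation oracle; the two
agree in rank order at ρ ≥ 0.95 on simulated sessions and the Dixon
estimate recovers a 0.6 g threshold within a few percent in the mean.
Estimator bias falls as the psychometric steepens when the true
threshold lies between filaments; on-lattice thresholds interact with
staircase quantization and mask that trend.

Tail-immersion summaries are arithmetic means of the (typically three)
latencies; any trial at the cutoff (15 s) marks the summary censored —
the mean is then a lower bound.

### Statistical dispatch

Each sample is checked for normality (Lilliefors-corrected
Kolmogorov–Smirnov by default, since the plain KS test with estimated
moments is anticonservative; the uncorrected variant is selectable, and
samples of n < 4 fall back to it because the Lilliefors tables need
n ≥ 4). Both normal → t-test (paired/unpaired); otherwise Wilcoxon
signed-rank / Mann–Whitney U. Two-sided, α = 0.05, no multiplicity
correction by default (matching per-comparison reporting), with
Benjamini–Hochberg available on the longitudinal report. Degenerate
comparisons (identical paired samples; two equal constants) return
statistic 0, p = 1 by convention. Empirical type-I error over 2000 null
replicates is 0.050.

Longitudinal reports normalize each group to its own pre-injury mean
(pre maps to exactly 1) and flag, rather than drop, missing cells.

## Problem sizes

Validation runs use the study-scale defaults: 25 neurons × 300 s
sessions; 20 seeds wherever a mean over realizations is asserted; 1000
circular-shift surrogates for significance; 1000 simulated staircases
for the behavioral estimator; 2000 null replicates for the dispatcher.
The ROI recovery movie is 25 cells on a 128×128 field over 120 s — the
segmentation algorithm is field-size agnostic, and a quarter-scale
field exercises it identically to 512×512.

## Known limitations

* The generator omits motion, neuropil contamination, photobleaching,
  and bursting; detector and segmentation scores are upper bounds for
  real recordings.
* Connectivity and synchronization formulas follow the standard
  constructions consistent with the study's figure conventions (pairwise
  correlation matrices, surrogate-calibrated synchrony); the original
  MATLAB implementation is not public, so exact numerical equivalence
  with it cannot be claimed.
* The synchrony index's active-bin conditioning makes its absolute value
  depend on bin width and event rate; compare within, not across,
  binning conventions.
* PSC amplitude is the peak deviation from the median baseline; no
  multi-event deconvolution is attempted, so amplitudes of events on
  tails of predecessors are biased by the residual tail.
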