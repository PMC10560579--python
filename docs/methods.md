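# Methods

This note documents the models and procedures implemented in `netbursts`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducibility.

## Signal model and preprocessing

Recordings are multichannel continuous voltages in μV with a shared
sampling rate; times are seconds, 0-based, and event intervals are
half-open `[onset, offset)`. Filtering uses third-order Butterworth
band-passes (1–100 Hz for LFP work, 4–100 Hz for burst detection,
400–4,000 Hz for MUA, 4–80 Hz for spike-field coherence), always applied
forward–backward (`sosfiltfilt`). Zero-phase filtering was chosen because
the lag analysis would otherwise be biased by the filter's group delay;
the cost is a doubled effective order, which is acceptable because all
band edges sit far from the frequencies analyzed.

Channel selection replaces by-eye choice with a deterministic rule: among
a region's candidate LFP channels, pick the one whose 50–100 Hz residual
has the smallest median absolute deviation (least high-frequency noise).
An explicit override is honored. This is a stand-in for a judgment call
that has no quantitative published definition.

## Burst detection

RMS is computed on a fixed grid of non-overlapping 200 ms windows aligned
to the recording start. A fixed grid (rather than a sliding one) keeps
event boundaries well-defined multiples of 0.2 s; the cost is up to one
window of onset quantization, which the recovery tests account for.

The detection threshold is μ + 3σ of a Gaussian least-squares fitted to
the histogram of window RMS values (Freedman–Diaconis bin width, at least
50 bins — the binning is otherwise unconstrained and is recorded in the
fit result). The fitted mean is capped at 50 μV: when bursting occupies a
large fraction of the recording, an unconstrained fit drifts toward the
burst mode and only burst peaks would be detected. `capped` records
whether the unconstrained fit exceeded the cap. If the fit fails to
converge the threshold falls back to median + 3·(MAD/0.6745) with a flag.

Consecutive supra-threshold windows merge into one event; a single
sub-threshold window breaks the run (no gap bridging). Quality filters
then reject events with duration < 0.2 s or > 20 s, fewer than 5
oscillation peaks above the event's mean RMS, or mean RMS > 1,000 μV
(motion artifacts), each with a labeled reason.

**Peak counting.** "Oscillation peaks above the mean RMS" is implemented
as positive local maxima whose height exceeds the event's mean RMS *and*
whose prominence exceeds half of it — the same half-RMS prominence rule
used for troughs in the ITI feature. A bare height criterion on |signal|
counts every noise ripple riding on an excursion (a 0.2 s noise crossing
typically shows 8–11 such sub-peaks) and lets through short false
positives that the filter exists to remove; the prominence requirement
restores the filter's intent of demanding genuine oscillatory cycles. The
|signal|-height-only variant remains available (`peak_mode="abs"`).

An independent detector (analytic-signal amplitude envelope thresholded
at a per-recording percentile, default 95) and a time-overlap metric
(percent of one event set's covered time also covered by the other,
optionally symmetrized) support cross-method validation. The envelope
method is parameterized per recording and is a cross-check, not the
primary detector.

## Spike detection

The spike threshold sits 5 SDs below baseline on the MUA band. "Baseline
SD" is estimated robustly as median(|x|)/0.6745 by default, so the spikes
themselves cannot inflate the threshold; plain SD is available by switch.
Each maximal run of sub-threshold samples yields one spike at its
minimum (no extra refractory period), with a 1 ms waveform centered there
(zero-padded at edges). Candidates whose waveform never rises above 0 μV
are rejected — real extracellular spikes are biphasic, so an all-negative
excursion is treated as artifact.

## Features and classification

Nine features per retained burst, computed from the 4–100 Hz signal
except the two band-power features: duration; negative peak (minimum
deflection); maximum 200 ms-window RMS; flatness = min/max of those
window RMS values (∈ (0,1]); maximum absolute first difference after
downsampling to 500 S/s (at native rates consecutive samples differ too
little for slope to discriminate); mean inter-trough interval, counting
troughs whose prominence exceeds half the event RMS; relative 4–16 Hz and
16–40 Hz power as fractions of the baseline-normalized spectrum's 1–50 Hz
integral; and spike rate over the event. An event with fewer than two
qualifying troughs gets ITI set to its duration plus a flag — keeping the
feature matrix rectangular was preferred to dropping events.

Features are z-scored (the normalization method is otherwise
unconstrained; min-max is not currently exposed because z-scoring is what
the permutation test also uses), embedded with PCA, and the first three
component scores clustered. PCA signs are fixed by making each
component's largest-magnitude loading positive, so reruns are
bit-identical.

Fuzzy c-means uses fuzzifier m = 2 (the conventional default),
convergence when the maximum membership change falls below 1e-6 or after
300 iterations, and 10 seeded restarts keeping the best objective —
c-means is initialization-sensitive and restarts make labels stable. The
FPC is the mean squared membership, ∈ [1/k, 1]. Cluster number is chosen
by maximizing FPC over k ≥ 2 (k = 1 trivially gives FPC 1); a
monotonically decreasing curve triggers a single-cluster warning.

With k = 2, the cluster with the higher membership-weighted mean relative
beta–low-gamma power is labeled NGB — the nested 16–40 Hz component is
the class's defining signature; mean duration breaks exact ties, and a
double tie raises an error requesting manual mapping. Events whose
maximum membership does not exceed 0.6 are UC; the comparison is strict,
so exactly 0.6 is unclassified.

## Spectra

Multitaper PSDs use 1 s windows advanced by 0.1 s, DPSS tapers with
time-half-bandwidth NW = 3 and K = 5 tapers, eigenspectra averaged with
unit weights (Thomson adaptive weighting is available but not default —
the windowing parameters were fixed first and unit weighting is the
simpler estimator). FFT length is the next power of two per window;
shorter segments fall back to a single whole-segment window with a
warning, and segments under 0.2 s are refused. One-sided scaling is
checked against Parseval in the tests, and the estimator is cross-checked
against an independent multitaper implementation.

The baseline PSD is the window-count-weighted mean over all non-bursting
gaps longer than 1 s; if none exists the caller must supply a baseline.
Normalization is the pointwise ratio P/P₀ with baseline bins below
1e-12 μV²/Hz floored (and counted) before division. Band fractions
integrate the normalized spectrum with trapezoids whose end values are
interpolated at the exact band edges, so a flat spectrum yields
fractions exactly proportional to bandwidth.

## Interactions

Two bursts co-occur when their onsets differ by strictly less than
0.5 s; matching is greedy 1-to-1 by smallest onset difference (earlier
event wins ties). Incidence per type combination is normalized by the
total number of events of the classes involved.

Pair coherence is Welch magnitude-squared coherence on the intersection
of the two event spans (Hann, 0.5 s, zero overlap, linear detrend per
segment); an intersection shorter than one segment falls back to a single
0.5 s window at the later onset, flagged. Mean coherence is averaged over
4–40 Hz — the union of the two analysis bands; the averaging range is
otherwise unconstrained. Pairs with mean coherence above 0.8 are rejected
as probable movement artifacts.

The shuffle null re-pairs partners with a random derangement (no event
keeps its true partner) 1,000 times, computing the mean coherence across
shuffled pairs each time; the significance threshold is the 95th
percentile of those means. Internally the package precomputes the matrix
of mean coherences between every event of one region and every event of
the other; when all segments share a length the Welch pieces are computed
once per event and combined — algebraically identical to per-pair calls
(asserted to 1e-12 in tests) but ~100× faster, which is what makes
500-experiment calibration runs cheap. With fewer than 3 pairs no
derangement exists and partners are resampled with replacement, warned.

Imaginary coherence is |Im(S_ab/√(S_aa·S_bb))| under the same windowing;
it vanishes for zero-lag (volume-conducted) coupling. Spike-field
coherence bins spikes at 2 ms, downsamples the 4–80 Hz LFP to the same
rate, and uses the magnitude of the real part of the normalized
cross-spectrum, so locking at any phase — including trough locking, which
makes the raw real part −1 — registers positively; the null shuffles
spike times uniformly over the span and thresholds per frequency bin at
the 95th percentile. Fewer than 10 spikes yields a flagged result with no
significance call.

### Lag estimation

LFP lags: both signals are band-passed to the analysis band (4–16 Hz for
SB, 16–40 Hz for NGB), decimated to ~1 kS/s (the bands top out at 40 Hz,
and at acquisition rates an AR model with a practical order cannot span a
meaningful fraction of a carrier period), pre-whitened, and the peak of
their normalized cross-correlation taken within ±50 ms. Lags under 20 ms
are flagged putative monosynaptic.

**Pre-whitening.** The default fits one AR(p) model (p by AIC over 1–10)
to the first series and filters *both* series with it — the classical
pre-whitening prescription. Fitting separate models per series is
supported (`prewhiten="independent"`) but not default: two different
whitening filters impose different phase responses, and on narrowband
signals this shifted recovered lags by up to a carrier period in
development tests (median absolute error 10–40 ms at 4–16 Hz versus
≤ 2 ms with the shared filter). With a shared filter the whitening phase
cancels exactly in the cross-correlation. A failed fit falls back to
first differencing with a flag.

**Sign convention.** One rule covers all region pairs: in canonical order
(cortex, striatum), (thalamus, striatum), (cortex, thalamus), a positive
lag means the second-listed region leads. Passing a pair in the opposite
order flips it internally; results always report the canonical pair and a
human-readable convention string, and a dedicated test constructs a known
leader for each pair and asserts the sign.

Spike-train lags: both trains are binned at 2 ms, convolved with a
unit-area Gaussian kernel (SD 2 ms), and the normalized cross-correlation
peak taken within ±10 ms; pairs with fewer than 5 spikes per train in the
co-occurring span are skipped with a flag. The population-level test is a
one-sample t-test of per-pair peak lags against zero.

## Permutation statistics

The multivariate test statistic is F = SS_A/SS_W with
SS_A = Σᵢ nᵢ‖Ȳ−Ȳᵢ‖²/(K−1) and SS_W = ΣᵢΣⱼ‖Ȳᵢ−Y_ij‖²/(N−K), Euclidean
distances, K = 2. For 1-D data this is exactly the classical one-way
ANOVA F (asserted to 1e-10), and on Euclidean distance matrices it equals
the PERMANOVA pseudo-F (cross-checked against an independent
implementation). The null shuffles group labels over the pooled rows with
group sizes fixed; p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), so
p ≥ 1/(n_perm+1) — the +1 correction keeps the p-value valid under random
permutation sampling. Because shuffling only redistributes rows, SS_A for
K = 2 depends only on the permuted first-group row sums and
SS_W = SS_total − SS_A with SS_total permutation-invariant; the
permutation distribution is therefore computed from one matrix product
per shuffle batch rather than a full re-evaluation.

Features are z-scored on the pooled data before the test by default: the
statistic is scale-sensitive and the nine burst features carry mixed
units. With standardization the test is invariant to common affine
rescalings of the features; without it it is not (both behaviors are
tested). Bonferroni correction (min(1, m·p)) is applied where several
pairwise comparisons are reported; the significance level is 0.05
throughout.

## Synthetic data: what it does and does not emulate

The generator's defaults define the conditions under which the recovery
guarantees are stated: 600 s at 10 kS/s (30 kS/s available; 10 kS/s keeps
the MUA band below Nyquist while staying desk-scale), three regions, 1/f¹
Gaussian background at 10 μV RMS synthesized in the frequency domain, SB
at 4/min (lognormal durations, mean 1.3 s) with a 10 Hz carrier and 50 μV
amplitude (5× the background RMS), NGB at 2/min (mean 4 s) adding a 30 Hz
component amplitude-modulated by the 8 Hz spindle phase at 90 μV. Event
placement is Poisson thinned to forbid same-region overlap (1.5 s minimum
gap) so detection recall is well-defined. Burst envelopes are flat-topped
with Hann-shaped rise/fall ramps over 20 % of the duration at each end: a
smooth onset avoids filter-ringing confounds while retaining
full-amplitude cycles — under a full Hann bell, short bursts genuinely
fail the ≥5-peak quality filter at several percent rates, far above the
1–2 % rejection regime the filter is meant to operate in. Cycle-to-cycle
amplitude jitter (25 %) keeps events from being perfectly periodic.

Co-occurring partners are generated along the canonical region pairs with
probability 0.7: both events share a band-limited core component, mixed
with independent realizations according to a gain (default 0.8, setting
the cross-regional coherence), with the partner's copy shifted by the
configured signed lag (defaults: cortex leads striatum and thalamus by
20 ms, thalamus leads striatum by 10 ms — recorded in the ground truth
with the same sign convention as the analysis). Spikes are an
inhomogeneous Poisson process (base 8 Hz) thinned by intensity
λ(t) = r·(1 + c·ŝ(t)) where ŝ is the LFP rescaled to [−1, 1] and
c = 0.6 the coupling; coupling 0 reduces exactly to homogeneous Poisson.
The MUA channel is white noise (4 μV RMS) plus biphasic ~1 ms spike
templates (negative peak −40 μV) at the generated spike times.

What it does **not** emulate: biophysical (conductance-based) burst
generation, anesthesia-state dynamics, electrode drift, shared volume
conduction between regions, non-stationary background spectra,
single-unit structure within the MUA, or pharmacological inactivation.
Passing recovery tests on these synthetics therefore demonstrates that
the implementation is correct and calibrated under the stated statistical
structure — not that the biological findings they mirror would replicate
on new animals.

Determinism: one integer seed drives a `SeedSequence` tree spanned per
region and stage, so identical (config, seed) reproduce recordings,
ground truth and downstream results bit-identically.

## Problem sizes used in the test suite

The bundled checks run at sizes chosen to give tight Monte-Carlo error on
a single CPU: detection/classification recovery on one seeded 10-minute
three-region recording; null calibration over 500 simulated experiments
of 40 independent pairs with 200 shuffles each (the vectorized coherence
matrix makes this take well under a minute); lag recovery over 9
replicates per imposed lag in each band; permutation-test calibration
over 2,000 null replicates at 1,000 shuffles (the acceptance script uses
1,500 replicates), and power over 200 replicates with a 1-SD shift in 3
of 9 dimensions.

## Known limitations

* The Gaussian RMS fit assumes the quiescent RMS mode is approximately
  Gaussian; strongly skewed backgrounds raise the false-positive rate
  above the nominal 3σ tail (the detector's precision guarantee is stated
  on the generator's 1/f background).
* The shuffle null for pair coherence is slightly anticonservative for
  very small pair counts (finite-pool effects narrow the derangement
  null); calibration is verified at 40 pairs per recording pair set.
* Event boundaries are quantized to the 200 ms detection grid; onset-
  based analyses inherit up to one window of jitter.
* Spike "detection" is multi-unit thresholding; no spike sorting.
* The envelope detector's threshold percentile is a free per-recording
  parameter and is only used for cross-method overlap checks.
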