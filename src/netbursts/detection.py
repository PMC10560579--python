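"""Burst detection by RMS-distribution thresholding.

The detector works on the 4-100 Hz band-passed LFP. RMS amplitude is
computed over a fixed grid of non-overlapping 200 ms windows; a Gaussian is
least-squares fitted to the histogram of RMS values and the detection
threshold set at mu + 3*sigma of the fit. Because at older ages bursting can
dominate the recording and drag a naive fit toward the burst mode, the
fitted mean is capped at 50 uV. Consecutive supra-threshold windows merge
into a single burst event; quality filters then reject events that are too
short (<0.2 s), too long (>20 s), insufficiently oscillatory (<5 peaks above
the event's mean RMS) or artifactual (mean RMS > 1,000 uV).

An independent envelope-threshold detector and a time-overlap metric are
provided for cross-validating the RMS method on a given recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import signal as sps

from .exceptions import ConfigError
from .preprocess import windowed_rms

RMS_WINDOW_S = 0.2
MEAN_CAP_UV = 50.0
MIN_DURATION_S = 0.2
MAX_DURATION_S = 20.0
MIN_PEAKS = 5
ARTIFACT_RMS_UV = 1000.0


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    threshold: float
    bin_width: float
    capped: bool
    fallback: bool = False


@dataclass
class BurstEvent:
    region: str
    onset: float
    offset: float
    mean_rms: float
    max_rms: float
    negative_peak: float
    n_peaks: int
    rejection_reason: str | None = None
    event_id: int = -1

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


def fit_rms_threshold(rms: np.ndarray, mean_cap_uv: float = MEAN_CAP_UV,
                      sd_mult: float = 3.0) -> GaussianFit:
    """Fit a Gaussian to the RMS histogram and derive mu + sd_mult*sigma.

    Binning uses the Freedman-Diaconis rule with a floor of 50 bins.
    ``capped`` records whether an unconstrained fit would have placed the
    mean above the cap. Non-convergence falls back to (median, MAD-sigma).
    """
    rms = np.asarray(rms, dtype=np.float64)
    if rms.size < 50:
        raise ConfigError("need at least 50 RMS values to fit a threshold")
    q75, q25 = np.percentile(rms, (75, 25))
    fd_width = 2 * (q75 - q25) / rms.size ** (1 / 3)
    span = rms.max() - rms.min()
    n_bins = max(50, int(np.ceil(span / fd_width)) if fd_width > 0 else 50)
    counts, edges = np.histogram(rms, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]

    mad_sigma = np.median(np.abs(rms - np.median(rms))) / 0.6745
    p0 = (counts.max(), centers[int(np.argmax(counts))],
          max(mad_sigma, bin_width))

    def _fit(mu_upper):
        popt, _ = optimize.curve_fit(
            _gauss, centers, counts,
            p0=(p0[0], min(p0[1], mu_upper - 1e-9), p0[2]),
            bounds=((0, 0, 1e-12), (np.inf, mu_upper, np.inf)),
            maxfev=20000)
        return popt

    try:
        a_u, mu_u, sig_u = _fit(np.inf)
        capped = mu_u > mean_cap_uv
        if capped:
            _, mu, sigma = _fit(mean_cap_uv)
        else:
            mu, sigma = mu_u, sig_u
        fallback = False
    except (RuntimeError, ValueError):
        warnings.warn("Gaussian fit failed; falling back to median/MAD")
        mu = float(min(np.median(rms), mean_cap_uv))
        sigma = float(max(mad_sigma, 1e-12))
        capped = np.median(rms) > mean_cap_uv
        fallback = True
    sigma = float(abs(sigma))
    threshold = float(mu + sd_mult * sigma)
    return GaussianFit(float(mu), sigma, threshold, float(bin_width),
                       bool(capped), fallback)


def count_oscillation_peaks(seg: np.ndarray, mean_rms: float,
                            mode: str = "pos") -> int:
    """Count oscillation peaks exceeding the event's mean RMS level.

    Default mode counts positive local maxima whose height exceeds the mean
    RMS and whose prominence exceeds half of it (the same prominence rule
    the trough/ITI feature uses), so noise ripples riding on an excursion
    do not count as cycles. Mode "abs" counts local maxima of |signal|
    above the mean RMS with no prominence requirement.
    """
    if mode == "abs":
        peaks, _ = sps.find_peaks(np.abs(seg), height=mean_rms)
    elif mode == "pos":
        peaks, _ = sps.find_peaks(seg, height=mean_rms,
                                  prominence=0.5 * mean_rms)
    else:
        raise ConfigError(f"unknown peak-count mode {mode!r}")
    return int(peaks.size)


def detect_bursts(lfp: np.ndarray, fs: float, fit: GaussianFit,
                  region: str = "", window_s: float = RMS_WINDOW_S,
                  t0: float = 0.0, peak_mode: str = "pos",
                  ) -> list[BurstEvent]:
    """Merge consecutive supra-threshold RMS windows into burst events.

    ``lfp`` must already be band-passed 4-100 Hz. Event boundaries lie on
    the 200 ms window grid; no bridging across sub-threshold windows.
    Per-event measures (mean/max window RMS, most negative deflection, and
    the oscillation-peak count above the event's mean RMS) are attached.
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    rms = windowed_rms(lfp, fs, window_s)
    above = rms > fit.threshold
    events: list[BurstEvent] = []
    if not above.any():
        return events
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    n_win = int(round(window_s * fs))
    for s, e in zip(starts, ends):
        seg = lfp[s * n_win: e * n_win]
        seg_rms = rms[s:e]
        mean_rms = float(seg_rms.mean())
        events.append(BurstEvent(
            region=region,
            onset=t0 + s * window_s,
            offset=t0 + e * window_s,
            mean_rms=mean_rms,
            max_rms=float(seg_rms.max()),
            negative_peak=float(seg.min()),
            n_peaks=count_oscillation_peaks(seg, mean_rms, peak_mode),
            event_id=len(events),
        ))
    return events


def apply_rejection_filters(events: list[BurstEvent],
                            min_duration_s: float = MIN_DURATION_S,
                            max_duration_s: float = MAX_DURATION_S,
                            min_peaks: int = MIN_PEAKS,
                            artifact_rms_uv: float = ARTIFACT_RMS_UV,
                            ) -> tuple[list[BurstEvent], list[BurstEvent]]:
    """Label and separate rejected events; returns (retained, rejected)."""
    retained, rejected = [], []
    for ev in events:
        if ev.duration < min_duration_s:
            ev.rejection_reason = "too_short"
        elif ev.duration > max_duration_s:
            ev.rejection_reason = "too_long"
        elif ev.mean_rms > artifact_rms_uv:
            ev.rejection_reason = "artifact"
        elif ev.n_peaks < min_peaks:
            ev.rejection_reason = "too_few_peaks"
        else:
            ev.rejection_reason = None
        (rejected if ev.rejection_reason else retained).append(ev)
    return retained, rejected


def envelope_detect(lfp: np.ndarray, fs: float, percentile: float = 95.0,
                    region: str = "", min_duration_s: float = MIN_DURATION_S,
                    t0: float = 0.0) -> list[BurstEvent]:
    """Alternative detector: analytic-signal amplitude envelope thresholded
    at a per-recording percentile; contiguous supra-threshold spans become
    events. Used only to cross-check the RMS detector via overlap_fraction.
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    env = np.abs(sps.hilbert(lfp))
    thr = np.percentile(env, percentile)
    above = env > thr
    events: list[BurstEvent] = []
    if not above.any():
        return events
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    for s, e in zip(starts, ends):
        if (e - s) / fs < min_duration_s:
            continue
        seg = lfp[s:e]
        events.append(BurstEvent(
            region=region, onset=t0 + s / fs, offset=t0 + e / fs,
            mean_rms=float(np.sqrt(np.mean(seg ** 2))),
            max_rms=float(env[s:e].max()),
            negative_peak=float(seg.min()),
            n_peaks=int(sps.find_peaks(np.abs(seg))[0].size),
            event_id=len(events)))
    return events


def _merge_intervals(events) -> list[tuple[float, float]]:
    ivs = sorted((ev.onset, ev.offset) for ev in events)
    merged: list[list[float]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def overlap_fraction(events_a, events_b, symmetrize: bool = False) -> float:
    """Percent of time covered by A that is also covered by B.

    With ``symmetrize`` the mean of the A-in-B and B-in-A percentages is
    returned. Identical sets give 100, disjoint sets 0.
    """
    if symmetrize:
        return 0.5 * (overlap_fraction(events_a, events_b)
                      + overlap_fraction(events_b, events_a))
    a = _merge_intervals(events_a)
    b = _merge_intervals(events_b)
    total = sum(hi - lo for lo, hi in a)
    if total == 0:
        return 0.0
    inter = 0.0
    for lo, hi in a:
        for lo2, hi2 in b:
            inter += max(0.0, min(hi, hi2) - max(lo, lo2))
    return 100.0 * inter / total
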