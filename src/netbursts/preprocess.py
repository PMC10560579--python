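"""Filtering, windowed RMS and MUA spike handling.

Filtering follows the acquisition conventions for neonatal extracellular
data: a third-order Butterworth band-pass (1-100 Hz for LFP, 400-4,000 Hz
for MUA), applied forward-backward so that no group delay biases later lag
estimates (this doubles the effective order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError

LFP_BAND = (1.0, 100.0)
DETECTION_BAND = (4.0, 100.0)
MUA_BAND = (400.0, 4000.0)


@dataclass
class FilterSpec:
    low_hz: float
    high_hz: float
    order: int = 3

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ConfigError(
                f"high_hz={self.high_hz} must be below Nyquist ({fs / 2})")


@dataclass
class SpikeTrain:
    """Detected multi-unit spikes: times (s), 1 ms waveforms (uV), threshold."""

    times: np.ndarray
    waveforms: np.ndarray  # (n_spikes, n_waveform_samples)
    threshold_uv: float
    fs: float = float("nan")

    def __len__(self) -> int:
        return len(self.times)


def bandpass(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
             order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    spec = FilterSpec(low_hz, high_hz, order)
    spec.validate(fs)
    x = np.asarray(x, dtype=np.float64)
    if x.size <= 3 * order:
        raise ConfigError("signal too short for the requested filter order")
    sos = sps.butter(order, (low_hz, high_hz), btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, x)


def windowed_rms(x: np.ndarray, fs: float, window_s: float = 0.2) -> np.ndarray:
    """RMS per consecutive non-overlapping window, aligned to signal start.

    The trailing partial window is dropped.
    """
    n_win = int(round(window_s * fs))
    x = np.asarray(x, dtype=np.float64)
    if n_win < 1 or x.size < n_win:
        raise ConfigError("signal shorter than one RMS window")
    n = x.size // n_win
    chunks = x[: n * n_win].reshape(n, n_win)
    return np.sqrt(np.mean(chunks * chunks, axis=1))


def robust_sd(x: np.ndarray) -> float:
    """Baseline SD estimated as median(|x|)/0.6745 (spike-robust)."""
    return float(np.median(np.abs(x)) / 0.6745)


def detect_spikes(mua: np.ndarray, fs: float, sd_mult: float = 5.0,
                  robust: bool = True) -> SpikeTrain:
    """Threshold-crossing spike detection on band-passed MUA.

    The threshold sits ``sd_mult`` standard deviations below baseline
    (negative-going). Each maximal run of consecutive sub-threshold samples
    yields one spike at the run's minimum; a 1 ms waveform centred there is
    extracted, and candidates whose waveform never rises above 0 uV are
    rejected (real extracellular spikes are biphasic).
    """
    mua = np.asarray(mua, dtype=np.float64)
    sigma = robust_sd(mua) if robust else float(np.std(mua))
    if sigma == 0:
        warnings.warn("flat MUA signal; no spikes detected")
        return SpikeTrain(np.empty(0), np.empty((0, 0)), 0.0, fs)
    threshold = -sd_mult * sigma
    below = mua < threshold
    if not below.any():
        half = int(round(0.5e-3 * fs))
        return SpikeTrain(np.empty(0), np.empty((0, 2 * half + 1)),
                          threshold, fs)
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, below.size]
    half = int(round(0.5e-3 * fs))
    times, waves = [], []
    for s, e in zip(starts, ends):
        i_min = s + int(np.argmin(mua[s:e]))
        lo, hi = i_min - half, i_min + half + 1
        wave = np.zeros(2 * half + 1)
        src_lo, src_hi = max(lo, 0), min(hi, mua.size)
        wave[src_lo - lo: src_lo - lo + (src_hi - src_lo)] = mua[src_lo:src_hi]
        if wave.max() <= 0.0:
            continue
        times.append(i_min / fs)
        waves.append(wave)
    if not times:
        return SpikeTrain(np.empty(0), np.empty((0, 2 * half + 1)),
                          threshold, fs)
    return SpikeTrain(np.asarray(times), np.asarray(waves), threshold, fs)


def smooth_spike_train(times: np.ndarray, t_start: float, t_stop: float,
                       bin_ms: float = 2.0,
                       kernel_sd_ms: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Binned spike counts convolved with a unit-area Gaussian kernel.

    Returns ``(t_centers, intensity)``; the integral of the intensity equals
    the spike count up to edge truncation of the kernel.
    """
    times = np.asarray(times, dtype=np.float64)
    bin_s = bin_ms * 1e-3
    n_bins = max(1, int(np.ceil((t_stop - t_start) / bin_s)))
    counts, edges = np.histogram(times, bins=n_bins,
                                 range=(t_start, t_start + n_bins * bin_s))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sd_bins = kernel_sd_ms / bin_ms
    half = int(np.ceil(4 * sd_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_bins) ** 2)
    k /= k.sum() * bin_s  # unit area in time units
    smooth = np.convolve(counts.astype(np.float64), k, mode="same") * 1.0
    return centers, smooth


def spike_rate(times: np.ndarray, onset: float, offset: float) -> float:
    """Spike count in [onset, offset) divided by the interval duration (Hz)."""
    if offset <= onset:
        raise ConfigError("zero-length interval")
    times = np.asarray(times)
    n = int(np.count_nonzero((times >= onset) & (times < offset)))
    return n / (offset - onset)


def mean_spike_rate_across_channels(trains: list[np.ndarray], onset: float,
                                    offset: float) -> float:
    """Mean spike rate over the configured channels (e.g. the three channels
    centred on the target channel in focal-inactivation comparisons)."""
    return float(np.mean([spike_rate(t, onset, offset) for t in trains]))


def lidocaine_window(kind: str, duration_s: float,
                     control_start_s: float = 300.0,
                     drug_window_s: tuple[float, float] = (300.0, 1500.0),
                     ) -> tuple[float, float]:
    """Analysis window for spike-rate comparisons around focal inactivation.

    Control recordings are analyzed from 5 min onward (and must last at
    least 5 min); drug recordings between 5 and 25 min, where the
    inactivation is maximal.
    """
    if kind == "control":
        if duration_s < control_start_s:
            raise ConfigError("control recording shorter than 5 min")
        return control_start_s, duration_s
    if kind == "lidocaine":
        lo, hi = drug_window_s
        return lo, min(hi, duration_s)
    raise ConfigError(f"unknown recording kind {kind!r}")
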