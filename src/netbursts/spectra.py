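"""Multitaper spectral estimation and baseline normalization.

PSDs are estimated with the multitaper (DPSS/Slepian) method: 1 s windows
advanced in 0.1 s steps, time-half-bandwidth NW = 3, the first K = 5 Slepian
tapers averaged with unit weights. Because transient bursts ride on a 1/f
background, burst spectra are expressed relative to a baseline PSD (P/P0)
estimated from all non-bursting gaps longer than 1 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

from .exceptions import BaselineUnavailableError, ConfigError

WINDOW_S = 1.0
STEP_S = 0.1
NW = 3.0
N_TAPERS = 5
TOTAL_BAND = (1.0, 50.0)
THETA_ALPHA_BAND = (4.0, 16.0)
BETA_LOW_GAMMA_BAND = (16.0, 40.0)
BASELINE_FLOOR = 1e-12


@dataclass
class PSD:
    freqs: np.ndarray
    power: np.ndarray  # uV^2/Hz, one-sided
    params: dict = field(default_factory=dict)
    n_windows: int = 1


@dataclass
class NormalizedPSD:
    freqs: np.ndarray
    relative_power: np.ndarray  # dimensionless P/P0
    baseline_id: str = ""
    n_floored_bins: int = 0


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def multitaper_psd(segment: np.ndarray, fs: float, window_s: float = WINDOW_S,
                   step_s: float = STEP_S, nw: float = NW,
                   n_tapers: int = N_TAPERS, adaptive: bool = False) -> PSD:
    """Multitaper PSD averaged over sliding windows.

    Windows shorter than ``window_s`` are handled by using the whole segment
    as a single window (with a warning); segments under 0.2 s are refused.
    The frequency grid uses the next power-of-two FFT length. With
    ``adaptive`` the Thomson adaptive taper weights are used instead of unit
    weights.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.size < int(round(0.2 * fs)):
        raise ConfigError("segment shorter than 0.2 s")
    n_win = int(round(window_s * fs))
    if x.size < n_win:
        warnings.warn("segment shorter than one spectral window; "
                      "using a single whole-segment window")
        n_win = x.size
    step = max(1, int(round(step_s * fs)))
    starts = np.arange(0, x.size - n_win + 1, step)
    nfft = _next_pow2(n_win)
    tapers, eigvals = dpss(n_win, nw, n_tapers, return_ratios=True)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    acc = np.zeros(freqs.size)
    for s in starts:
        seg = x[s: s + n_win]
        spec = np.fft.rfft(tapers * seg[None, :], n=nfft, axis=1)
        eig = (spec.real ** 2 + spec.imag ** 2) / fs
        if adaptive:
            psd_k = _adaptive_weights(eig, eigvals, np.var(seg))
        else:
            psd_k = eig.mean(axis=0)
        acc += psd_k
    power = acc / starts.size
    # one-sided scaling (DC and Nyquist bins are not doubled)
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    return PSD(freqs, power,
               params={"window_s": n_win / fs, "step_s": step / fs,
                       "nw": nw, "n_tapers": n_tapers, "adaptive": adaptive},
               n_windows=int(starts.size))


def _adaptive_weights(eig: np.ndarray, eigvals: np.ndarray,
                      variance: float, n_iter: int = 10) -> np.ndarray:
    psd = eig[:2].mean(axis=0)
    ev = eigvals[:, None]
    for _ in range(n_iter):
        d = psd[None, :] / (ev * psd[None, :] + (1 - ev) * variance + 1e-300)
        w = d ** 2 * ev
        psd = (w * eig).sum(axis=0) / w.sum(axis=0)
    return psd


def non_burst_gaps(events, duration_s: float,
                   min_gap_s: float = 1.0) -> list[tuple[float, float]]:
    """Complement of the (merged) event intervals, keeping gaps > min_gap_s."""
    ivs = sorted((ev.onset, ev.offset) for ev in events)
    merged: list[list[float]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    gaps, cursor = [], 0.0
    for lo, hi in merged:
        if lo - cursor > min_gap_s:
            gaps.append((cursor, lo))
        cursor = max(cursor, hi)
    if duration_s - cursor > min_gap_s:
        gaps.append((cursor, duration_s))
    return gaps


def baseline_psd(lfp: np.ndarray, fs: float, events,
                 min_gap_s: float = 1.0, **mt_kwargs) -> PSD:
    """Mean multitaper PSD over all non-bursting gaps longer than 1 s,
    each gap weighted by its number of spectral windows."""
    duration_s = len(lfp) / fs
    gaps = non_burst_gaps(events, duration_s, min_gap_s)
    if not gaps:
        raise BaselineUnavailableError(
            "no non-burst gap exceeds the minimum baseline duration; "
            "supply an explicit baseline segment")
    acc = None
    total_w = 0
    for lo, hi in gaps:
        seg = lfp[int(round(lo * fs)): int(round(hi * fs))]
        psd = multitaper_psd(seg, fs, **mt_kwargs)
        w = psd.n_windows
        acc = psd.power * w if acc is None else acc + psd.power * w
        total_w += w
        freqs = psd.freqs
    return PSD(freqs, acc / total_w, params={"baseline_gaps": len(gaps)},
               n_windows=total_w)


def normalize_psd(psd: PSD, baseline: PSD,
                  floor: float = BASELINE_FLOOR,
                  baseline_id: str = "") -> NormalizedPSD:
    """Pointwise ratio P/P0; grids are linearly interpolated if they differ.

    Baseline bins below ``floor`` are floored before division and counted in
    ``n_floored_bins``.
    """
    if psd.freqs.shape == baseline.freqs.shape and np.allclose(
            psd.freqs, baseline.freqs):
        base = baseline.power
        freqs = psd.freqs
        power = psd.power
    else:
        freqs = psd.freqs
        power = psd.power
        base = np.interp(freqs, baseline.freqs, baseline.power)
    floored = base < floor
    base = np.where(floored, floor, base)
    return NormalizedPSD(freqs, power / base, baseline_id,
                         int(np.count_nonzero(floored)))


def band_fraction(npsd: NormalizedPSD, band: tuple[float, float],
                  total: tuple[float, float] = TOTAL_BAND) -> float:
    """Fraction of the normalized spectrum's total-band power in ``band``."""
    lo, hi = band
    if lo < total[0] or hi > total[1] or lo >= hi:
        raise ConfigError(f"band {band} must lie within the total band {total}")
    f, p = npsd.freqs, npsd.relative_power

    def _integral(a: float, b: float) -> float:
        # trapezoid with interpolated values at the band edges, so the
        # integral covers [a, b] exactly rather than the nearest bins
        inner = f[(f > a) & (f < b)]
        grid = np.concatenate(([a], inner, [b]))
        vals = np.interp(grid, f, p)
        return float(np.trapezoid(vals, grid))

    denom = _integral(*total)
    if denom <= 0:
        return 0.0
    return float(_integral(lo, hi) / denom)
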