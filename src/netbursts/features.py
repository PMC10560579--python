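"""Per-burst features, PCA embedding and fuzzy c-means classification.

Each retained burst yields a nine-dimensional feature vector capturing its
structure and spectral content: duration, negative peak, maximum RMS,
flatness (min/max of the 200 ms window RMS values), maximum slope (on a
500 S/s downsampled copy), mean inter-trough interval (troughs with
prominence above half the event RMS), relative theta-alpha (4-16 Hz) and
beta-low gamma (16-40 Hz) power of the baseline-normalized spectrum within
1-50 Hz, and spike rate. Features are z-scored, embedded with PCA, and the
first three components clustered with fuzzy c-means; events whose maximum
membership does not exceed 0.6 stay unclassified (UC). Of the two clusters,
the one with the higher mean relative beta-low gamma power is the nested
gamma spindle burst (NGB) class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import PCA

from .detection import BurstEvent
from .exceptions import ConfigError, UnresolvedLabelError
from .preprocess import spike_rate, windowed_rms
from .spectra import (BETA_LOW_GAMMA_BAND, THETA_ALPHA_BAND, PSD,
                      band_fraction, multitaper_psd, normalize_psd)

FEATURE_NAMES = [
    "duration_s",
    "negative_peak_uv",
    "max_rms_uv",
    "flatness",
    "max_slope_uv",
    "iti_s",
    "rel_theta_alpha",
    "rel_beta_low_gamma",
    "spike_rate_hz",
]

UC_THRESHOLD = 0.6
SLOPE_FS = 500.0


@dataclass
class FuzzyClustering:
    memberships: np.ndarray  # (n_events, n_clusters), rows sum to 1
    centers: np.ndarray      # (n_clusters, n_dims)
    fpc: float
    n_clusters: int
    fuzzifier: float
    objective: float
    labels: np.ndarray | None = None  # "SB"/"NGB"/"UC" once assigned


def compute_features(event: BurstEvent, lfp_filtered: np.ndarray, fs: float,
                     spike_times: np.ndarray, baseline: PSD,
                     window_s: float = 0.2) -> dict[str, float]:
    """Nine features for one retained burst event.

    ``lfp_filtered`` is the full 4-100 Hz band-passed trace of the event's
    region (structural features); band powers come from the event's
    baseline-normalized multitaper spectrum. An event with fewer than two
    qualifying troughs gets ITI = its duration and ``iti_degenerate`` set.
    """
    i0 = int(round(event.onset * fs))
    i1 = int(round(event.offset * fs))
    seg = np.asarray(lfp_filtered[i0:i1], dtype=np.float64)
    rms_chunks = windowed_rms(seg, fs, window_s)
    event_rms = float(np.sqrt(np.mean(seg ** 2)))

    # slope on a 500 S/s copy: inter-sample steps large enough to vary
    factor = max(1, int(round(fs / SLOPE_FS)))
    slow = sps.decimate(seg, factor, ftype="fir", zero_phase=True) \
        if factor > 1 else seg
    max_slope = float(np.max(np.abs(np.diff(slow)))) if slow.size > 1 else 0.0

    troughs, _ = sps.find_peaks(-seg, prominence=0.5 * event_rms)
    degenerate = troughs.size < 2
    iti = (event.duration if degenerate
           else float(np.mean(np.diff(troughs)) / fs))

    npsd = normalize_psd(multitaper_psd(seg, fs), baseline)
    rel_ta = band_fraction(npsd, THETA_ALPHA_BAND)
    rel_bg = band_fraction(npsd, BETA_LOW_GAMMA_BAND)

    return {
        "duration_s": event.duration,
        "negative_peak_uv": float(seg.min()),
        "max_rms_uv": float(rms_chunks.max()),
        "flatness": float(rms_chunks.min() / rms_chunks.max()),
        "max_slope_uv": max_slope,
        "iti_s": iti,
        "rel_theta_alpha": rel_ta,
        "rel_beta_low_gamma": rel_bg,
        "spike_rate_hz": spike_rate(spike_times, event.onset, event.offset),
        "iti_degenerate": float(degenerate),
    }


def feature_matrix(events, lfp_filtered, fs, spike_times, baseline,
                   ) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = compute_features(ev, lfp_filtered, fs, spike_times, baseline)
        row["event_id"] = ev.event_id
        row["region"] = ev.region
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_and_embed(features: pd.DataFrame | np.ndarray,
                        n_components: int = 3,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each feature, run PCA, return (scores, explained_variance).

    Constant features are dropped with a warning. The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    if isinstance(features, pd.DataFrame):
        x = features[FEATURE_NAMES].to_numpy(dtype=np.float64)
    else:
        x = np.asarray(features, dtype=np.float64)
    if x.shape[0] < n_components + 1:
        raise ConfigError(
            f"need at least {n_components + 1} events for a "
            f"{n_components}-component embedding")
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s)")
        x = x[:, keep]
        sd = sd[keep]
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=min(n_components, z.shape[1]))
    scores = pca.fit_transform(z)
    # deterministic sign convention
    for j in range(pca.components_.shape[0]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores, pca.explained_variance_ratio_


def fuzzy_cmeans(scores: np.ndarray, n_clusters: int, fuzzifier: float = 2.0,
                 n_restarts: int = 10, seed: int | None = 0,
                 tol: float = 1e-6, max_iter: int = 300) -> FuzzyClustering:
    """Standard fuzzy c-means; the best objective over restarts is kept.

    Convergence when the maximum membership change falls below ``tol``.
    The fuzzy partition coefficient (FPC) is the mean squared membership.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    n, d = x.shape
    if n == 0:
        raise ConfigError("empty input to fuzzy_cmeans")
    if n_clusters < 1:
        raise ConfigError("n_clusters must be >= 1")
    if n_clusters == 1:
        u = np.ones((n, 1))
        center = x.mean(axis=0, keepdims=True)
        obj = float(np.sum((x - center) ** 2))
        return FuzzyClustering(u, center, 1.0, 1, fuzzifier, obj)
    rng = np.random.default_rng(seed)
    best = None
    expo = 2.0 / (fuzzifier - 1.0)
    for _ in range(max(1, n_restarts)):
        u = rng.dirichlet(np.ones(n_clusters), size=n)
        for _ in range(max_iter):
            um = u ** fuzzifier
            centers = (um.T @ x) / um.sum(axis=0)[:, None]
            d2 = np.maximum(
                ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1), 1e-300)
            inv = d2 ** (-expo / 2.0)
            u_new = inv / inv.sum(axis=1, keepdims=True)
            if np.max(np.abs(u_new - u)) < tol:
                u = u_new
                break
            u = u_new
        um = u ** fuzzifier
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        obj = float(np.sum(um * d2))
        if best is None or obj < best.objective:
            fpc = float(np.sum(u ** 2) / n)  # mean squared membership
            best = FuzzyClustering(u, centers, fpc, n_clusters, fuzzifier,
                                   obj)
    return best


def select_k_by_fpc(scores: np.ndarray, k_range=range(2, 7), seed: int = 0,
                    **kwargs) -> tuple[int, dict[int, float]]:
    """Choose the cluster number maximizing the FPC (k = 1 excluded)."""
    k_range = [k for k in k_range]
    if any(k < 2 for k in k_range):
        raise ConfigError("k_range must exclude the trivial k = 1")
    curve = {k: fuzzy_cmeans(scores, k, seed=seed, **kwargs).fpc
             for k in k_range}
    best_k = max(curve, key=lambda k: (curve[k], -k))
    if all(curve[a] >= curve[b] for a, b in zip(k_range, k_range[1:])):
        warnings.warn("FPC decreases monotonically over k_range; the data "
                      "may contain a single cluster")
    return best_k, curve


def assign_labels(clustering: FuzzyClustering, features: pd.DataFrame,
                  threshold: float = UC_THRESHOLD,
                  tol: float = 1e-9) -> np.ndarray:
    """Map the two clusters to SB/NGB and apply the UC membership rule.

    An event is unclassified (UC) unless its maximum membership strictly
    exceeds ``threshold``. The cluster with the higher membership-weighted
    mean relative beta-low gamma power is NGB (the nested 16-40 Hz
    component is its defining signature); mean duration breaks exact ties.
    """
    if clustering.n_clusters != 2:
        raise ConfigError("label assignment requires exactly 2 clusters")
    u = clustering.memberships
    rel_bg = features["rel_beta_low_gamma"].to_numpy(dtype=np.float64)
    w_mean_bg = (u * rel_bg[:, None]).sum(axis=0) / u.sum(axis=0)
    diff = w_mean_bg[1] - w_mean_bg[0]
    if abs(diff) < tol:
        dur = features["duration_s"].to_numpy(dtype=np.float64)
        w_mean_dur = (u * dur[:, None]).sum(axis=0) / u.sum(axis=0)
        diff = w_mean_dur[1] - w_mean_dur[0]
        if abs(diff) < tol:
            raise UnresolvedLabelError(
                "clusters tie on beta-low gamma power and duration; "
                "override the cluster-to-class mapping manually")
    ngb_cluster = 1 if diff > 0 else 0
    names = np.array(["NGB" if k == ngb_cluster else "SB" for k in range(2)])
    arg = u.argmax(axis=1)
    labels = names[arg]
    labels[u.max(axis=1) <= threshold] = "UC"
    clustering.labels = labels
    return labels


def classify_events(features: pd.DataFrame, n_clusters: int = 2,
                    seed: int = 0, threshold: float = UC_THRESHOLD,
                    ) -> tuple[np.ndarray, FuzzyClustering, np.ndarray]:
    """Convenience pipeline: embed, cluster, label. Returns
    (labels, clustering, pc_scores)."""
    scores, _ = normalize_and_embed(features)
    clustering = fuzzy_cmeans(scores, n_clusters, seed=seed)
    labels = assign_labels(clustering, features, threshold)
    return labels, clustering, scores
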