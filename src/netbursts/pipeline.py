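"""End-to-end orchestration: detection -> features -> classification ->
spectra -> interactions -> statistics.

The pipeline consumes a YAML/dict configuration that either names an input
recording or contains a ``simulate`` block for the bundled generator, runs
every stage with the documented defaults, writes per-stage CSV/JSON outputs
and returns a machine-readable summary. Every output embeds the seed and a
hash of the configuration so results are traceable to their parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import detection, features, interactions, spectra, stats, synth
from .exceptions import ConfigError
from .io import Recording, events_to_frame, read_recording, \
    select_channel, write_events
from .preprocess import DETECTION_BAND, MUA_BAND, bandpass, detect_spikes, \
    windowed_rms

log = logging.getLogger("netbursts")


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return dict(source)
    text = Path(source).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration file must contain a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _get_recording(cfg: dict, seed: int | None,
                   ) -> tuple[Recording, synth.GroundTruth | None]:
    if "simulate" in cfg:
        fields = {f.name for f in dataclasses.fields(synth.SynthConfig)}
        params = dict(cfg["simulate"] or {})
        unknown = set(params) - fields
        if unknown:
            raise ConfigError(f"unknown simulate field(s): {sorted(unknown)}")
        if "pair_lag_ms" in params and isinstance(params["pair_lag_ms"], dict):
            params["pair_lag_ms"] = {
                tuple(k.split("-")) if isinstance(k, str) else tuple(k): v
                for k, v in params["pair_lag_ms"].items()}
        if "regions" in params:
            params["regions"] = tuple(params["regions"])
        if seed is not None:
            params["seed"] = seed
        scfg = synth.SynthConfig(**params)
        return synth.generate_recording(scfg)
    if "recording" in cfg:
        return read_recording(cfg["recording"]), None
    raise ConfigError("config must contain a 'recording' path or a "
                      "'simulate' block")


def detect_stage(rec: Recording, cfg: dict) -> dict[str, Any]:
    """Per-region RMS-threshold burst detection. Returns per-region dict of
    filtered LFP, fit, retained and rejected events."""
    out: dict[str, Any] = {}
    channel_cfg = cfg.get("channels", {})
    eid = 0
    for region in rec.regions:
        idx = select_channel(rec, region,
                             candidates=channel_cfg.get(region),
                             override=(channel_cfg.get(region, [None])[0]
                                       if isinstance(channel_cfg.get(region),
                                                     list)
                                       and len(channel_cfg[region]) == 1
                                       else None))
        lfp = bandpass(rec.samples[idx], rec.fs, *DETECTION_BAND)
        rms = windowed_rms(lfp, rec.fs)
        fit = detection.fit_rms_threshold(rms)
        events = detection.detect_bursts(lfp, rec.fs, fit, region=region)
        retained, rejected = detection.apply_rejection_filters(events)
        for ev in retained + rejected:
            ev.event_id = eid
            eid += 1
        log.info("%s: threshold %.2f uV (mu=%.2f, sigma=%.2f, capped=%s); "
                 "%d retained, %d rejected", region, fit.threshold, fit.mu,
                 fit.sigma, fit.capped, len(retained), len(rejected))
        out[region] = {"lfp": lfp, "fit": fit, "retained": retained,
                       "rejected": rejected, "channel": idx}
    return out


def spikes_stage(rec: Recording, cfg: dict) -> dict[str, np.ndarray]:
    """MUA spike detection per region (400-4,000 Hz band where fs allows)."""
    out = {}
    for region in rec.regions:
        try:
            idx = rec.channel_index(region, "mua")
        except KeyError:
            out[region] = np.empty(0)
            continue
        high = min(MUA_BAND[1], 0.45 * rec.fs)
        if high <= MUA_BAND[0]:
            log.warning("%s: fs too low for MUA band; no spikes", region)
            out[region] = np.empty(0)
            continue
        mua = bandpass(rec.samples[idx], rec.fs, MUA_BAND[0], high)
        train = detect_spikes(mua, rec.fs,
                              sd_mult=cfg.get("spike_sd_mult", 5.0))
        out[region] = train.times
    return out


def features_stage(det: dict, spikes: dict, fs: float) -> pd.DataFrame:
    frames = []
    for region, d in det.items():
        if not d["retained"]:
            continue
        baseline = spectra.baseline_psd(
            d["lfp"], fs, d["retained"] + d["rejected"])
        frames.append(features.feature_matrix(
            d["retained"], d["lfp"], fs, spikes.get(region, np.empty(0)),
            baseline))
    if not frames:
        raise ConfigError("no retained events; cannot build feature matrix")
    return pd.concat(frames, ignore_index=True)


def classify_stage(feats: pd.DataFrame, cfg: dict, seed: int):
    labels, clustering, scores = features.classify_events(
        feats, n_clusters=cfg.get("n_clusters", 2), seed=seed)
    feats = feats.copy()
    feats["pc1"], feats["pc2"], feats["pc3"] = scores.T[:3]
    order = ["SB", "NGB"]
    names = _cluster_names(clustering)
    for k in range(2):
        feats[f"membership_{names[k].lower()}"] = clustering.memberships[:, k]
    feats["label"] = labels
    return feats, clustering


def _cluster_names(clustering) -> list[str]:
    if clustering.labels is None:
        return ["c0", "c1"]
    # recover which cluster index maps to NGB from the assigned labels
    arg = clustering.memberships.argmax(axis=1)
    names = ["SB", "NGB"]
    for k in (0, 1):
        mask = (arg == k) & (clustering.labels != "UC")
        if mask.any():
            names[k] = clustering.labels[mask][0]
    return names


def interactions_stage(rec: Recording, det: dict, feats: pd.DataFrame,
                       spikes: dict, cfg: dict, seed: int) -> dict:
    """Co-occurrence, coherence + shuffle null, and lags per region pair."""
    n_shuffle = cfg.get("n_shuffle", 1000)
    label_by_id = dict(zip(feats["event_id"], feats["label"]))
    results: dict[str, Any] = {}
    pairs_rows, lag_rows = [], []
    for ra, rb in interactions.CANONICAL_PAIRS:
        if ra not in det or rb not in det:
            continue
        ev_a = [e for e in det[ra]["retained"]]
        ev_b = [e for e in det[rb]["retained"]]
        for e in ev_a + ev_b:
            e.kind = label_by_id.get(e.event_id, "UC")
        pairs = interactions.find_cooccurring(ev_a, ev_b)
        if not pairs:
            continue
        incidence = interactions.cooccurrence_incidence(pairs, ev_a, ev_b)
        lfp_a, lfp_b = det[ra]["lfp"], det[rb]["lfp"]
        sigs_a, sigs_b = [], []
        for p in pairs:
            i0, i1, _ = interactions._common_span(p, rec.fs, rec.n_samples)
            sigs_a.append(lfp_a[i0:i1])
            sigs_b.append(lfp_b[i0:i1])
        coh = [interactions.cross_spectral_coherence(p, lfp_a, lfp_b, rec.fs)
               for p in pairs]
        null = None
        if len(pairs) >= 2:
            cmat = interactions.pairwise_mean_coherence(sigs_a, sigs_b,
                                                        rec.fs)
            null = interactions.coherence_null(cmat, n_shuffle=n_shuffle,
                                               seed=seed)
        for p, c in zip(pairs, coh):
            row = {"region_a": ra, "region_b": rb,
                   "event_id_a": p.event_a.event_id,
                   "event_id_b": p.event_b.event_id,
                   "type_combo": p.type_combo,
                   "onset_diff_s": p.onset_diff,
                   "mean_csc": c.mean_coherence,
                   "null_thr": null.threshold if null else float("nan"),
                   "significant": (c.mean_coherence > null.threshold
                                   if null else None),
                   "rejected": c.rejected_artifact}
            pairs_rows.append(row)
            if c.rejected_artifact:
                continue
            span = (max(p.event_a.onset, p.event_b.onset),
                    min(p.event_a.offset, p.event_b.offset))
            if span[1] - span[0] >= 1.0:
                i0, i1 = int(span[0] * rec.fs), int(span[1] * rec.fs)
                for band in (interactions.THETA_ALPHA_BAND,
                             interactions.BETA_LOW_GAMMA_BAND):
                    lr = interactions.prewhitened_xcorr_lag(
                        lfp_a[i0:i1], lfp_b[i0:i1], rec.fs, band,
                        region_pair=(ra, rb))
                    lag_rows.append({
                        "region_a": ra, "region_b": rb,
                        "event_id_a": p.event_a.event_id,
                        "event_id_b": p.event_b.event_id,
                        "band": f"{band[0]:g}-{band[1]:g}Hz",
                        "lag_ms": lr.lag_ms, "peak_corr": lr.peak_corr,
                        "putative_mono": lr.putative_mono,
                        "sign_convention": lr.sign_convention})
        results[f"{ra}-{rb}"] = {
            "n_pairs": len(pairs), "incidence": incidence,
            "null_threshold": null.threshold if null else None,
            "observed_mean_csc": null.observed_mean if null else None,
            "significant": null.significant if null else None}
    return {"summary": results,
            "pairs": pd.DataFrame(pairs_rows),
            "lags": pd.DataFrame(lag_rows)}


def stats_stage(feats: pd.DataFrame, cfg: dict, seed: int) -> dict:
    """Permutation F comparing each burst class across region pairs."""
    n_perm = cfg.get("n_perm", 10_000)
    out = {}
    cols = features.FEATURE_NAMES
    regions = sorted(feats["region"].unique())
    for kind in ("SB", "NGB"):
        sub = feats[feats["label"] == kind]
        for i, ra in enumerate(regions):
            for rb in regions[i + 1:]:
                a = sub[sub["region"] == ra][cols].to_numpy()
                b = sub[sub["region"] == rb][cols].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    continue
                res = stats.multivariate_perm_f(a, b, n_perm=n_perm,
                                                seed=seed)
                out[f"{kind}:{ra}-vs-{rb}"] = {
                    "f": res.f_stat, "p": res.p_value,
                    "effect_size": res.effect_size,
                    "n": list(res.group_sizes), "n_perm": res.n_perm}
    if out:
        adj = stats.bonferroni([v["p"] for v in out.values()])
        for v, padj in zip(out.values(), adj):
            v["p_bonferroni"] = float(padj)
    return out


def run_pipeline(config: str | Path | dict, out_dir: str | Path,
                 seed: int = 0) -> dict:
    """Run every stage and write the results bundle under ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    rec, truth = _get_recording(cfg, seed)
    if truth is not None:
        synth.write_truth(truth, out)

    det = detect_stage(rec, cfg)
    all_events = [e for d in det.values() for e in d["retained"] + d["rejected"]]
    write_events(events_to_frame(all_events), out / "events.csv")

    spikes = spikes_stage(rec, cfg)
    feats = features_stage(det, spikes, rec.fs)
    feats, clustering = classify_stage(feats, cfg, seed)
    feats.to_csv(out / "labeled_events.csv", index=False)

    inter = interactions_stage(rec, det, feats, spikes, cfg, seed)
    inter["pairs"].to_csv(out / "pairs.csv", index=False)
    inter["lags"].to_csv(out / "lags.csv", index=False)

    stat_results = stats_stage(feats, cfg, seed)

    summary = {
        "config_hash": chash,
        "seed": seed,
        "fs": rec.fs,
        "duration_s": rec.duration_s,
        "regions": rec.regions,
        "n_events_retained": int(sum(len(d["retained"])
                                     for d in det.values())),
        "n_events_rejected": int(sum(len(d["rejected"])
                                     for d in det.values())),
        "thresholds_uv": {r: d["fit"].threshold for r, d in det.items()},
        "fpc": clustering.fpc,
        "label_counts": feats["label"].value_counts().to_dict(),
        "interactions": inter["summary"],
        "stats": stat_results,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 default=str))
    return summary
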