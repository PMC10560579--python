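"""Ground-truth-annotated synthetic recordings of neonatal network bursts.

The generator emulates the phenomenology of early (P5-12) cortico-basal
ganglia activity: a 1/f background with intermittent oscillatory bursts of
two kinds — spindle bursts (SB; dominant 4-16 Hz power, ~1.3 s) and nested
gamma spindle bursts (NGB; an additional 16-40 Hz component riding on a
spindle-frequency envelope, longer and larger) — occurring a few times per
minute per region. Bursts can co-occur across regions with a configurable
signed propagation lag (tens of ms) and a shared band-limited component
whose gain sets the cross-regional coherence. A companion MUA channel per
region carries biphasic spike waveforms from an inhomogeneous Poisson
process phase-coupled to the local LFP oscillation.

Lag sign convention matches the interaction analysis: for a region pair
(a, b), a positive lag means region b leads (its activity occurs earlier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import windows as sps_windows

from .exceptions import ConfigError
from .io import ChannelMeta, Recording

DEFAULT_PAIR_LAGS_MS = {
    ("cortex", "striatum"): -20.0,   # cortex leads striatum by 20 ms
    ("cortex", "thalamus"): -20.0,   # cortex leads thalamus
    ("thalamus", "striatum"): -10.0, # thalamus leads striatum
}


@dataclass
class SynthConfig:
    duration_s: float = 600.0
    fs: float = 10_000.0
    regions: tuple[str, ...] = ("cortex", "striatum", "thalamus")
    # incidence: a few events per minute per region
    sb_rate_per_min: float = 4.0
    ngb_rate_per_min: float = 2.0
    # lognormal durations (log-space sigma); SB ~1.3 s, NGB ~4 s mean
    sb_duration_mean_s: float = 1.3
    sb_duration_sigma: float = 0.25
    ngb_duration_mean_s: float = 4.0
    ngb_duration_sigma: float = 0.2
    sb_carrier_hz: float = 10.0
    ngb_carrier_hz: float = 8.0
    ngb_nested_hz: float = 30.0
    sb_amplitude_uv: float = 50.0
    ngb_amplitude_uv: float = 90.0
    noise_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    cooccurrence_prob: float = 0.7
    pair_lag_ms: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_LAGS_MS))
    shared_gain: float = 0.8
    spike_rate_hz: float = 8.0
    phase_coupling: float = 0.6
    mua_noise_rms_uv: float = 4.0
    spike_amp_uv: float = 40.0
    min_event_gap_s: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        highest = max(self.sb_carrier_hz, self.ngb_carrier_hz,
                      self.ngb_nested_hz)
        if self.fs < 2.5 * highest:
            raise ConfigError(
                f"fs={self.fs} must be >= 2.5x the highest synthesized "
                f"frequency ({highest} Hz)")
        for name in ("sb_rate_per_min", "ngb_rate_per_min", "spike_rate_hz",
                     "noise_rms_uv", "mua_noise_rms_uv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("cooccurrence_prob", "shared_gain", "phase_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not self.regions:
            raise ConfigError("regions must be non-empty")


@dataclass
class GroundTruth:
    """Inserted events, cross-regional pairs and spike times.

    ``events`` columns: event_id, region, kind (SB/NGB), onset_s, offset_s,
    amp_uv. ``pairs`` columns: event_id_a, event_id_b, region_a, region_b,
    lag_ms (positive = region_b leads). ``spikes`` maps region -> times (s).
    """

    events: pd.DataFrame
    pairs: pd.DataFrame
    spikes: dict[str, np.ndarray]


def pink_noise(n: int, fs: float, exponent: float, rms: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent Gaussian noise synthesized in the frequency domain."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(amp * phases, n=n)
    x *= rms / np.sqrt(np.mean(x * x))
    return x


def synthesize_burst(kind: str, duration: float, fs: float,
                     carrier_hz: float = 10.0, nested_hz: float = 30.0,
                     amplitude: float = 1.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """One burst waveform (uV) with a Hann rise/fall envelope.

    SB: an oscillation at ``carrier_hz`` (4-16 Hz band) with mild cycle-to-
    cycle amplitude jitter. NGB: the same spindle-frequency component plus a
    ``nested_hz`` (16-40 Hz) component amplitude-modulated by the spindle
    phase, i.e. nested within the slower envelope.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    rng = rng or np.random.default_rng()
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # flat top with Hann-shaped rise/fall ramps (20% of the duration each)
    env = sps_windows.tukey(n, 0.4)
    phi = rng.uniform(0, 2 * np.pi)
    # slow amplitude jitter makes consecutive cycles inequal, as in vivo
    jitter = 1.0 + 0.25 * np.interp(
        t, np.linspace(0, duration, 8), rng.standard_normal(8))
    spindle = jitter * np.sin(2 * np.pi * carrier_hz * t + phi)
    if kind == "SB":
        wave = spindle
    elif kind == "NGB":
        mod = 0.5 * (1.0 + np.sin(2 * np.pi * carrier_hz * t + phi))
        nested = mod * np.sin(2 * np.pi * nested_hz * t
                              + rng.uniform(0, 2 * np.pi))
        wave = spindle + 0.9 * nested
    else:
        raise ConfigError(f"unknown burst kind {kind!r}")
    return amplitude * env * wave


def generate_spike_train(lfp_segment: np.ndarray, fs: float, base_rate: float,
                         coupling: float, rng: np.random.Generator,
                         t0: float = 0.0) -> np.ndarray:
    """Inhomogeneous Poisson spikes with LFP-phase-modulated intensity.

    The intensity is ``base_rate * (1 + coupling * s(t))`` where ``s`` is
    the LFP segment rescaled to [-1, 1] by its absolute maximum; with
    ``coupling = 0`` the process is homogeneous at ``base_rate``. Generated
    by thinning.
    """
    if base_rate < 0:
        raise ConfigError("base_rate must be >= 0")
    if not 0.0 <= coupling <= 1.0:
        raise ConfigError("coupling must lie in [0, 1]")
    n = len(lfp_segment)
    duration = n / fs
    if base_rate == 0 or n == 0:
        return np.empty(0)
    lam_max = base_rate * (1.0 + coupling)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0, duration, n_cand))
    if coupling == 0:
        return t0 + cand
    peak = np.max(np.abs(lfp_segment))
    if peak == 0:
        return t0 + cand
    s = np.asarray(lfp_segment) / peak
    lam = base_rate * (1.0 + coupling * s[np.minimum(
        (cand * fs).astype(int), n - 1)])
    keep = rng.uniform(0, lam_max, n_cand) < lam
    return t0 + cand[keep]


def spike_template(fs: float, amp_uv: float) -> np.ndarray:
    """Biphasic ~1 ms extracellular spike template (dominant negative phase)."""
    half = int(round(0.5e-3 * fs))
    t = np.arange(-half, half + 1) / fs
    neg = -np.exp(-0.5 * (t / 0.12e-3) ** 2)
    pos = 0.45 * np.exp(-0.5 * ((t - 0.25e-3) / 0.18e-3) ** 2)
    w = neg + pos
    return amp_uv * w / abs(w.min())  # negative peak = -amp_uv


def _place_events(cfg: SynthConfig, region: str,
                  rng: np.random.Generator) -> list[dict]:
    """Poisson placement of SB/NGB events, thinned to forbid same-region
    overlap (a minimum gap keeps detection recall well-defined)."""
    proposals = []
    for kind, rate, mean_s, sigma in (
            ("SB", cfg.sb_rate_per_min, cfg.sb_duration_mean_s,
             cfg.sb_duration_sigma),
            ("NGB", cfg.ngb_rate_per_min, cfg.ngb_duration_mean_s,
             cfg.ngb_duration_sigma)):
        n = rng.poisson(rate * cfg.duration_s / 60.0)
        onsets = rng.uniform(0, cfg.duration_s, n)
        mu = np.log(mean_s) - sigma ** 2 / 2.0
        durs = np.clip(rng.lognormal(mu, sigma, n), 0.4, 15.0)
        for o, d in zip(onsets, durs):
            proposals.append({"region": region, "kind": kind,
                              "onset_s": float(o), "offset_s": float(o + d)})
    proposals.sort(key=lambda e: e["onset_s"])
    placed: list[dict] = []
    for ev in proposals:
        if ev["offset_s"] > cfg.duration_s:
            continue
        if placed and ev["onset_s"] < placed[-1]["offset_s"] + cfg.min_event_gap_s:
            continue
        placed.append(ev)
    return placed


def _fits(events: list[dict], onset: float, offset: float, gap: float,
          limit: float) -> bool:
    if onset < 0 or offset > limit:
        return False
    return all(offset + gap <= e["onset_s"] or onset >= e["offset_s"] + gap
               for e in events)


def generate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Synthesize a multi-region LFP+MUA recording with full ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    streams = {r: rng.spawn(1)[0] for r in cfg.regions}
    n = int(round(cfg.duration_s * cfg.fs))

    per_region: dict[str, list[dict]] = {
        r: _place_events(cfg, r, streams[r]) for r in cfg.regions}
    pairs: list[dict] = []

    # co-occurring partners along the canonical pair ordering
    pair_rng = rng.spawn(1)[0]
    for (ra, rb), lag_ms in cfg.pair_lag_ms.items():
        if ra not in cfg.regions or rb not in cfg.regions:
            continue
        for ev in list(per_region[ra]):
            if ev.get("partner_of") is not None:
                continue
            if pair_rng.uniform() >= cfg.cooccurrence_prob:
                continue
            shift_s = lag_ms / 1000.0  # positive lag: partner (b) earlier
            onset_b = ev["onset_s"] - shift_s
            offset_b = ev["offset_s"] - shift_s
            if not _fits(per_region[rb], onset_b, offset_b,
                         cfg.min_event_gap_s, cfg.duration_s):
                continue
            partner = {"region": rb, "kind": ev["kind"], "onset_s": onset_b,
                       "offset_s": offset_b, "partner_of": ev,
                       "lag_ms": lag_ms}
            per_region[rb].append(partner)
            per_region[rb].sort(key=lambda e: e["onset_s"])
            pairs.append({"a": ev, "b": partner, "lag_ms": lag_ms})

    for evs in per_region.values():
        for ev in evs:
            ev.setdefault("partner_of", None)

    # assemble signals
    lfp = {r: pink_noise(n, cfg.fs, cfg.noise_exponent, cfg.noise_rms_uv,
                         streams[r]) for r in cfg.regions}
    wave_rng = rng.spawn(1)[0]
    for r in cfg.regions:
        for ev in per_region[r]:
            if ev["partner_of"] is not None:
                continue  # waveform inserted together with its source event
            dur = ev["offset_s"] - ev["onset_s"]
            amp = (cfg.sb_amplitude_uv if ev["kind"] == "SB"
                   else cfg.ngb_amplitude_uv)
            kwargs = dict(carrier_hz=(cfg.sb_carrier_hz if ev["kind"] == "SB"
                                      else cfg.ngb_carrier_hz),
                          nested_hz=cfg.ngb_nested_hz, rng=wave_rng)
            partners = [p for p in pairs if p["a"] is ev]
            if not partners:
                w = synthesize_burst(ev["kind"], dur, cfg.fs, amplitude=amp,
                                     **kwargs)
                _add(lfp[r], int(round(ev["onset_s"] * cfg.fs)), w)
                ev["amp_uv"] = amp
            else:
                core = synthesize_burst(ev["kind"], dur, cfg.fs,
                                        amplitude=1.0, **kwargs)
                g = cfg.shared_gain
                ind_a = synthesize_burst(ev["kind"], dur, cfg.fs,
                                         amplitude=1.0, **kwargs)
                wa = amp * (np.sqrt(g) * core + np.sqrt(1 - g) * ind_a)
                _add(lfp[r], int(round(ev["onset_s"] * cfg.fs)), wa)
                ev["amp_uv"] = amp
                for p in partners:
                    ind_b = synthesize_burst(ev["kind"], dur, cfg.fs,
                                             amplitude=1.0, **kwargs)
                    wb = amp * (np.sqrt(g) * core + np.sqrt(1 - g) * ind_b)
                    b = p["b"]
                    _add(lfp[b["region"]],
                         int(round(b["onset_s"] * cfg.fs)), wb)
                    b["amp_uv"] = amp

    # spikes + MUA channels
    spikes: dict[str, np.ndarray] = {}
    mua: dict[str, np.ndarray] = {}
    template = spike_template(cfg.fs, cfg.spike_amp_uv)
    for r in cfg.regions:
        srng = streams[r].spawn(1)[0]
        spikes[r] = generate_spike_train(lfp[r], cfg.fs, cfg.spike_rate_hz,
                                         cfg.phase_coupling, srng)
        m = srng.standard_normal(n) * cfg.mua_noise_rms_uv
        half = (len(template) - 1) // 2
        for st in spikes[r]:
            i = int(round(st * cfg.fs))
            lo, hi = i - half, i + half + 1
            src_lo, src_hi = max(lo, 0), min(hi, n)
            m[src_lo:src_hi] += template[src_lo - lo: src_lo - lo
                                         + (src_hi - src_lo)]
        mua[r] = m

    samples = np.empty((2 * len(cfg.regions), n), dtype=np.float32)
    channels = []
    for i, r in enumerate(cfg.regions):
        samples[2 * i] = lfp[r]
        samples[2 * i + 1] = mua[r]
        channels.append(ChannelMeta(r, "lfp", 0))
        channels.append(ChannelMeta(r, "mua", 0))
    rec = Recording(samples, cfg.fs, channels)

    # truth tables
    rows, ids = [], {}
    eid = 0
    for r in cfg.regions:
        for ev in per_region[r]:
            ids[id(ev)] = eid
            rows.append({"event_id": eid, "region": r, "kind": ev["kind"],
                         "onset_s": ev["onset_s"], "offset_s": ev["offset_s"],
                         "amp_uv": ev.get("amp_uv", 0.0)})
            eid += 1
    events_df = pd.DataFrame(
        rows, columns=["event_id", "region", "kind", "onset_s", "offset_s",
                       "amp_uv"])
    pair_rows = [{"event_id_a": ids[id(p["a"])], "event_id_b": ids[id(p["b"])],
                  "region_a": p["a"]["region"], "region_b": p["b"]["region"],
                  "lag_ms": p["lag_ms"]} for p in pairs]
    pairs_df = pd.DataFrame(
        pair_rows, columns=["event_id_a", "event_id_b", "region_a",
                            "region_b", "lag_ms"])
    return rec, GroundTruth(events_df, pairs_df, spikes)


def _add(signal: np.ndarray, start: int, wave: np.ndarray) -> None:
    lo, hi = max(start, 0), min(start + len(wave), len(signal))
    if hi > lo:
        signal[lo:hi] += wave[lo - start: hi - start]


def score_detection(truth_events: pd.DataFrame, detected,
                    region: str | None = None) -> dict[str, float]:
    """Recall/precision of detected events against ground truth by overlap.

    A truth event is recalled if any detection overlaps its span; a
    detection is a true positive if it overlaps any truth span.
    """
    t = truth_events
    if region is not None:
        t = t[t["region"] == region]
        detected = [ev for ev in detected if ev.region == region]
    t_iv = list(zip(t["onset_s"], t["offset_s"]))
    d_iv = [(ev.onset, ev.offset) for ev in detected]

    def _overlaps(a, bs):
        return any(min(a[1], b[1]) > max(a[0], b[0]) for b in bs)

    recall = (np.mean([_overlaps(a, d_iv) for a in t_iv]) if t_iv else
              float("nan"))
    precision = (np.mean([_overlaps(d, t_iv) for d in d_iv]) if d_iv else
                 float("nan"))
    return {"recall": float(recall), "precision": float(precision),
            "n_truth": len(t_iv), "n_detected": len(d_iv)}


def write_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.events.to_csv(out / "truth_events.csv", index=False)
    truth.pairs.to_csv(out / "truth_pairs.csv", index=False)
    rows = [{"region": r, "time_s": t} for r, ts in truth.spikes.items()
            for t in ts]
    pd.DataFrame(rows, columns=["region", "time_s"]).to_csv(
        out / "truth_spikes.csv", index=False)
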