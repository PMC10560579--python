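"""Reading and writing recordings, event tables and result files.

Two on-disk signal containers are supported:

* HDF5 (``.h5``/``.hdf5``): a ``samples`` dataset (channels x time) with
  ``fs``, ``t0``, ``gain_uv_per_bit`` attributes and per-channel ``region``,
  ``kind`` and ``depth`` arrays.
* Flat binary (``.dat``) with a JSON sidecar (same stem, ``.json``) carrying
  ``fs``, ``dtype``, ``n_channels``, ``gain_uv_per_bit``, ``t0`` and a
  ``channels`` list of ``{"region": ..., "kind": ..., "depth": ...}``.

All in-memory sample values are microvolts (uV); integer payloads are scaled
by the sidecar gain on read. Times are seconds, 0-based; event intervals are
half-open ``[onset, offset)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .exceptions import ConfigError, FormatError, IntegrityError

EVENT_COLUMNS = [
    "event_id",
    "region",
    "onset_s",
    "offset_s",
    "duration_s",
    "mean_rms_uv",
    "max_rms_uv",
    "neg_peak_uv",
    "n_peaks",
    "rejection_reason",
]


@dataclass
class ChannelMeta:
    region: str
    kind: str = "lfp"  # "lfp" or "mua"
    depth: int = 0


@dataclass
class Recording:
    """Multichannel continuous recording in microvolts.

    ``samples`` is a (n_channels, n_samples) array; every channel shares the
    sampling rate ``fs`` (S/s) and the start time ``t0`` (s).
    """

    samples: np.ndarray
    fs: float
    channels: list[ChannelMeta]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise IntegrityError(
                f"{len(self.channels)} channel descriptors for "
                f"{self.samples.shape[0]} sample rows"
            )
        for meta in self.channels:
            if not meta.region:
                raise ConfigError("channel region label must be non-empty")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for meta in self.channels:
            if meta.region not in seen:
                seen.append(meta.region)
        return seen

    def channel_index(self, region: str, kind: str = "lfp") -> int:
        for i, meta in enumerate(self.channels):
            if meta.region == region and meta.kind == kind:
                return i
        raise KeyError(f"no {kind} channel for region {region!r}")

    def get_channel(self, region: str, kind: str = "lfp") -> np.ndarray:
        return self.samples[self.channel_index(region, kind)]


def write_recording(rec: Recording, path: str | Path,
                    dtype: str | None = None,
                    gain_uv_per_bit: float = 1.0) -> Path:
    """Write a recording to HDF5 or flat-binary+JSON depending on suffix."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("samples", data=rec.samples.astype(
                dtype or rec.samples.dtype))
            ds.attrs["fs"] = float(rec.fs)
            ds.attrs["t0"] = float(rec.t0)
            ds.attrs["gain_uv_per_bit"] = float(gain_uv_per_bit)
            f.create_dataset("region", data=np.array(
                [m.region for m in rec.channels], dtype="S32"))
            f.create_dataset("kind", data=np.array(
                [m.kind for m in rec.channels], dtype="S8"))
            f.create_dataset("depth", data=np.array(
                [m.depth for m in rec.channels], dtype="i4"))
        return path
    # flat binary + JSON sidecar; data stored channel-major (C order)
    payload_dtype = np.dtype(dtype or "float32")
    if np.issubdtype(payload_dtype, np.integer):
        raw = np.round(rec.samples / gain_uv_per_bit).astype(payload_dtype)
    else:
        raw = rec.samples.astype(payload_dtype)
    raw.tofile(path)
    sidecar = {
        "fs": float(rec.fs),
        "t0": float(rec.t0),
        "dtype": payload_dtype.name,
        "n_channels": int(rec.samples.shape[0]),
        "gain_uv_per_bit": float(gain_uv_per_bit),
        "channels": [
            {"region": m.region, "kind": m.kind, "depth": m.depth}
            for m in rec.channels
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording container; values are converted to uV via the gain."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "samples" not in f:
                raise FormatError(f"{path}: missing 'samples' dataset")
            ds = f["samples"]
            for key in ("fs", "gain_uv_per_bit"):
                if key not in ds.attrs:
                    raise FormatError(f"{path}: missing attribute {key!r}")
            gain = float(ds.attrs["gain_uv_per_bit"])
            samples = np.asarray(ds)
            if np.issubdtype(samples.dtype, np.integer):
                samples = samples.astype(np.float64) * gain
            elif gain != 1.0:
                samples = samples * gain
            channels = [
                ChannelMeta(r.decode(), k.decode(), int(d))
                for r, k, d in zip(f["region"][()], f["kind"][()],
                                   f["depth"][()])
            ]
            return Recording(samples, float(ds.attrs["fs"]), channels,
                             float(ds.attrs.get("t0", 0.0)))
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("fs", "dtype", "n_channels", "channels"):
        if key not in sidecar:
            raise FormatError(f"{sidecar_path}: missing key {key!r}")
    raw = np.fromfile(path, dtype=np.dtype(sidecar["dtype"]))
    n_ch = int(sidecar["n_channels"])
    if raw.size % n_ch:
        raise IntegrityError(
            f"{path}: payload of {raw.size} values is not divisible by "
            f"n_channels={n_ch}")
    if len(sidecar["channels"]) != n_ch:
        raise IntegrityError(
            f"{sidecar_path}: {len(sidecar['channels'])} channel entries "
            f"for n_channels={n_ch}")
    samples = raw.reshape(n_ch, -1).astype(np.float64)
    gain = float(sidecar.get("gain_uv_per_bit", 1.0))
    if gain != 1.0:
        samples = samples * gain
    channels = [ChannelMeta(c["region"], c.get("kind", "lfp"),
                            int(c.get("depth", 0)))
                for c in sidecar["channels"]]
    return Recording(samples, float(sidecar["fs"]), channels,
                     float(sidecar.get("t0", 0.0)))


def events_to_frame(events: Sequence) -> pd.DataFrame:
    """Serialize a list of BurstEvent objects into the canonical table."""
    rows = []
    for i, ev in enumerate(events):
        rows.append({
            "event_id": getattr(ev, "event_id", i),
            "region": ev.region,
            "onset_s": ev.onset,
            "offset_s": ev.offset,
            "duration_s": ev.duration,
            "mean_rms_uv": ev.mean_rms,
            "max_rms_uv": ev.max_rms,
            "neg_peak_uv": ev.negative_peak,
            "n_peaks": ev.n_peaks,
            "rejection_reason": ev.rejection_reason or "none",
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events, path: str | Path) -> Path:
    """Write an event table as CSV (header always present).

    Accepts either a DataFrame with the canonical columns or a sequence of
    BurstEvent objects. Onset/offset round-trip to well below 1 us.
    """
    path = Path(path)
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if not frame.empty and (frame["onset_s"] >= frame["offset_s"]).any():
        raise ConfigError("event table contains onset >= offset")
    frame.to_csv(path, index=False, float_format="%.9g")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("onset_s", "offset_s") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return frame


def select_channel(rec: Recording, region: str,
                   candidates: Sequence[int] | None = None,
                   override: int | None = None) -> int:
    """Pick the analysis channel for a region.

    Deterministic replacement for by-eye channel selection: among the
    candidate LFP channels of the region, choose the one whose 50-100 Hz
    residual has the smallest median absolute deviation (i.e. the least
    high-frequency noise). An explicit ``override`` index wins.
    """
    from .preprocess import bandpass  # local import to avoid cycle

    if override is not None:
        return int(override)
    if candidates is None:
        candidates = [i for i, m in enumerate(rec.channels)
                      if m.region == region and m.kind == "lfp"]
    if not candidates:
        raise ConfigError(f"no candidate channels for region {region!r}")
    if len(candidates) == 1:
        return int(candidates[0])
    scores = []
    for idx in candidates:
        hf = bandpass(rec.samples[idx], rec.fs, 50.0,
                      min(100.0, rec.fs / 2 * 0.9))
        scores.append(np.median(np.abs(hf - np.median(hf))))
    return int(candidates[int(np.argmin(scores))])
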