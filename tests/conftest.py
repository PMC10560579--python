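import numpy as np
import pytest

from netbursts import pipeline
from netbursts.preprocess import bandpass
from netbursts.synth import SynthConfig, generate_recording, pink_noise, \
    synthesize_burst


@pytest.fixture(scope="session")
def ten_min_run():
    """Seeded 10-minute three-region recording with detection results.

    Session-scoped because generation plus detection is the priciest
    fixture; tests must not mutate it.
    """
    cfg = SynthConfig(duration_s=600.0, seed=1)
    rec, truth = generate_recording(cfg)
    det = pipeline.detect_stage(rec, {})
    return {"cfg": cfg, "rec": rec, "truth": truth, "det": det}


@pytest.fixture(scope="session")
def short_recording():
    """2-minute two-region recording for cheaper end-to-end tests."""
    cfg = SynthConfig(duration_s=120.0, regions=("cortex", "striatum"),
                      seed=4)
    rec, truth = generate_recording(cfg)
    return rec, truth


def make_lagged_pair(rng, lag_ms, band, fs=1000.0, n_s=3.0, gain=0.8):
    """Two band-limited signals sharing a core component; a positive
    ``lag_ms`` makes the second signal lead (its copy of the core occurs
    earlier), matching the analysis sign convention."""
    n = int(n_s * fs)
    pad = 200
    core = bandpass(rng.standard_normal(n + 2 * pad), fs, *band)
    na = bandpass(rng.standard_normal(n + 2 * pad), fs, *band)
    nb = bandpass(rng.standard_normal(n + 2 * pad), fs, *band)
    shift = int(round(lag_ms * fs / 1000.0))
    a = np.sqrt(gain) * core[pad: pad + n] + np.sqrt(1 - gain) * na[pad: pad + n]
    b = (np.sqrt(gain) * core[pad + shift: pad + shift + n]
         + np.sqrt(1 - gain) * nb[pad: pad + n])
    return a, b


def make_burst_pairs(rng, n_pairs, fs=1000.0, dur=1.5):
    """Mutually independent burst-like signals for null-calibration tests."""
    sa, sb = [], []
    for _ in range(n_pairs):
        for lst in (sa, sb):
            w = synthesize_burst("SB", dur, fs, carrier_hz=10.0,
                                 amplitude=50.0, rng=rng)
            lst.append(w + pink_noise(len(w), fs, 1.0, 10.0, rng))
    return sa, sb
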