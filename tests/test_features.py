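"""Burst features, PCA embedding, fuzzy c-means and SB/NGB labeling."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from netbursts.detection import BurstEvent
from netbursts.exceptions import ConfigError
from netbursts.features import (FuzzyClustering,
                                assign_labels, compute_features,
                                fuzzy_cmeans, normalize_and_embed,
                                select_k_by_fpc)
from netbursts.spectra import multitaper_psd

FS = 1000.0


@pytest.fixture(scope="module")
def tone_features():
    """Stationary 10 Hz, 2 s, amplitude 40 uV event with known features."""
    rng = np.random.default_rng(0)
    t = np.arange(0, 4, 1 / FS)
    lfp = 40.0 * np.sin(2 * np.pi * 10 * t)
    baseline = multitaper_psd(rng.standard_normal(int(4 * FS)) * 5.0, FS)
    ev = BurstEvent("cortex", 1.0, 3.0, 0, 0, 0, 0, event_id=0)
    spikes = np.linspace(1.05, 2.95, 10)
    return compute_features(ev, lfp, FS, spikes, baseline)


class TestComputeFeatures:
    def test_tone_closed_forms(self, tone_features):
        f = tone_features
        assert f["duration_s"] == 2.0
        assert abs(f["iti_s"] - 0.1) < 0.002
        assert f["flatness"] == pytest.approx(1.0, abs=0.01)
        assert f["negative_peak_uv"] == pytest.approx(-40.0, rel=0.01)
        assert f["max_rms_uv"] == pytest.approx(40.0 / np.sqrt(2), rel=0.01)
        assert f["spike_rate_hz"] == 5.0

    def test_tone_band_power_concentrated_in_theta_alpha(self, tone_features):
        assert tone_features["rel_theta_alpha"] > 0.9
        assert tone_features["rel_beta_low_gamma"] < 0.05

    def test_degenerate_iti_flagged(self):
        # a monotonic ramp has no interior troughs at all
        rng = np.random.default_rng(1)
        lfp = np.linspace(-10.0, 10.0, int(2 * FS))
        baseline = multitaper_psd(rng.standard_normal(int(2 * FS)), FS)
        ev = BurstEvent("cortex", 0.0, 0.4, 0, 0, 0, 0)
        f = compute_features(ev, lfp, FS, np.array([]), baseline)
        assert f["iti_degenerate"] == 1.0
        assert f["iti_s"] == pytest.approx(ev.duration)


class TestEmbed:
    def test_uncorrelated_standardized_inputs(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((300, 3))
        scores, evr = normalize_and_embed(x, n_components=3)
        # eigen-decomposition oracle on the correlation matrix
        eigvals = np.linalg.eigvalsh(np.corrcoef(x.T))[::-1]
        np.testing.assert_allclose(evr, eigvals / eigvals.sum(), atol=0.02)
        # scores reproduce a rotation: variances match eigenvalues
        np.testing.assert_allclose(np.var(scores, axis=0), sorted(
            np.var(scores, axis=0), reverse=True))

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((40, 5))
        dup = np.repeat(x, 2, axis=0)
        scores, _ = normalize_and_embed(dup, n_components=3)
        np.testing.assert_allclose(scores[::2], scores[1::2], atol=1e-10)

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((50, 4))
        x[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            scores, _ = normalize_and_embed(x, n_components=3)
        assert scores.shape == (50, 3)

    def test_too_few_events_rejected(self):
        with pytest.raises(ConfigError):
            normalize_and_embed(np.zeros((2, 5)), n_components=3)


def _two_clouds(rng, n=100, sep=10.0, d=3):
    a = rng.standard_normal((n, d))
    b = rng.standard_normal((n, d))
    b[:, 0] += sep
    return np.vstack([a, b])


class TestFuzzyCMeans:
    def test_separated_clouds_crisp(self):
        rng = np.random.default_rng(5)
        x = _two_clouds(rng)
        res = fuzzy_cmeans(x, 2, seed=0)
        # nearly all points crisply assigned; rare 3-SD outliers of a unit
        # cloud keep residual membership in the far cluster under m = 2
        top = res.memberships.max(axis=1)
        assert np.median(top) > 0.95
        assert (top > 0.9).mean() > 0.95
        assert res.fpc > 0.9
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_matches_reference_e1071_cmeans(self, tmp_path):
        """Independent oracle: R e1071::cmeans on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(6)
        x = _two_clouds(rng, n=60, sep=8.0, d=2)
        csv = tmp_path / "x.csv"
        np.savetxt(csv, x, delimiter=",")
        script = tmp_path / "cm.R"
        script.write_text(
            'x <- as.matrix(read.csv("%s", header=FALSE))\n'
            "set.seed(1)\n"
            "r <- e1071::cmeans(x, 2, m=2, iter.max=300)\n"
            "cat(sort(r$centers[,1]), fill=TRUE)\n"
            'cat(mean(rowSums(r$membership^2)), fill=TRUE)\n' % csv)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        lines = out.stdout.strip().splitlines()
        ref_centers = np.array([float(v) for v in lines[0].split()])
        ref_fpc = float(lines[1])
        mine = fuzzy_cmeans(x, 2, seed=0)
        np.testing.assert_allclose(sorted(mine.centers[:, 0]), ref_centers,
                                   atol=0.05)
        assert abs(mine.fpc - ref_fpc) < 0.01

    def test_equidistant_point_half_membership(self):
        x = np.array([[-1.0], [-1.0], [1.0], [1.0], [0.0]])
        res = fuzzy_cmeans(x, 2, seed=0)
        np.testing.assert_allclose(res.memberships[-1], [0.5, 0.5],
                                   atol=1e-3)

    def test_k1_trivial(self):
        res = fuzzy_cmeans(np.random.default_rng(7).standard_normal((20, 2)),
                           1)
        assert res.fpc == 1.0
        assert np.all(res.memberships == 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            fuzzy_cmeans(np.empty((0, 2)), 2)

    def test_fpc_within_bounds(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((80, 3))
        for k in (2, 3, 4):
            res = fuzzy_cmeans(x, k, seed=0)
            assert 1.0 / k - 1e-9 <= res.fpc <= 1.0 + 1e-9


class TestSelectK:
    def test_two_clouds_pick_two(self):
        rng = np.random.default_rng(9)
        best, curve = select_k_by_fpc(_two_clouds(rng), range(2, 6), seed=0)
        assert best == 2

    def test_three_clouds_pick_three(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((60, 2))
        b = rng.standard_normal((60, 2)) + [12, 0]
        c = rng.standard_normal((60, 2)) + [0, 12]
        best, _ = select_k_by_fpc(np.vstack([a, b, c]), range(2, 6), seed=0)
        assert best == 3

    def test_single_cloud_warns_and_returns_two(self):
        rng = np.random.default_rng(11)
        with pytest.warns(UserWarning, match="single cluster"):
            best, curve = select_k_by_fpc(rng.standard_normal((100, 3)),
                                          range(2, 6), seed=0)
        assert best == 2
        ks = sorted(curve)
        assert all(curve[a] >= curve[b] for a, b in zip(ks, ks[1:]))

    def test_k1_excluded(self):
        with pytest.raises(ConfigError):
            select_k_by_fpc(np.zeros((10, 2)), range(1, 4))


class TestAssignLabels:
    def _clustering(self, memberships):
        u = np.asarray(memberships, dtype=float)
        return FuzzyClustering(u, np.zeros((2, 3)), 0.8, 2, 2.0, 0.0)

    def _features(self, rel_bg):
        return pd.DataFrame({
            "rel_beta_low_gamma": rel_bg,
            "duration_s": np.ones(len(rel_bg)),
        })

    def test_uc_rule_strict_at_threshold(self):
        u = [[0.55, 0.45], [0.61, 0.39], [0.60, 0.40], [0.2, 0.8]]
        feats = self._features([0.5, 0.5, 0.5, 0.1])
        labels = assign_labels(self._clustering(u), feats)
        assert labels[0] == "UC"          # 0.55 does not exceed 0.6? it is
        # below threshold -> UC; 0.61 exceeds strictly -> classified
        assert labels[1] != "UC"
        assert labels[2] == "UC"          # exactly 0.6 stays unclassified
        assert labels[3] != "UC"

    def test_high_beta_cluster_is_ngb(self):
        u = [[0.9, 0.1], [0.9, 0.1], [0.1, 0.9], [0.1, 0.9]]
        feats = self._features([0.1, 0.1, 0.6, 0.6])
        labels = assign_labels(self._clustering(u), feats)
        assert list(labels) == ["SB", "SB", "NGB", "NGB"]

    def test_requires_two_clusters(self):
        u = np.ones((3, 1))
        clustering = FuzzyClustering(u, np.zeros((1, 3)), 1.0, 1, 2.0, 0.0)
        with pytest.raises(ConfigError):
            assign_labels(clustering, self._features([0.1, 0.2, 0.3]))
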