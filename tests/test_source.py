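"""Beamforming, voxel selection, DBSCAN clustering, signal extraction."""

import numpy as np
import pytest

from gatingnet.containers import EpochArray
from gatingnet.source import (
    apply_filter,
    bandpass_fir,
    dbscan_cluster,
    extract_cluster_signals,
    lcmv_common_filter,
    select_top_voxels,
    source_gating_contrast,
)
from gatingnet.synthetic import gen_sensor_epochs, make_leadfield


def _tone_epochs(freq, sf=256.0, n_times=1025, amp=1.0):
    times = -2.0 + np.arange(n_times) / sf
    data = amp * np.sin(2 * np.pi * freq * times)[None, None, :] * np.ones((2, 2, 1))
    return EpochArray(data, times, sf, ["a", "b"])


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        ep = bandpass_fir(_tone_epochs(20.0), "beta")
        mid = slice(300, 700)
        ratio = ep.data[0, 0, mid].std() / _tone_epochs(20.0).data[0, 0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuated(self):
        ep = bandpass_fir(_tone_epochs(5.0), "beta")
        mid = slice(300, 700)
        ratio = ep.data[0, 0, mid].std() / _tone_epochs(5.0).data[0, 0, mid].std()
        assert 20 * np.log10(max(ratio, 1e-12)) < -40.0

    def test_band_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(_tone_epochs(10.0), (100.0, 130.0))


class TestLCMV:
    def test_unit_gain_identity(self):
        lf = make_leadfield(64, 25, seed=0)
        rng = np.random.default_rng(0)
        ep = EpochArray(
            rng.standard_normal((10, 25, 200)),
            np.arange(200) / 256.0,
            256.0,
            lf.channel_names,
        )
        filt = lcmv_common_filter(ep, lf, reg=0.05)
        gains = np.einsum("vc,vc->v", filt.weights, lf.gain)
        assert np.max(np.abs(gains - 1.0)) < 1e-10

    def test_single_source_peak_at_true_voxel(self):
        lf = make_leadfield(64, 25, seed=1)
        rng = np.random.default_rng(1)
        v = 37
        src = 30.0 * rng.standard_normal((20, 1, 1025))
        sw = gen_sensor_epochs(src, lf, [v], sensor_noise_sd=1.0, seed=2)
        ns = gen_sensor_epochs(np.zeros_like(src), lf, [v], sensor_noise_sd=1.0, seed=3)
        filt = lcmv_common_filter([sw, ns], lf)
        eff = source_gating_contrast(apply_filter(filt, sw), apply_filter(filt, ns))
        assert np.argmax(np.abs(eff)) == v

    def test_span_of_one_column_reconstructs_source(self):
        lf = make_leadfield(27, 12, seed=2)
        rng = np.random.default_rng(2)
        v = 13
        s = rng.standard_normal((1, 1, 1025))
        ep = gen_sensor_epochs(s, lf, [v], sensor_noise_sd=1e-6, seed=0)
        filt = lcmv_common_filter(ep, lf, reg=1e-8)
        rec = apply_filter(filt, ep)[0, v]
        assert np.corrcoef(rec, s[0, 0])[0, 1] > 0.99


class TestVoxelSelection:
    def test_ceil_of_one_percent(self):
        eff = np.arange(64.0)
        assert select_top_voxels(eff, pct=1.0).size == 1

    def test_monotone_map_selects_argmax(self):
        eff = np.linspace(-1, 2, 100)
        assert 99 in select_top_voxels(eff, pct=1.0)

    def test_absolute_value_and_tie_break_by_index(self):
        eff = np.array([0.5, -0.9, 0.9, 0.1])
        assert list(select_top_voxels(eff, pct=50.0)) == [1, 2]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        eff = rng.standard_normal(50)
        perm = rng.permutation(50)
        sel = set(select_top_voxels(eff, pct=10.0))
        sel_p = set(select_top_voxels(eff[perm], pct=10.0))
        assert {perm[i] for i in sel_p} == sel


def _brute_dbscan(pos, eps, min_pts):
    """Reference DBSCAN by direct definition (density-reachable expansion)."""
    n = len(pos)
    d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [i for i in range(n) if len(neighbors[i]) >= min_pts]
    labels = -np.ones(n, dtype=int)
    cid = 0
    for i in core:
        if labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if len(neighbors[j]) >= min_pts:
                for k in neighbors[j]:
                    if labels[k] == -1:
                        labels[k] = cid
                        stack.append(k)
        cid += 1
    return labels


class TestDBSCAN:
    def test_two_separated_groups(self):
        pos = np.vstack([np.zeros((3, 3)), 10.0 + np.zeros((3, 3))])
        pos += 0.1 * np.arange(6)[:, None]
        cls = dbscan_cluster(pos, eps=1.5)
        assert len(cls) == 2
        assert all(len(c.voxels) >= 2 for c in cls)

    def test_singleton_is_noise(self):
        pos = np.array([[0, 0, 0], [0.5, 0, 0], [50, 50, 50]], dtype=float)
        cls = dbscan_cluster(pos, eps=1.5)
        assert len(cls) == 1
        assert 2 not in {v for c in cls for v in c.voxels}

    def test_equivalence_with_direct_definition(self):
        rng = np.random.default_rng(5)
        for rep in range(50):
            pos = rng.uniform(0, 5, size=(rng.integers(5, 25), 3))
            eps = rng.uniform(0.5, 2.0)
            ours = dbscan_cluster(pos, eps=eps, min_pts=2)
            ref = _brute_dbscan(pos, eps, 2)
            ours_sets = sorted(sorted(c.voxels) for c in ours)
            ref_sets = sorted(
                sorted(np.flatnonzero(ref == c)) for c in set(ref) if c != -1
            )
            assert ours_sets == ref_sets

    def test_input_order_invariance(self):
        rng = np.random.default_rng(6)
        pos = rng.uniform(0, 4, size=(20, 3))
        perm = rng.permutation(20)
        a = dbscan_cluster(pos, eps=1.2, voxel_indices=np.arange(20))
        b = dbscan_cluster(pos[perm], eps=1.2, voxel_indices=perm)
        assert sorted(sorted(c.voxels) for c in a) == sorted(sorted(c.voxels) for c in b)


class TestExtractSignals:
    def test_switch_equal_to_baseline_gives_zero(self):
        sf = 256.0
        times = -2.0 + np.arange(1025) / sf
        base = np.random.default_rng(7).standard_normal((4, 1025))
        ts = np.tile(base, (5, 1, 1))
        pos = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        cls = dbscan_cluster(pos, eps=1.5)
        sigs = extract_cluster_signals(ts, cls, base, times)
        assert np.allclose(sigs[0].data, 0.0)

    def test_crop_yields_512_samples(self):
        sf = 256.0
        times = -2.0 + np.arange(1025) / sf
        ts = np.zeros((2, 2, 1025))
        base = np.zeros((2, 1025))
        cls = dbscan_cluster(np.array([[0.0, 0, 0], [1.0, 0, 0]]), eps=1.5)
        sigs = extract_cluster_signals(ts, cls, base, times)
        assert sigs[0].data.shape == (2, 512)
        assert sigs[0].times_s[0] == pytest.approx(-0.5)
        assert sigs[0].times_s[-1] < 1.5

    def test_baseline_algebra_by_hand(self):
        times = np.array([-0.5, 0.0, 0.5])
        ts = np.array([[[3.0, 5.0, 7.0]]])  # one trial, one voxel
        base = np.array([[1.0, 2.0, 3.0]])
        cls = dbscan_cluster(np.zeros((2, 3)), eps=1.0)  # both dummy voxels
        sigs = extract_cluster_signals(
            ts.repeat(2, axis=1), cls, base.repeat(2, axis=0), times, window=(-1, 1)
        )
        assert np.allclose(sigs[0].data, [[2.0, 3.0, 4.0]])

    def test_unknown_voxel_rejected(self):
        times = np.linspace(-0.5, 1.0, 10)
        pos = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        cls = dbscan_cluster(pos, eps=1.5)
        with pytest.raises(IndexError):
            extract_cluster_signals(np.zeros((1, 3, 10)), cls, np.zeros((3, 10)), times)
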