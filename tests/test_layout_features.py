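"""Filtering, windowing, differential entropy, maps, and graphs."""

import numpy as np
import pytest

from eegdann.layout_features import (
    BandScheme,
    DEFeatureMatrix,
    ElectrodeLayout,
    DegenerateSignalError,
    InvalidBandError,
    LayoutCollisionError,
    MissingChannelError,
    RawRecording,
    TooShortError,
    bandpass_filter,
    build_activity_map,
    build_adjacency,
    build_topology_graph,
    compute_de_features,
    differential_entropy,
    recover_features,
    segment_windows,
)

GAUSS_DE_UNIT = 0.5 * np.log(2 * np.pi * np.e)  # DE of sigma^2 = 1


def band_power(x, fs, lo, hi):
    """FFT band power oracle."""
    f = np.fft.rfftfreq(x.size, 1 / fs)
    p = np.abs(np.fft.rfft(x)) ** 2
    return p[(f >= lo) & (f <= hi)].sum()


def make_rec(samples, fs=200.0, names=None):
    n_ch = samples.shape[0]
    names = names or [f"CH{i}" for i in range(n_ch)]
    return RawRecording(samples, fs, names)


class TestBandScheme:
    def test_default_bands(self):
        s = BandScheme()
        assert s.names == ["delta", "theta", "alpha", "beta", "gamma"]
        assert s.bands[0][1:] == (1.0, 4.0) and s.bands[4][1:] == (31.0, 50.0)

    def test_rejects_overlap_and_inversion(self):
        with pytest.raises(InvalidBandError):
            BandScheme((("a", 1, 5), ("b", 4, 8), ("c", 8, 14), ("d", 14, 31), ("e", 31, 50)))
        with pytest.raises(InvalidBandError):
            BandScheme((("a", 4, 1), ("b", 4, 8), ("c", 8, 14), ("d", 14, 31), ("e", 31, 50)))


class TestBandpass:
    def test_dc_is_removed(self):
        rec = make_rec(np.full((2, 2000), 7.0))
        out = bandpass_filter(rec, 8, 14)
        assert np.abs(out.samples).max() < 1e-6

    def test_tone_in_band_retained_out_of_band_rejected(self):
        t = np.arange(4000) / 200.0
        tone = np.sin(2 * np.pi * 10 * t)[None, :]
        rec = make_rec(tone)
        in_band = bandpass_filter(rec, 8, 14).samples[0]
        out_band = bandpass_filter(rec, 1, 4).samples[0]
        p0 = band_power(tone[0], 200, 0, 100)
        assert band_power(in_band, 200, 0, 100) >= 0.95 * p0
        assert band_power(out_band, 200, 0, 100) <= 0.01 * p0

    def test_white_noise_power_partition(self):
        # Periodogram/Parseval oracle: the five filtered band powers sum to
        # the 1-50 Hz power of the input. Forward-backward filtering squares
        # the -3 dB edge response, so the recovered fraction depends on the
        # filter order: a sharp order-10 design is within 5%; the default
        # order-5 design loses a further ~3% to edge attenuation.
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 40000))
        rec = make_rec(x)
        total = band_power(x[0], 200, 1, 50)

        def recovered(order):
            return sum(
                band_power(bandpass_filter(rec, lo, hi, order=order).samples[0],
                           200, 0, 100)
                for _, lo, hi in BandScheme().bands
            ) / total

        assert abs(recovered(10) - 1.0) < 0.05
        assert recovered(5) > 0.85

    def test_invalid_band_and_too_short(self):
        rec = make_rec(np.random.default_rng(1).standard_normal((1, 2000)))
        with pytest.raises(InvalidBandError):
            bandpass_filter(rec, 8, 120)  # above Nyquist
        with pytest.raises(TooShortError):
            bandpass_filter(make_rec(np.zeros((1, 10)) + np.arange(10.0)), 8, 14)


class TestSegmentation:
    @pytest.mark.parametrize("n,expected", [(1800, 2), (800, 1), (1600, 2)])
    def test_window_counts(self, n, expected):
        rec = make_rec(np.random.default_rng(2).standard_normal((62, n)))
        wins = segment_windows(rec, 4.0)
        assert len(wins) == expected
        assert all(w.n_samples == 800 for w in wins)
        assert [w.window_index for w in wins] == list(range(expected))

    def test_below_one_window_errors(self):
        rec = make_rec(np.random.default_rng(3).standard_normal((62, 799)))
        with pytest.raises(TooShortError):
            segment_windows(rec, 4.0)


class TestDifferentialEntropy:
    def test_closed_form_values(self):
        rng = np.random.default_rng(4)
        # exactly unit / fourfold variance via standardisation
        z = rng.standard_normal(800)
        z = (z - z.mean()) / z.std()
        assert differential_entropy(z) == pytest.approx(GAUSS_DE_UNIT, abs=1e-12)
        assert differential_entropy(2 * z) == pytest.approx(
            GAUSS_DE_UNIT + 0.5 * np.log(4), abs=1e-12
        )

    def test_monte_carlo_gaussian_calibration(self):
        # The estimator is 0.5*ln(s^2) + const with sd ~ 0.5*sqrt(2/n) =
        # 0.025 nats at n=800, so 0.05 nats is a 2-sigma band (~95% per
        # window) and 0.08 nats is ~3.2 sigma. Check both failure rates and
        # that the estimator is unbiased to well within the band.
        errs = np.array([
            differential_entropy(np.random.default_rng(seed).standard_normal(800))
            - GAUSS_DE_UNIT
            for seed in range(100)
        ])
        assert (np.abs(errs) >= 0.05).sum() <= 10  # binomial bound at p=0.046
        assert (np.abs(errs) >= 0.08).sum() <= 1
        assert abs(errs.mean()) < 0.01

    def test_degenerate_and_short_signals(self):
        with pytest.raises(DegenerateSignalError):
            differential_entropy(np.ones(100))
        with pytest.raises(TooShortError):
            differential_entropy(np.array([1.0]))


class TestComputeDeFeatures:
    def test_exchangeable_channels_and_amplified_channel(self, layout, scheme):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((62, 8000))
        x[5] *= 2.0  # one channel amplified
        rec = RawRecording(x, 200.0, list(layout.names))
        feats = compute_de_features(rec, scheme, layout)
        de = np.mean([f.values for f in feats], axis=0)
        others = np.delete(de, 5, axis=0)
        # exchangeability: unamplified channels agree per band
        assert (others.max(axis=0) - others.min(axis=0)).max() < 0.25
        # amplification by 2 raises DE by ln 2 in every band
        np.testing.assert_allclose(
            de[5] - others.mean(axis=0), np.log(2), atol=0.1
        )

    def test_single_window_count_and_row_order(self, layout, scheme):
        rng = np.random.default_rng(6)
        names = list(layout.names)[::-1]  # scrambled order
        rec = RawRecording(rng.standard_normal((62, 800)), 200.0, names)
        feats = compute_de_features(rec, scheme, layout)
        assert len(feats) == 1
        assert feats[0].values.shape == (62, 5)

    def test_missing_channel_reported(self, layout, scheme):
        rng = np.random.default_rng(7)
        names = list(layout.names)[:-1] + ["NOT_A_CHANNEL"]
        rec = RawRecording(rng.standard_normal((62, 800)), 200.0, names)
        with pytest.raises(MissingChannelError, match="CB2"):
            compute_de_features(rec, scheme, layout)


class TestActivityMap:
    def test_zero_features_zero_map(self, layout):
        f = DEFeatureMatrix(np.zeros((62, 5)), 0)
        assert build_activity_map(f, layout).tensor.sum() == 0

    def test_single_entry_lands_on_grid_cell(self, layout):
        vals = np.zeros((62, 5))
        e = layout.index_of("FP1")
        vals[e, 2] = 2.0  # alpha plane
        amap = build_activity_map(DEFeatureMatrix(vals, 0), layout)
        r, c = layout.grid_coords[e]
        assert amap.tensor[r, c, 2] == 2.0
        assert np.count_nonzero(amap.tensor) == 1

    def test_round_trip_and_conservation(self, layout):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((62, 5))
        amap = build_activity_map(DEFeatureMatrix(vals, 0), layout)
        np.testing.assert_array_equal(recover_features(amap), vals)
        assert amap.tensor.sum() == pytest.approx(vals.sum(), rel=1e-12)

    def test_layout_collision_detected(self):
        with pytest.raises(LayoutCollisionError):
            ElectrodeLayout(
                names=("A", "B"), grid_coords=((0, 0), (0, 0)),
                planar_xy=((0, 0), (0.1, 0)), height=9, width=9,
            )


class TestAdjacency:
    def test_full_rule(self, layout):
        assert (build_adjacency(layout, "full") == 1).all()

    def test_knn_zero_is_identity(self, layout):
        np.testing.assert_array_equal(
            build_adjacency(layout, "knn", 0), np.eye(62)
        )

    def test_knn4_against_brute_force_ranking(self, layout):
        adj = build_adjacency(layout, "knn", 4)
        xy = np.asarray(layout.planar_xy)
        np.testing.assert_array_equal(adj, adj.T)
        assert (np.diag(adj) == 1).all()
        assert (adj.sum(axis=1) >= 5).all()  # self + >=4 after symmetrization
        # brute-force: every electrode's 4 nearest must be connected
        for i in range(62):
            d = np.linalg.norm(xy - xy[i], axis=1)
            nearest = [j for j in np.argsort(d, kind="stable") if j != i][:4]
            assert all(adj[i, j] == 1 for j in nearest)

    def test_invalid_parameters(self, layout):
        with pytest.raises(ValueError):
            build_adjacency(layout, "radius", 0)
        with pytest.raises(ValueError):
            build_adjacency(layout, "knn", -1)
        with pytest.raises(ValueError):
            build_adjacency(layout, "voronoi", 1)


class TestTopologyGraph:
    def test_node_features_bitwise_and_symmetry(self, layout, adjacency):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((62, 5))
        g = build_topology_graph(DEFeatureMatrix(vals, 0), layout, adjacency)
        np.testing.assert_array_equal(g.node_features, vals)
        np.testing.assert_array_equal(g.adjacency, g.adjacency.T)

    def test_neighborhoods_match_edge_list(self, layout, adjacency):
        g = build_topology_graph(
            DEFeatureMatrix(np.zeros((62, 5)), 0), layout, adjacency
        )
        edges = {(i, j) for i in range(62) for j in range(62) if adjacency[i, j] > 0}
        for i in range(62):
            assert set(g.neighbors(i)) == {j for (a, j) in edges if a == i}
            assert i in g.neighbors(i)  # self-loop

    def test_shape_mismatch_rejected(self, layout):
        with pytest.raises(ValueError):
            build_topology_graph(
                DEFeatureMatrix(np.zeros((62, 5)), 0), layout, np.eye(10)
            )
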