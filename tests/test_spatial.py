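import numpy as np
import pytest

from nscpatterns.spatial import (
    LabeledPattern,
    analyze_pattern,
    classify_pattern,
    ripley_spatial,
    ripley_spatiotemporal,
    sampling_envelope,
    standardize_k,
)
from nscpatterns.synthetic import generate_pattern

from conftest import grid_index


def brute_k_spatial(coords2d, events, area, radii):
    """Independent double-loop evaluation of the discrete spatial K (w = 1)."""
    s = len(events)
    out = np.zeros(len(radii))
    for b, r in enumerate(radii):
        total = 0
        for i in events:
            for j in events:
                if i == j:
                    continue
                if np.linalg.norm(coords2d[i] - coords2d[j]) <= r:
                    total += 1
        out[b] = (area / s) * total / s
    return out


def brute_k_st(coords2d, s1, s2, area, radii):
    """Independent double-loop spatiotemporal K (w = 1, j = i allowed)."""
    out = np.zeros(len(radii))
    for b, r in enumerate(radii):
        total = 0
        for i in s1:
            for j in s2:
                if np.linalg.norm(coords2d[i] - coords2d[j]) <= r:
                    total += 1
        out[b] = (area / len(s1)) * total / len(s2)
    return out


class TestRipleySpatial:
    def test_hand_enumeration_on_grid(self, grid3):
        h, d, coords = grid3
        events = [grid_index(coords, 0, 0), grid_index(coords, 10, 0)]
        k = ripley_spatial(LabeledPattern(h, events), d, [5.0, 15.0], edge_mode="none")
        assert k[0] == pytest.approx(0.0)
        assert k[1] == pytest.approx(200.0)

    def test_single_event_gives_zero(self, grid3):
        h, d, _ = grid3
        k = ripley_spatial(LabeledPattern(h, [4]), d, [10.0, 50.0], edge_mode="none")
        assert np.allclose(k, 0.0)

    def test_no_events_rejected(self, grid3):
        h, d, _ = grid3
        with pytest.raises(ValueError, match="no events"):
            ripley_spatial(LabeledPattern(h, []), d, [10.0])

    def test_monotone_without_edge_correction(self, disc1200):
        h, d = disc1200
        rng = np.random.default_rng(1)
        ev = rng.choice(h.n_cells, 25, replace=False)
        k = ripley_spatial(LabeledPattern(h, ev), d, np.arange(10.0, 200.0, 10.0), edge_mode="none")
        assert (np.diff(k) >= -1e-9).all()

    def test_matches_bruteforce_on_random_configs(self, disc1200):
        h, d = disc1200
        radii = np.arange(10.0, 160.0, 25.0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ev = rng.choice(h.n_cells, rng.integers(2, 30), replace=False)
            k = ripley_spatial(LabeledPattern(h, ev), d, radii, edge_mode="none")
            kb = brute_k_spatial(h.coords[:, :2], ev, h.area, radii)
            assert np.allclose(k, kb)

    def test_edge_correction_never_increases_k(self, disc1200):
        h, d = disc1200
        rng = np.random.default_rng(2)
        ev = rng.choice(h.n_cells, 30, replace=False)
        radii = np.arange(20.0, 200.0, 20.0)
        pat = LabeledPattern(h, ev)
        k_w = ripley_spatial(pat, d, radii, edge_mode="fraction")
        k_0 = ripley_spatial(pat, d, radii, edge_mode="none")
        assert (k_w <= k_0 + 1e-9).all()


class TestRipleySpatiotemporal:
    def test_hand_enumeration_on_grid(self, grid3):
        h, d, coords = grid3
        s1 = [grid_index(coords, 0, 0)]
        s2 = [grid_index(coords, 10, 0), grid_index(coords, 20, 20)]
        k = ripley_spatiotemporal(LabeledPattern(h, s1, s2), d, [15.0], edge_mode="none")
        assert k[0] == pytest.approx(200.0)

    def test_matches_bruteforce_including_shared_cells(self, disc1200):
        h, d = disc1200
        radii = np.arange(10.0, 160.0, 25.0)
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            s1 = rng.choice(h.n_cells, rng.integers(2, 25), replace=False)
            s2 = rng.choice(h.n_cells, rng.integers(2, 25), replace=False)
            pat = LabeledPattern(h, s1, np.setdiff1d(s2, []))
            k = ripley_spatiotemporal(pat, d, radii, edge_mode="none")
            kb = brute_k_st(h.coords[:, :2], s1, s2, h.area, radii)
            assert np.allclose(k, kb)

    def test_empty_sets_rejected(self, grid3):
        h, d, _ = grid3
        with pytest.raises(ValueError):
            ripley_spatiotemporal(LabeledPattern(h, [], [1]), d, [10.0])

    def test_clustered_s2_exceeds_envelope(self, disc1200):
        h, d = disc1200
        center = int(np.argmin((h.coords[:, :2] ** 2).sum(axis=1)))
        s1 = np.array([center])
        near = np.argsort(d.entries[center])[1:15]
        pat = LabeledPattern(h, s1, near)
        radii = np.array([60.0])
        k = ripley_spatiotemporal(pat, d, radii)
        _, q95 = sampling_envelope(pat, d, radii, seed=0)
        assert k[0] > q95[0]


class TestEnvelope:
    def test_degenerate_all_cells_are_events(self, grid3):
        h, d, _ = grid3
        pat = LabeledPattern(h, np.arange(9))
        radii = np.array([15.0, 25.0])
        q05, q95 = sampling_envelope(pat, d, radii, mode="spatial", seed=0)
        k = ripley_spatial(pat, d, radii)
        assert np.allclose(q05, k)
        assert np.allclose(q95, k)

    def test_fixed_seed_reproducible(self, disc1200):
        h, d = disc1200
        rng = np.random.default_rng(3)
        pat = LabeledPattern(h, rng.choice(h.n_cells, 20, replace=False))
        radii = np.arange(20.0, 120.0, 20.0)
        env1 = sampling_envelope(pat, d, radii, mode="spatial", seed=42)
        env2 = sampling_envelope(pat, d, radii, mode="spatial", seed=42)
        assert np.array_equal(env1[0], env2[0]) and np.array_equal(env1[1], env2[1])

    def test_observed_k_of_random_pattern_mostly_inside(self, disc1200):
        h, d = disc1200
        rng = np.random.default_rng(4)
        radii = np.arange(20.0, 160.0, 20.0)
        inside = 0
        trials = 0
        for _ in range(10):
            ev = rng.choice(h.n_cells, 25, replace=False)
            pat = LabeledPattern(h, ev)
            k = ripley_spatial(pat, d, radii)
            q05, q95 = sampling_envelope(
                pat, d, radii, mode="spatial", seed=int(rng.integers(2**31))
            )
            inside += int(((k >= q05) & (k <= q95)).sum())
            trials += len(radii)
        assert inside / trials > 0.75  # ~90% expected for a 5-95% band


class TestStandardizeAndClassify:
    def test_envelope_endpoints_map_to_unit_scores(self):
        q05 = np.array([1.0, 2.0])
        q95 = np.array([3.0, 6.0])
        assert np.allclose(standardize_k(q95, q05, q95), [1.0, 1.0])
        assert np.allclose(standardize_k(q05, q05, q95), [-1.0, -1.0])
        mid = (q05 + q95) / 2
        assert np.allclose(standardize_k(mid, q05, q95), [0.0, 0.0])

    def test_degenerate_envelope_maps_to_zero(self):
        z = standardize_k(np.array([5.0]), np.array([5.0]), np.array([5.0]))
        assert z[0] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            standardize_k(np.zeros(3), np.zeros(2), np.zeros(2))

    @pytest.mark.parametrize(
        "z,expected",
        [(0.0, "random"), (1.2, "aggregated"), (-1.5, "dispersed")],
    )
    def test_threshold_rules(self, z, expected):
        radii = np.arange(10.0, 310.0, 10.0)
        assert classify_pattern(np.full(len(radii), z), radii) == expected

    def test_window_must_intersect_grid(self):
        with pytest.raises(ValueError):
            classify_pattern(np.zeros(2), np.array([200.0, 250.0]))

    def test_mean_uses_window_radii_only(self):
        radii = np.array([20.0, 30.0, 150.0, 160.0])
        z = np.array([-99.0, 1.5, 1.5, -99.0])  # outside-window values ignored
        assert classify_pattern(z, radii) == "aggregated"


def test_full_chain_on_null_pattern_is_usually_random(disc1200):
    """End-to-end: uniform resamples classify random in >= 80% of seeds."""
    h, d = disc1200
    labels = []
    for seed in range(25):
        pat = generate_pattern(h, d, n1=20, n2=20, g=1.0, r=100.0, seed=seed)
        curve = analyze_pattern(pat, d, mode="spatiotemporal", seed=seed)
        labels.append(curve.classification)
    assert labels.count("random") >= 20
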