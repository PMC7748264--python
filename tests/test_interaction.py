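import numpy as np
import pytest

from nscpatterns.geometry import build_hemisphere, distance_matrix
from nscpatterns.interaction import (
    InteractionDataset,
    InteractionParams,
    fit_interaction,
    interaction_loglik,
    strength_significance,
)
from nscpatterns.synthetic import generate_pattern


def enumeration_loglik(coords2d, s1, s2, g, r):
    """Independent oracle: explicit categorical weight table per Time-2 event."""
    n = len(coords2d)
    candidates = [k for k in range(n) if k not in set(s1)]
    weights = {}
    for k in candidates:
        dmin = min(np.linalg.norm(coords2d[k] - coords2d[i]) for i in s1)
        weights[k] = g if dmin <= r else 1.0
    z = sum(weights.values())
    return sum(np.log(weights[j] / z) for j in s2)


@pytest.fixture(scope="module")
def small_cloud():
    rng = np.random.default_rng(0)
    coords = np.column_stack([rng.uniform(0, 100, 10), rng.uniform(0, 100, 10), np.zeros(10)])
    h = build_hemisphere(coords)
    return h, distance_matrix(h)


class TestLoglik:
    def test_worked_example_three_inside_candidates(self, small_cloud):
        h, d = small_cloud
        s1 = [0]
        dmin = d.entries[0].copy()
        dmin[0] = np.inf
        r = float(np.sort(dmin)[2]) + 1e-9  # exactly 3 of 9 candidates inside
        inside = int(np.argsort(dmin)[0])
        ll = interaction_loglik(h, s1, [inside], InteractionParams(2.0, r), d)
        assert ll == pytest.approx(np.log(2.0 / 12.0))
        # g = 1: uniform choice among the 9 candidates, r-independent
        for rr in (5.0, r, 200.0):
            ll1 = interaction_loglik(h, s1, [inside], InteractionParams(1.0, rr), d)
            assert ll1 == pytest.approx(np.log(1.0 / 9.0))
        # g -> infinity concentrates on the 3 inside candidates
        ll_inf = interaction_loglik(h, s1, [inside], InteractionParams(1e9, r), d)
        assert ll_inf == pytest.approx(np.log(1.0 / 3.0), abs=1e-6)

    def test_matches_enumeration_oracle_exactly(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            n = int(rng.integers(6, 13))
            coords = np.column_stack(
                [rng.uniform(0, 100, n), rng.uniform(0, 100, n), np.zeros(n)]
            )
            try:
                h = build_hemisphere(coords)
            except Exception:
                continue
            d = distance_matrix(h)
            s1 = list(rng.choice(n, 2, replace=False))
            rest = [k for k in range(n) if k not in s1]
            s2 = list(rng.choice(rest, min(3, len(rest)), replace=False))
            g = float(rng.uniform(0.2, 4.0))
            r = float(rng.uniform(10, 120))
            ll = interaction_loglik(h, s1, s2, InteractionParams(g, r), d)
            assert ll == pytest.approx(enumeration_loglik(h.coords[:, :2], s1, s2, g, r))

    def test_flat_in_radius_at_unit_strength(self, disc1200):
        h, d = disc1200
        rng = np.random.default_rng(1)
        s1 = rng.choice(h.n_cells, 15, replace=False)
        s2 = rng.choice(np.setdiff1d(np.arange(h.n_cells), s1), 20, replace=False)
        lls = [
            interaction_loglik(h, s1, s2, InteractionParams(1.0, r), d)
            for r in (15.0, 60.0, 140.0, 280.0)
        ]
        assert np.ptp(lls) < 1e-12
        assert lls[0] == pytest.approx(-len(s2) * np.log(h.n_cells - len(s1)))

    def test_monotone_in_strength_when_all_s2_inside(self, disc1200):
        h, d = disc1200
        center = int(np.argmin((h.coords[:, :2] ** 2).sum(axis=1)))
        s1 = [center]
        s2 = np.argsort(d.entries[center])[1:10]
        lls = [
            interaction_loglik(h, s1, s2, InteractionParams(g, 100.0), d)
            for g in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(lls, lls[1:]))

    def test_dls_assigned_to_time1_only(self, disc1200):
        """A cell in both label sets is dropped from s2 before fitting."""
        h, d = disc1200
        s1 = np.array([0, 1, 2])
        s2 = np.array([1, 10, 11])
        ds = InteractionDataset.from_pattern(h, s1, s2, d)
        assert len(ds.s2_dmin_sorted) == 2

    def test_all_cells_time1_rejected(self, grid3):
        h, d, _ = grid3
        with pytest.raises(ValueError):
            InteractionDataset.from_pattern(h, np.arange(9), [0], d)


class TestFit:
    def test_single_dataset_combined_equals_loglik(self, small_cloud):
        h, d = small_cloud
        s1, s2 = [0], [3]
        ds = InteractionDataset.from_pattern(h, s1, s2, d)
        fit = fit_interaction([ds], n_samples=500, seed=0)
        g, r = fit.ml_params.g, fit.ml_params.r
        assert fit.log_likelihood == pytest.approx(
            interaction_loglik(h, s1, s2, InteractionParams(g, r), d)
        )

    def test_requires_data(self):
        with pytest.raises(ValueError):
            fit_interaction([])

    def test_null_strength_interval_contains_one(self, disc2000):
        h, d = disc2000
        rng = np.random.default_rng(11)
        covered = 0
        for rep in range(6):
            ds = [
                InteractionDataset.from_pattern(h, p.s1_indices, p.s2_indices, d)
                for p in (
                    generate_pattern(h, d, 40, 40, 1.0, 100.0, seed=rng) for _ in range(6)
                )
            ]
            fit = fit_interaction(ds, n_samples=3000, seed=rep)
            covered += int(fit.ci_g[0] <= 1.0 <= fit.ci_g[1])
        assert covered >= 5

    def test_aggregated_generator_recovers_direction(self, disc2000):
        h, d = disc2000
        rng = np.random.default_rng(12)
        ds = [
            InteractionDataset.from_pattern(h, p.s1_indices, p.s2_indices, d)
            for p in (
                generate_pattern(h, d, 12, 40, 5.0, 100.0, seed=rng) for _ in range(6)
            )
        ]
        fit = fit_interaction(ds, n_samples=3000, seed=5)
        assert fit.ml_params.g > 1.3
        assert fit.ci_g[0] > 1.0  # interval excludes the null

    def test_dispersed_generator_recovers_direction(self, disc2000):
        h, d = disc2000
        rng = np.random.default_rng(13)
        ds = [
            InteractionDataset.from_pattern(h, p.s1_indices, p.s2_indices, d)
            for p in (
                generate_pattern(h, d, 12, 40, 0.2, 100.0, seed=rng) for _ in range(6)
            )
        ]
        fit = fit_interaction(ds, n_samples=3000, seed=6)
        assert fit.ml_params.g < 0.8


class TestStrengthSignificance:
    def test_exact_null(self):
        res = strength_significance([1.0, 1.0, 1.0])
        assert res["shift"] == 0.0
        assert res["p_value"] == 1.0

    def test_obvious_shift(self):
        rng = np.random.default_rng(0)
        strengths = 1.2 + 1e-3 * rng.standard_normal(4)
        res = strength_significance(strengths)
        assert res["shift"] == pytest.approx(0.2, abs=0.01)
        assert res["p_value"] < 0.05

    def test_requires_two_fits(self):
        with pytest.raises(ValueError):
            strength_significance([1.1])

    def test_type_i_error_near_nominal(self):
        """Constant-fit t-test rejects ~5% of null draws."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            strengths = 1.0 + rng.normal(0, 0.1, size=8)
            if strength_significance(strengths)["p_value"] < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)
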