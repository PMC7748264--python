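import numpy as np
import pytest

from nscpatterns.division import (
    FITTED_KINETICS,
    CellCycleParams,
    abc_distance,
    abc_fit,
    cohort_fractions,
    estimate_division_rate,
    lagexp_pdf,
    lagexp_sample,
    simulate_cohort,
    virtual_double_label,
)


class TestLagExp:
    def test_pdf_zero_below_delay(self):
        assert lagexp_pdf([21.9, 0.0, -5.0], beta=85.3, d=22.2).tolist() == [0, 0, 0]

    def test_pdf_integrates_to_one(self):
        x = np.linspace(0, 2000, 200001)
        pdf = lagexp_pdf(x, beta=85.3, d=22.2)
        assert np.trapezoid(pdf, x) == pytest.approx(1.0, abs=1e-4)

    def test_fitted_cycle_mean_is_107_5(self):
        # minimal cycle 22.2 h with scale 85.3 h gives the mean cycle 107.5 h
        assert 22.2 + 85.3 == pytest.approx(107.5)
        x = np.linspace(0, 5000, 500001)
        mean = np.trapezoid(x * lagexp_pdf(x, 85.3, 22.2), x)
        assert mean == pytest.approx(107.5, abs=0.01)

    def test_samples_respect_support_and_mean(self):
        draws = lagexp_sample(beta=1.6, d=16.6, n=1_000_000, seed=0)
        assert draws.min() >= 16.6
        se = 1.6 / np.sqrt(len(draws))
        assert abs(draws.mean() - 18.2) < 3 * se

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            lagexp_sample(beta=0.0, d=1.0, n=10)
        with pytest.raises(ValueError):
            lagexp_pdf([1.0], beta=-1.0, d=0.0)


class TestParams:
    def test_mean_properties(self):
        assert FITTED_KINETICS.mean_cycle == pytest.approx(107.5)
        assert FITTED_KINETICS.mean_s_phase == pytest.approx(18.2)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            CellCycleParams(0.0, 1.0, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            CellCycleParams(10.0, 1.0, 1.0, 1.0, 1.5)


class TestCohort:
    def test_no_redivision_means_no_chains(self):
        params = CellCycleParams(22.2, 85.3, 16.6, 1.6, 0.0)
        hist = simulate_cohort(params, n_cells=2000, seed=1)
        assert hist.n_cells == 2000
        assert (hist.generation == 0).all()

    def test_history_invariants(self):
        hist = simulate_cohort(FITTED_KINETICS, n_cells=5000, seed=2)
        assert (hist.s_end - hist.s_start >= FITTED_KINETICS.d_sp - 1e-9).all()
        assert (hist.division - hist.birth >= FITTED_KINETICS.d_cc - 1e-9).all()
        assert (hist.s_start >= hist.birth - 1e-9).all()
        assert (hist.s_end == hist.division).all()
        # chain parents precede their children
        child = hist.parent >= 0
        assert (hist.birth[child] == hist.division[hist.parent[child]]).all()

    def test_chain_frequency_matches_p_rediv(self):
        hist = simulate_cohort(FITTED_KINETICS, n_cells=20000, seed=3, t_end=450.0)
        # among divisions completing well inside the span, the fraction that
        # spawns a redivision chain is p_rediv
        done = hist.division <= 300.0
        spawned = np.isin(np.nonzero(done)[0], hist.parent)
        frac = spawned.mean()
        se = np.sqrt(0.38 * 0.62 / done.sum())
        assert abs(frac - 0.38) < 4 * se


class TestVirtualDoubleLabel:
    def _single(self, s_start, s_end, parent=-1, division=None):
        from nscpatterns.division import CohortHistories

        division = s_end if division is None else division
        return CohortHistories(
            parent=np.array([parent]),
            birth=np.array([s_start - 1.0]),
            division=np.array([division]),
            s_start=np.array([s_start]),
            s_end=np.array([s_end]),
            generation=np.array([0]),
            redivider=np.array([False]),
        )

    def test_dls_when_both_snapshots_in_one_s_phase(self):
        ro = virtual_double_label(self._single(10.0, 28.0), t1=20.0, t2=26.0)
        assert ro.n_labeled_t1 == 1 and ro.n_dls == 1

    def test_redivision_when_daughter_in_s_at_t2(self):
        from nscpatterns.division import CohortHistories

        hist = CohortHistories(
            parent=np.array([-1, 0]),
            birth=np.array([0.0, 30.0]),
            division=np.array([30.0, 98.0]),
            s_start=np.array([10.0, 80.0]),
            s_end=np.array([28.0, 98.0]),
            generation=np.array([0, 1]),
            redivider=np.array([False, True]),
        )
        ro = virtual_double_label(hist, t1=20.0, t2=92.0)
        assert ro.n_labeled_t1 == 1 and ro.n_rediv == 1 and ro.n_dls == 0

    def test_no_dls_at_72h_interval(self):
        # P(S-phase > 72 h) = exp(-(72 - 16.6)/1.6) < 1e-14 at fitted kinetics
        fr = cohort_fractions(FITTED_KINETICS, intervals=(72.0,), n_cells=20000, seed=4)
        assert fr[72.0]["dls"] == 0.0

    def test_rediv_fraction_near_zero_at_9h(self):
        fr = cohort_fractions(FITTED_KINETICS, intervals=(9.0,), n_cells=20000, seed=5)
        assert fr[9.0]["rediv"] < 0.02

    def test_dls_fraction_decreases_with_interval(self):
        fr = cohort_fractions(FITTED_KINETICS, n_cells=20000, seed=6)
        dls = [fr[dt]["dls"] for dt in sorted(fr)]
        assert all(a >= b - 1e-9 for a, b in zip(dls, dls[1:]))

    def test_observed_rediv_fraction_below_p_rediv(self):
        # snapshot labeling can only miss redivisions, never overcount them
        for seed in range(3):
            fr = cohort_fractions(FITTED_KINETICS, n_cells=10000, seed=seed)
            assert all(v["rediv"] <= FITTED_KINETICS.p_rediv for v in fr.values())

    def test_bad_times_rejected(self):
        hist = self._single(10.0, 28.0)
        with pytest.raises(ValueError):
            virtual_double_label(hist, t1=20.0, t2=15.0)
        with pytest.raises(ValueError):
            virtual_double_label(hist, t1=20.0, t2=500.0)


class TestAbcDistance:
    def test_identity_is_zero(self):
        obs = {9.0: {"rediv": [0.1, 0.2], "dls": [0.5, 0.4]}}
        assert abc_distance(obs, obs) == 0.0

    def test_single_interval_arithmetic(self):
        obs = {24.0: {"rediv": [0.1], "dls": [0.0]}}
        sim = {24.0: {"rediv": [0.2], "dls": [0.0]}}
        assert abc_distance(obs, sim) == pytest.approx(0.1)

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(0)
        obs = {dt: {"rediv": rng.random(4).tolist(), "dls": rng.random(4).tolist()} for dt in (9.0, 24.0)}
        sim = {dt: {"rediv": rng.random(4).tolist(), "dls": rng.random(4).tolist()} for dt in (9.0, 24.0)}
        assert abc_distance(obs, sim) == pytest.approx(abc_distance(sim, obs))
        assert abc_distance(obs, sim) >= 0

    def test_mismatched_intervals_rejected(self):
        with pytest.raises(ValueError):
            abc_distance({9.0: {"rediv": [0], "dls": [0]}}, {24.0: {"rediv": [0], "dls": [0]}})


class TestAbcFit:
    def test_smoke_recovery_of_p_rediv_direction(self):
        """Tiny ABC run pulls p_rediv toward the generating value."""
        from nscpatterns.synthetic import generate_observed_fractions

        truth = CellCycleParams(22.0, 85.0, 17.0, 1.5, 0.4)
        obs = generate_observed_fractions(truth, hemispheres_per_interval=4, n_cells=4000, seed=0)
        res = abc_fit(obs, epochs=4, particles=40, seed=1, n_cells=3000, replicates=3)
        lo, hi = res.credible_interval("p_rediv", 0.9)
        assert lo <= truth.p_rediv <= hi
        assert abs(res.point_estimate.p_rediv - 0.4) < 0.25

    def test_needs_three_intervals(self):
        with pytest.raises(ValueError):
            abc_fit({9.0: {"rediv": [0.1], "dls": [0.1]}}, epochs=1, particles=5)


def test_division_rate_from_snapshot_fraction():
    # 1.9% of NSCs in S-phase with ~18 h S-phases: 0.019/18 ~ 1e-3 per hour
    rate = estimate_division_rate(0.019, 18.0)
    assert rate == pytest.approx(0.019 / 18.0)
    assert rate == pytest.approx(1e-3, rel=0.06)
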