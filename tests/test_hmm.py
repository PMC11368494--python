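import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest, vonmises

from migtrack import hmm
from migtrack.hmm import (FLIGHT, STOPOVER, HMMModel, InsufficientDataError,
                          StepSeries, build_steps, count_movements, fit_hmm,
                          forward_loglik, label_states, merge_segments,
                          pseudo_residuals, segment_track, simulate_steps,
                          summarize_migration, viterbi)

from conftest import make_track, random_hmm


class TestBuildSteps:
    def test_collinear_equidistant_zero_turn(self):
        tr = make_track([0.0, 0.0, 0.0, 0.0], [30.0, 30.5, 31.0, 31.5])
        steps = build_steps(tr)
        assert np.isnan(steps.angles[0])
        np.testing.assert_allclose(steps.angles[1:], 0.0, atol=1e-9)

    def test_left_turn_is_positive_half_pi(self):
        # north, then west at the same latitude: a 90-degree left turn
        tr = make_track([0.0, 0.0, -0.5], [0.0, 0.5, 0.5])
        steps = build_steps(tr)
        assert steps.angles[1] == pytest.approx(np.pi / 2, abs=0.01)

    def test_meridian_half_degree_step(self):
        tr = make_track([0.0, 0.0, 0.0], [30.0, 30.5, 31.0])
        steps = build_steps(tr)
        assert steps.lengths[0] == pytest.approx(55.6, rel=2e-3)

    def test_speed_covariate_offset(self):
        tr = make_track([0.0, 0.0, 0.0], [30.0, 30.5, 31.0],
                        speed=[10.0, 12.0, 11.0])
        steps = build_steps(tr)
        np.testing.assert_allclose(steps.covariate, [10.1, 12.1])

    def test_too_few_fixes(self):
        with pytest.raises(InsufficientDataError):
            build_steps(make_track([0.0, 0.0], [30.0, 30.5]))


class TestFit:
    def test_two_state_parameter_recovery(self, two_state_model):
        steps, _ = simulate_steps(two_state_model, 2000, seed=1)
        m = fit_hmm(steps, 2, seed=0, n_restarts=3)
        np.testing.assert_allclose(m.step_mean, [0.2, 30.0], rtol=0.10)

    def test_single_state_reduces_to_direct_mle(self, rng_seed=7):
        rng = np.random.default_rng(rng_seed)
        lengths = rng.gamma(2.0, 3.0, 1500)
        angles = rng.vonmises(0.3, 2.0, 1500)
        angles[0] = np.nan
        steps = StepSeries(lengths, angles, np.full(1500, 30.0),
                           np.full(1500, 1.0), np.zeros(1500), None, "x")
        m = fit_hmm(steps, 1, seed=0, n_restarts=2)
        a, loc, scale = gamma_dist.fit(lengths, floc=0)
        np.testing.assert_allclose(m.step_mean[0], a * scale, rtol=1e-3)
        kap, mu, _ = vonmises.fit(angles[1:], fscale=1)
        assert m.angle_mean[0] == pytest.approx(mu, abs=0.01)
        assert m.angle_conc[0] == pytest.approx(kap, rel=0.02)

    def test_same_seed_bit_identical(self, two_state_model):
        steps, _ = simulate_steps(two_state_model, 600, seed=3)
        m1 = fit_hmm(steps, 2, seed=11, n_restarts=2)
        m2 = fit_hmm(steps, 2, seed=11, n_restarts=2)
        np.testing.assert_array_equal(m1.step_mean, m2.step_mean)
        np.testing.assert_array_equal(m1.tpm_intercept[~np.eye(2, dtype=bool)],
                                      m2.tpm_intercept[~np.eye(2, dtype=bool)])
        assert m1.loglik == m2.loglik

    def test_zero_steps_handled_by_zero_mass(self, two_state_model):
        steps, _ = simulate_steps(two_state_model, 800, seed=5)
        steps.lengths[::17] = 0.0
        m = fit_hmm(steps, 2, seed=0, n_restarts=2)
        assert np.isfinite(m.loglik)
        assert (m.zero_mass >= 0).all() and (m.zero_mass <= 1).all()


def _brute_force_viterbi(model, steps):
    """Exhaustive argmax over all joint state paths (tiny problems only)."""
    from migtrack.hmm import _log_emissions, _tpm_from_logits
    log_emis = _log_emissions(steps, model.step_mean, model.step_sd,
                              model.zero_mass, model.angle_mean, model.angle_conc)
    tpm = _tpm_from_logits(model.tpm_intercept, model.tpm_slope,
                           np.zeros(1))[0]
    with np.errstate(divide="ignore"):
        log_tpm = np.log(tpm)
        log_init = np.log(model.initial)
    T, N = log_emis.shape
    best, best_path = -np.inf, (0,) * T
    for path in itertools.product(range(N), repeat=T):
        ll = log_init[path[0]] + log_emis[0, path[0]]
        for t in range(1, T):
            ll += log_tpm[path[t - 1], path[t]] + log_emis[t, path[t]]
        if ll > best:
            best, best_path = ll, path
    return np.array(best_path)


class TestViterbi:
    def test_single_state_all_same(self):
        rng = np.random.default_rng(0)
        m = random_hmm(rng, 1)
        steps, _ = simulate_steps(m, 20, seed=0)
        assert (viterbi(m, steps) == 0).all()

    def test_eight_step_equals_exhaustive(self, two_state_model):
        steps, _ = simulate_steps(two_state_model, 8, seed=2)
        np.testing.assert_array_equal(viterbi(two_state_model, steps),
                                      _brute_force_viterbi(two_state_model, steps))

    def test_well_separated_recovery(self, two_state_model):
        steps, states = simulate_steps(two_state_model, 3000, seed=9)
        acc = np.mean(viterbi(two_state_model, steps) == states)
        assert acc >= 0.98


class TestPseudoResiduals:
    def test_uniform_under_true_model(self, two_state_model):
        rejections = 0
        n_rep = 100
        for s in range(n_rep):
            steps, _ = simulate_steps(two_state_model, 800, seed=1000 + s)
            u = pseudo_residuals(two_state_model, steps)
            if kstest(u, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections / n_rep <= 0.05

    def test_deterministic_repeat(self, two_state_model):
        steps, _ = simulate_steps(two_state_model, 500, seed=4)
        np.testing.assert_array_equal(pseudo_residuals(two_state_model, steps),
                                      pseudo_residuals(two_state_model, steps))

    def test_misspecified_single_state_rejected(self, two_state_model):
        steps, _ = simulate_steps(two_state_model, 2000, seed=6)
        m1 = fit_hmm(steps, 1, seed=0, n_restarts=2)
        u = pseudo_residuals(m1, steps)
        assert kstest(u, "uniform").pvalue < 1e-6


class TestLabeling:
    def _model(self, means, concs=None, angle_means=None):
        n = len(means)
        b0 = np.zeros((n, n))
        np.fill_diagonal(b0, np.nan)
        return HMMModel(n, np.array(means, float), np.ones(n),
                        np.zeros(n),
                        np.array(angle_means if angle_means else [0.0] * n),
                        np.array(concs if concs else [1.0] * n),
                        b0, np.where(np.isnan(b0), np.nan, 0.0),
                        np.full(n, 1 / n))

    def test_largest_mean_wins(self):
        roles = label_states(self._model([0.1, 1.0, 5.0, 32.0]))
        assert roles[3] == FLIGHT
        assert [roles[i] for i in range(3)] == [STOPOVER] * 3

    def test_near_tie_resolved_by_concentration(self):
        m = self._model([10.0, 10.5], concs=[8.0, 0.5])
        assert label_states(m)[0] == FLIGHT

    def test_two_state_exactly_one_migratory(self):
        roles = label_states(self._model([0.5, 20.0]))
        assert sum(1 for r in roles.values() if r == FLIGHT) == 1

    def test_permutation_equivariance(self):
        m = self._model([0.1, 5.0, 32.0])
        mp = self._model([32.0, 0.1, 5.0])
        assert label_states(m)[2] == FLIGHT
        assert label_states(mp)[0] == FLIGHT


def _steps_from_lengths(lengths, dlat=None):
    n = len(lengths)
    return StepSeries(np.asarray(lengths, float),
                      np.full(n, np.nan), np.full(n, 30.0), np.ones(n),
                      np.asarray(dlat if dlat is not None else np.ones(n) * 0.1),
                      None, "x")


ROLE2 = {0: STOPOVER, 1: FLIGHT}


class TestMergeSegments:
    def test_seventy_km_run_retained_at_threshold(self):
        steps = _steps_from_lengths([1, 35, 35, 1])
        seg = merge_segments(np.array([0, 1, 1, 0]), steps, 64.6, ROLE2)
        assert [s.role for s in seg.segments] == [STOPOVER, FLIGHT, STOPOVER]

    def test_short_run_reclassified_stopover(self):
        steps = _steps_from_lengths([1, 20, 20, 1])
        seg = merge_segments(np.array([0, 1, 1, 0]), steps, 64.6, ROLE2)
        assert [s.role for s in seg.segments] == [STOPOVER]
        assert seg.segments[0].n_steps == 4

    def test_all_stopover_single_segment(self):
        steps = _steps_from_lengths([1, 1, 1])
        seg = merge_segments(np.zeros(3, dtype=int), steps, 64.6, ROLE2)
        assert len(seg.segments) == 1 and not seg.flights

    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0.01, 200.0)),
                    min_size=1, max_size=60))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_no_adjacent_same_role_and_steps_conserved(self, seq):
        states = np.array([s for s, _ in seq])
        steps = _steps_from_lengths([l for _, l in seq])
        seg = merge_segments(states, steps, 64.6, ROLE2)
        roles = [s.role for s in seg.segments]
        assert all(a != b for a, b in zip(roles, roles[1:]))
        assert sum(s.n_steps for s in seg.segments) == len(seq)
        # flights that survive meet the cumulative threshold
        for f in seg.flights:
            assert f.length_km >= 64.6


class TestCountMovements:
    def test_final_stopover_excluded(self):
        steps = _steps_from_lengths([40, 40, 1, 1, 40, 40, 1, 1])
        seg = merge_segments(np.array([1, 1, 0, 0, 1, 1, 0, 0]), steps,
                             64.6, ROLE2)
        n_stop, n_rev = count_movements(seg)
        assert n_stop == 1 and n_rev == 0

    def test_southward_flight_counts_reverse(self):
        steps = _steps_from_lengths([40, 40, 1, 40, 40, 1],
                                    dlat=[0.3, 0.3, 0.0, -0.3, -0.3, 0.0])
        seg = merge_segments(np.array([1, 1, 0, 1, 1, 0]), steps, 64.6, ROLE2)
        assert count_movements(seg) == (1, 1)

    def test_zero_flights(self):
        steps = _steps_from_lengths([1, 1, 1, 1])
        seg = merge_segments(np.zeros(4, dtype=int), steps, 64.6, ROLE2)
        assert count_movements(seg) == (0, 0)


class TestSummarize:
    def test_three_day_flight(self):
        # one continuous 3-day flight: 144 steps of ~2.9 km (sums > 400 km)
        lats = 40.0 + np.cumsum(np.full(145, 0.026)) - 0.026
        tr = make_track([-100.0] * 145, lats)
        steps = build_steps(tr)
        states = np.ones(144, dtype=int)
        seg = merge_segments(states, steps, 64.6, ROLE2)
        s = summarize_migration(seg, tr, 0)
        assert s.duration_days == pytest.approx(3.0, abs=0.05)
        assert s.total_distance_km >= 400
        assert s.n_stopovers == 0

    def test_winter_region_other_outside_polygons(self):
        from migtrack.io_formats import RegionSet
        import shapely
        poly = shapely.box(-120, 50, -110, 60)
        lats = [30.0, 30.0] + list(30 + np.cumsum(np.full(4, 0.7)))
        tr = make_track([-100.0] * 6, lats)
        steps = build_steps(tr)
        states = np.array([0, 1, 1, 1, 1])
        seg = merge_segments(states, steps, 64.6, ROLE2)
        s = summarize_migration(seg, tr, 1,
                                winter_regions=RegionSet({"P": poly}))
        assert s.winter_region == "Other"


class TestModelProperties:
    def test_loglik_invariant_to_state_permutation(self, two_state_model):
        steps, _ = simulate_steps(two_state_model, 300, seed=8)
        m = two_state_model
        perm = HMMModel(
            2, m.step_mean[::-1].copy(), m.step_sd[::-1].copy(),
            m.zero_mass[::-1].copy(), m.angle_mean[::-1].copy(),
            m.angle_conc[::-1].copy(),
            m.tpm_intercept[::-1, ::-1].copy(), m.tpm_slope[::-1, ::-1].copy(),
            m.initial[::-1].copy())
        assert forward_loglik(m, steps) == pytest.approx(
            forward_loglik(perm, steps), abs=1e-8)

    def test_serialization_roundtrip(self, two_state_model):
        d = two_state_model.to_dict()
        back = HMMModel.from_dict(d)
        np.testing.assert_array_equal(back.step_mean, two_state_model.step_mean)
        steps, _ = simulate_steps(two_state_model, 100, seed=0)
        assert forward_loglik(back, steps) == forward_loglik(two_state_model, steps)

    def test_default_flight_threshold_doubles_migratory_mean(self, two_state_model):
        steps, _ = simulate_steps(two_state_model, 200, seed=0)
        seg = segment_track(steps, two_state_model)
        assert seg.flight_min_km == 2.0 * two_state_model.step_mean[1]
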