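"""Prediction envelopes, interval scores, and the three scenarios."""

import dataclasses

import numpy as np
import pytest

from bvselect.calibrate import FitOptions, fit_mle
from bvselect.cohort import CohortSpec, generate_cohort
from bvselect.models import ValidationError
from bvselect.predict import (interval_score, percentile_envelope,
                              proportion_within, scenario_loo,
                              scenario_steady_state, scenario_transient)

FAST_FIT = FitOptions(n_starts=2)


class TestIntervalScore:
    @pytest.mark.parametrize("lower,upper,y,expected", [
        (-1.0, 1.0, 0.0, 2.0),     # inside: width only
        (0.0, 1.0, -0.1, 5.0),     # miss below: 1 + 40*0.1
        (0.0, 1.0, 1.2, 9.0),      # miss above: 1 + 40*0.2
        (0.0, 1.0, 1.0, 1.0),      # boundary counts as inside
        (0.0, 1.0, 0.0, 1.0),
    ])
    def test_hand_cases(self, lower, upper, y, expected):
        assert interval_score(lower, upper, y, alpha=0.05) == \
            pytest.approx(expected)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValidationError, match="lower"):
            interval_score(1.0, 0.0, 0.5)

    def test_widening_a_covering_interval_adds_exactly_the_width(self):
        base = interval_score(-2.0, 3.0, 1.0)
        widened = interval_score(-2.5, 4.0, 1.0)
        assert widened - base == pytest.approx(1.5)


class TestPercentileEnvelope:
    def test_identical_replicates_zero_width(self):
        reps = np.full((50, 4), 7.25)
        lower, upper = percentile_envelope(reps)
        np.testing.assert_allclose(lower, 7.25)
        np.testing.assert_allclose(upper, 7.25)

    def test_matches_sort_and_interpolate_oracle(self):
        reps = np.arange(1.0, 101.0)[:, None]
        lower, upper = percentile_envelope(reps, alpha=0.05)

        def quantile_oracle(sorted_vals, q):
            # linear interpolation between order statistics
            h = (len(sorted_vals) - 1) * q
            lo = int(np.floor(h))
            return sorted_vals[lo] + (h - lo) * (
                sorted_vals[min(lo + 1, len(sorted_vals) - 1)] - sorted_vals[lo])
        assert lower[0] == pytest.approx(quantile_oracle(np.arange(1.0, 101.0),
                                                         0.025))
        assert upper[0] == pytest.approx(quantile_oracle(np.arange(1.0, 101.0),
                                                         0.975))

    def test_ordering_for_random_matrices(self):
        rng = np.random.default_rng(1)
        reps = rng.normal(size=(30, 7))
        lower, upper = percentile_envelope(reps)
        assert np.all(lower <= upper)

    def test_needs_two_replicates(self):
        with pytest.raises(ValidationError, match="2 replicates"):
            percentile_envelope(np.ones((1, 3)))


class TestProportionWithin:
    def test_extremes_and_hand_count(self):
        lower, upper = np.zeros(6), np.ones(6)
        assert proportion_within(lower, upper, np.full(6, 0.5)) == 1.0
        assert proportion_within(lower, upper, np.full(6, 9.0)) == 0.0
        y = np.array([0.5, 0.2, 1.5, -0.3, 1.0, 2.0])  # bounds inclusive
        assert proportion_within(lower, upper, y) == 0.5


@pytest.fixture(scope="module")
def noisefree():
    spec = CohortSpec(n_lr=1, n_hex=0, variant="refined", noise_sd=0.0,
                      seed=5)
    return generate_cohort(spec)[0][0]


class TestSubsampleScenarios:
    def test_noise_free_steady_state_full_coverage(self, noisefree):
        env = scenario_steady_state(noisefree, "refined", n_boot=10,
                                    gamma=0.0, seed=2, fit_options=FAST_FIT)
        assert env.pm == 1.0
        assert np.all(env.times > 150.0)

    def test_noise_free_transient_full_coverage(self, noisefree):
        env = scenario_transient(noisefree, "refined", n_boot=10, gamma=0.0,
                                 seed=2, fit_options=FAST_FIT)
        assert env.pm == 1.0
        # holdout window boundaries inclusive
        assert env.times.min() == 45.0
        assert env.times.max() == 80.0

    def test_same_seed_reproduces_envelope(self, noisefree):
        envs = [scenario_steady_state(noisefree, "original", n_boot=8,
                                      gamma=1.0, seed=11,
                                      fit_options=FAST_FIT)
                for _ in range(2)]
        np.testing.assert_array_equal(envs[0].lower, envs[1].lower)
        np.testing.assert_array_equal(envs[0].upper, envs[1].upper)

    def test_subsample_floor_enforced(self, noisefree):
        thin = dataclasses.replace(
            noisefree, measurements=dataclasses.replace(
                noisefree.measurements).subset(
                    np.isin(noisefree.measurements.times,
                            [0.0, 30.0, 60.0, 90.0, 120.0, 140.0, 160.0,
                             170.0, 180.0])))
        with pytest.raises(ValidationError, match="required"):
            scenario_steady_state(thin, "refined", n_boot=5, gamma=0.0,
                                  seed=1, fit_options=FAST_FIT)


class TestLeaveOneOut:
    def _donor_fits(self, subjects, variant="refined"):
        fits = [fit_mle(s, variant, gamma=0.0, options=FAST_FIT, seed=3)
                for s in subjects]
        return fits, [s.fluid_type for s in subjects]

    def test_identical_donors_collapse_envelope(self, noisefree):
        fit = fit_mle(noisefree, "refined", gamma=0.0, options=FAST_FIT,
                      seed=3)
        donors = [fit, fit, fit]
        with pytest.warns(UserWarning, match="point mass"):
            env = scenario_loo(noisefree, donors, ["LR", "LR", "LR"],
                               "refined", n_draws=50, seed=1)
        np.testing.assert_allclose(env.upper - env.lower, 0.0, atol=1e-9)
        # the envelope equals the common model's trajectory
        from bvselect.models import delta_bv_at
        traj = delta_bv_at(fit.params, noisefree.protocol, env.times)
        np.testing.assert_allclose(env.lower, traj, atol=1e-9)

    def test_determinism(self, small_cohort):
        subjects, _ = small_cohort
        donors, fluids = self._donor_fits(subjects[1:])
        envs = [scenario_loo(subjects[0], donors, fluids, "refined",
                             n_draws=200, seed=7) for _ in range(2)]
        np.testing.assert_array_equal(envs[0].lower, envs[1].lower)
        assert envs[0].pm == envs[1].pm

    def test_insufficient_donors_rejected(self, small_cohort):
        subjects, _ = small_cohort
        donors, fluids = self._donor_fits(subjects[1:3])
        with pytest.raises(ValidationError, match="3 donor"):
            scenario_loo(subjects[0], donors, fluids, "refined", n_draws=10,
                         seed=0)

    def test_well_specified_donors_beat_shifted_donors(self, small_cohort):
        subjects, _ = small_cohort
        held = subjects[0]
        donors, fluids = self._donor_fits(subjects[1:])
        env_good = scenario_loo(held, donors, fluids, "refined", n_draws=300,
                                seed=9)
        shifted = [dataclasses.replace(
            d, params=dataclasses.replace(d.params,
                                          alpha_u=d.params.alpha_u + 3.0))
            for d in donors]
        env_bad = scenario_loo(held, shifted, fluids, "refined", n_draws=300,
                               seed=9)
        assert env_good.pm >= env_bad.pm
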