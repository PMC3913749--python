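"""Model-free metrics: recall error, chance-corrected precision, nontarget RMS."""

import math

import numpy as np
import pytest

from recallmix import metrics
from recallmix.circstats import kappa_to_sd, sample_vm
from recallmix.metrics import (
    CHANCE_RMS,
    PRECISION_CAP,
    chance_rms_test,
    error_magnitude_correlation,
    expected_cooccurrence_correlation,
    nontarget_rms_deviation,
    precision,
    recall_error,
)
from recallmix.mixture import MixtureParams, simulate_responses


class TestRecallError:
    @pytest.mark.parametrize(
        "resp, targ, expected",
        [
            (0.3, 0.1, 0.2),
            (-3.0, 3.0, 2 * np.pi - 6.0),
            (1.234, 1.234, 0.0),
        ],
    )
    def test_values(self, resp, targ, expected):
        assert recall_error(resp, targ) == pytest.approx(expected, abs=1e-12)


class TestPrecision:
    def test_uniform_responder_is_at_chance(self, rng):
        # chance correction centres random responders on zero in expectation
        vals = [
            precision(rng.uniform(-np.pi, np.pi, 2000), n_chance_reps=3000, seed=0)
            for _ in range(25)
        ]
        assert np.mean([v.precision for v in vals]) == pytest.approx(0.0, abs=0.02)
        assert vals[0].chance_level > 0

    def test_von_mises_errors_match_closed_form(self, rng):
        errs = sample_vm(10**4, 0.0, 8.0, seed=2)
        est = precision(errs, n_chance_reps=3000, seed=0)
        expected = 1.0 / kappa_to_sd(8.0) - est.chance_level
        assert est.precision == pytest.approx(expected, abs=0.05)

    def test_zero_dispersion_saturates(self):
        est = precision(np.full(100, 0.4), n_chance_reps=500, seed=0)
        assert est.saturated
        assert est.precision == pytest.approx(PRECISION_CAP - est.chance_level)

    def test_requires_two_errors(self):
        with pytest.raises(ValueError):
            precision([0.1])

    def test_chance_level_is_cached_and_deterministic(self):
        a = metrics.chance_precision_level(175, 2000, seed=3)
        b = metrics.chance_precision_level(175, 2000, seed=3)
        assert a == b

    def test_precision_monotone_in_concentration(self, rng):
        # coarse: higher kappa (less dispersed errors) => higher precision
        meds = []
        for kappa in (32, 8, 2):
            vals = [
                precision(
                    sample_vm(2000, 0.0, kappa, seed=100 * kappa + r),
                    n_chance_reps=1000,
                    seed=0,
                ).precision
                for r in range(3)
            ]
            meds.append(np.median(vals))
        assert meds[0] > meds[1] > meds[2]


class TestNontargetRms:
    def test_independent_responses_hit_chance_value(self, rng):
        n = 10**5
        resp = rng.uniform(-np.pi, np.pi, n)
        nts = rng.uniform(-np.pi, np.pi, (n, 2))
        assert nontarget_rms_deviation(resp, nts) == pytest.approx(
            CHANCE_RMS, abs=0.01
        )
        assert CHANCE_RMS == pytest.approx(np.pi / np.sqrt(3), rel=1e-12)

    def test_exact_nontarget_reports_give_zero(self):
        nts = np.linspace(-3, 3, 50)[:, None]
        assert nontarget_rms_deviation(nts[:, 0], nts) == 0.0

    def test_misreports_pull_rms_below_chance(self, rng):
        n = 10**5
        targ = rng.uniform(-np.pi, np.pi, n)
        nts = rng.uniform(-np.pi, np.pi, (n, 2))
        p = MixtureParams(alpha=0.6, beta=0.4, kappa=10.0)
        resp = simulate_responses(p, targ, nts, seed=0)
        observed = nontarget_rms_deviation(resp, nts)
        assert observed < CHANCE_RMS - 0.05
        # independent simulation oracle of the same generative mixture
        resp2 = simulate_responses(p, targ, nts, seed=99)
        assert observed == pytest.approx(
            nontarget_rms_deviation(resp2, nts), abs=0.01
        )

    def test_no_nontargets_rejected(self):
        with pytest.raises(ValueError):
            nontarget_rms_deviation([0.1, 0.2], np.empty((2, 0)))


class TestChanceRmsTest:
    def test_exactly_at_chance_gives_zero_t(self):
        t, df, p = chance_rms_test(np.full(12, CHANCE_RMS))
        assert t == pytest.approx(0.0, abs=1e-9)
        assert df == 11

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            chance_rms_test([1.0, 1.1])

    def test_power_under_misreporting(self, rng):
        # cohorts that do misreport should be detected essentially always
        n_detect = 0
        for rep in range(20):
            rms = []
            for s in range(30):
                targ = rng.uniform(-np.pi, np.pi, 175)
                nts = rng.uniform(-np.pi, np.pi, (175, 2))
                resp = simulate_responses(
                    MixtureParams(alpha=0.7, beta=0.2, kappa=8.0), targ, nts, seed=rng
                )
                rms.append(nontarget_rms_deviation(resp, nts))
            t, _, p = chance_rms_test(rms)
            n_detect += (p < 0.05) and (t < 0)
        assert n_detect >= 19


class TestErrorMagnitudeCorrelation:
    def test_identical_magnitudes_correlate_perfectly(self, rng):
        e = rng.uniform(-np.pi, np.pi, 100)
        assert error_magnitude_correlation(e, -e) == pytest.approx(1.0)

    def test_independent_dimensions_near_zero(self, rng):
        e1 = rng.uniform(-np.pi, np.pi, 10**4)
        e2 = rng.uniform(-np.pi, np.pi, 10**4)
        assert abs(error_magnitude_correlation(e1, e2)) < 0.03

    def test_symmetric(self, rng):
        e1 = rng.normal(0, 0.5, 200)
        e2 = 0.5 * e1 + rng.normal(0, 0.3, 200)
        assert error_magnitude_correlation(e1, e2) == pytest.approx(
            error_magnitude_correlation(e2, e1), rel=1e-12
        )

    def test_shared_variability_gives_positive_r(self, rng):
        # a per-trial noise-scale modulator shared by both dimensions
        scale = rng.uniform(0.2, 1.5, 5000)
        e1 = rng.normal(0, 1, 5000) * scale
        e2 = rng.normal(0, 1, 5000) * scale
        assert error_magnitude_correlation(e1, e2) > 0.1

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            error_magnitude_correlation([0.1, 0.2, 0.3], [0.1, 0.2])


class TestCooccurrenceBenchmark:
    def test_no_misreports_gives_zero(self):
        p = MixtureParams(alpha=0.9, beta=0.0, kappa=8.0)
        r = expected_cooccurrence_correlation(p, p, m=2, n_sim=20_000, seed=1)
        assert abs(r) < 0.02

    def test_full_coupling_strongly_positive(self):
        p = MixtureParams(alpha=0.0, beta=1.0, kappa=50.0)
        r = expected_cooccurrence_correlation(p, p, m=2, n_sim=20_000, seed=1)
        assert r > 0.3

    def test_deterministic_given_seed(self):
        p1 = MixtureParams(alpha=0.6, beta=0.3, kappa=8.0)
        p2 = MixtureParams(alpha=0.7, beta=0.2, kappa=12.0)
        a = expected_cooccurrence_correlation(p1, p2, m=2, n_sim=5000, seed=7)
        b = expected_cooccurrence_correlation(p1, p2, m=2, n_sim=5000, seed=7)
        assert a == b
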