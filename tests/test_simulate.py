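"""Synthetic cohort generator: design structure, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recallmix.circstats import kappa_to_sd, sd_to_kappa
from recallmix.metrics import nontarget_abs_deviations
from recallmix.mixture import MixtureParams, fit_em
from recallmix.simulate import (
    CohortSpec,
    LinearAgeMap,
    SubjectSpec,
    default_age_maps,
    generate_array,
    generate_cohort,
    generate_subject,
)


def _make_subject(params_by_cell, age=30.0, exposure=2000):
    sigma = {k: kappa_to_sd(v.kappa) for k, v in params_by_cell.items()}
    return SubjectSpec(
        subject_id="S001",
        age=age,
        exposure_ms=exposure,
        education_years=15.0,
        span_scores={},
        params=params_by_cell,
        sigma=sigma,
    )


def _uniform_cell_params(alpha, beta, kappa):
    p = MixtureParams(alpha=alpha, beta=beta, kappa=kappa)
    p0 = MixtureParams(alpha=alpha + beta, beta=0.0, kappa=kappa)
    return {
        ("orientation", 1): p0,
        ("color", 1): p0,
        ("orientation", 3): p,
        ("color", 3): p,
    }


class TestGenerateArray:
    def test_low_load_has_no_nontargets(self):
        arr = generate_array(1, rng=np.random.default_rng(0))
        for dim in ("orientation", "color"):
            t, nts = arr[dim]
            assert np.isscalar(t)
            assert nts.size == 0

    def test_unsupported_load_rejected(self):
        with pytest.raises(ValueError):
            generate_array(2)

    def test_target_index_uniform_and_features_uniform(self):
        rng = np.random.default_rng(1)
        n = 2 * 10**4
        # the target is drawn uniformly among items: its value distribution
        # must match the (uniform) item distribution, and all values uniform
        targets = np.array([generate_array(3, rng)["color"][0] for _ in range(n)])
        u = (targets + np.pi) / (2 * np.pi)
        assert stats.kstest(u, "uniform").pvalue > 1e-3


class TestGenerateSubject:
    def test_row_structure(self):
        subj = _make_subject(_uniform_cell_params(0.7, 0.2, 8.0))
        df = generate_subject(subj, trials_low=10, trials_high=20, seed=0)
        assert len(df) == 2 * (10 + 20)
        assert set(df["dimension"]) == {"orientation", "color"}
        low = df[df["load"] == 1]
        assert low["nontarget1"].isna().all()
        high = df[df["load"] == 3]
        assert high[["nontarget1", "nontarget2"]].notna().all().all()
        for col in ("target", "response"):
            assert ((df[col] > -np.pi) & (df[col] <= np.pi)).all()

    def test_fit_round_trip_recovers_sigma(self):
        subj = _make_subject(_uniform_cell_params(1.0, 0.0, 50.0))
        df = generate_subject(subj, trials_low=25, trials_high=400, seed=1)
        cell = df[(df["load"] == 3) & (df["dimension"] == "orientation")]
        fit = fit_em(
            cell["response"].to_numpy(),
            cell["target"].to_numpy(),
            cell[["nontarget1", "nontarget2"]].to_numpy(),
            n_starts=10,
            seed=0,
        )
        assert abs(fit.sigma - kappa_to_sd(50.0)) < 0.03

    @staticmethod
    def _pairwise_nt_correlation(df):
        devs = {}
        high = df[df["load"] == 3]
        for dim in ("orientation", "color"):
            g = high[high["dimension"] == dim].sort_values("trial")
            devs[dim] = nontarget_abs_deviations(
                g["response"].to_numpy(), g[["nontarget1", "nontarget2"]].to_numpy()
            ).ravel()
        return stats.pearsonr(devs["orientation"], devs["color"])[0]

    def test_coupling_zero_gives_independent_misreports(self):
        subj = _make_subject(_uniform_cell_params(0.8, 0.1, 20.0))
        df = generate_subject(subj, trials_low=2, trials_high=10**4, coupling=0.0, seed=2)
        assert abs(self._pairwise_nt_correlation(df)) < 0.03

    def test_full_coupling_matches_cooccurrence_benchmark(self):
        from recallmix.metrics import expected_cooccurrence_correlation

        p = MixtureParams(alpha=0.5, beta=0.5, kappa=20.0)
        subj = _make_subject(_uniform_cell_params(0.5, 0.5, 20.0))
        df = generate_subject(subj, trials_low=2, trials_high=10**4, coupling=1.0, seed=3)
        observed = self._pairwise_nt_correlation(df)
        expected = expected_cooccurrence_correlation(p, p, m=2, n_sim=50_000, seed=9)
        assert observed == pytest.approx(expected, abs=0.05)
        assert observed > 0.1


class TestGenerateCohort:
    def test_byte_identical_regeneration(self):
        spec = CohortSpec(n_subjects=6, trials_high=40, seed=11)
        t1, s1, g1 = generate_cohort(spec)
        t2, s2, g2 = generate_cohort(spec)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_design_counts_and_invariants(self, small_cohort):
        spec, trials, subjects, truth = small_cohort
        per_subj = trials.groupby("subject_id").size()
        assert (per_subj == 2 * (spec.trials_low + spec.trials_high)).all()
        # every generated probability triple sums to 1
        s = truth[["alpha", "beta", "gamma"]].sum(axis=1)
        np.testing.assert_allclose(s, 1.0, atol=1e-12)
        # low-load cells have beta = 0
        assert (truth.loc[truth["load"] == 1, "beta"] == 0).all()
        # ages within range
        assert subjects["age"].between(*spec.age_range).all()

    def test_exposure_groups_age_matched(self):
        spec = CohortSpec(n_subjects=60, trials_low=2, trials_high=2, seed=5)
        _, subjects, _ = generate_cohort(spec)
        a = subjects.loc[subjects["exposure_ms"] == 200, "age"]
        b = subjects.loc[subjects["exposure_ms"] == 2000, "age"]
        assert len(a) == len(b) == 30
        assert stats.ks_2samp(a, b).pvalue > 0.05

    def test_age_maps_directionality(self):
        maps = default_age_maps()
        for dim in ("orientation", "color"):
            for load in (1, 3):
                assert maps[("sigma", dim, load)].slope > 0
                assert maps[("gamma", dim, load)].slope == 0
            assert maps[("beta", dim, 3)].slope > 0

    def test_manifest_round_trip(self):
        spec = CohortSpec(n_subjects=4, trials_high=30, seed=99, coupling=0.2)
        again = CohortSpec.from_manifest(spec.to_manifest())
        assert again == spec

    def test_null_age_maps_give_null_regressions(self):
        # zero-slope maps: age regressions on the generating parameters are
        # non-significant in most replicates (type-I error only)
        from recallmix.pipeline import regress_on_age

        maps = default_age_maps()
        flat = {
            k: LinearAgeMap(
                v.intercept + v.slope * 48.0, 0.0, v.noise_sd, v.lower, v.upper
            )
            for k, v in maps.items()
        }
        rng = np.random.default_rng(0)
        nonsig = 0
        n_rep = 40
        for _ in range(n_rep):
            spec = CohortSpec(
                n_subjects=40, trials_low=2, trials_high=2,
                age_maps=flat, seed=int(rng.integers(2**31)),
            )
            _, subjects, truth = generate_cohort(spec)
            merged = truth.merge(subjects[["subject_id", "age"]], on="subject_id")
            cell = merged[(merged["dimension"] == "orientation") & (merged["load"] == 3)]
            r = regress_on_age(cell["sigma"].to_numpy(), cell["age"].to_numpy())
            nonsig += r.p >= 0.05
        assert nonsig >= int(0.85 * n_rep)
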