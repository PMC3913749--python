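"""Validation suite: oracle comparisons, parameter recovery, calibration.

These routines exercise the package end to end against independent
benchmarks — an exhaustive grid search standing in for the EM fitter,
closed-form circular-statistics limits, Monte-Carlo type-I-error
calibration of every inferential test, and qualitative sign recovery of the
full synthetic-cohort pipeline.  They are used by the acceptance tests and
the acceptance script; sizes are parameters so both can choose their scale.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, stats

from .circstats import a1, kappa_to_sd, sd_to_kappa, vm_pdf, wrap, circ_sd, sample_vm
from .metrics import (
    CHANCE_RMS,
    chance_rms_test,
    nontarget_rms_deviation,
    precision,
)
from .mixture import MixtureParams, fit_em, fit_em_many, simulate_responses
from .pipeline import (
    analyze_cohort,
    ancova,
    compare_dependent_correlations,
    exposure_contrasts,
    fit_cohort,
    quartile_summary,
    regress_on_age,
)
from .simulate import CohortSpec, generate_cohort

__all__ = [
    "grid_max_loglik",
    "em_grid_gap",
    "parameter_recovery",
    "analytic_limits",
    "chance_calibration",
    "null_calibration",
    "sign_recovery",
    "structural_checks",
]

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# 1. EM vs exhaustive grid
# ---------------------------------------------------------------------------

def grid_max_loglik(responses, targets, nontargets, weight_step=0.05, n_kappa=30,
                    kappa_range=(0.25, 100.0)):
    """Exhaustive-grid maximum of the mixture log-likelihood.

    Evaluates the log-likelihood over all weight pairs (alpha, beta) on a
    ``weight_step`` lattice of the probability simplex crossed with
    ``n_kappa`` log-spaced concentrations, entirely independent of the EM
    path.  Used as a lower-bound oracle for the fitted optimum.
    """
    dev_t = wrap(np.asarray(responses) - np.asarray(targets))
    m = 0 if nontargets is None else np.asarray(nontargets).shape[1]
    cos_t = np.cos(dev_t)
    if m:
        dev_nt = wrap(np.asarray(responses)[:, None] - np.asarray(nontargets))
        cos_nt = np.cos(dev_nt)
    kappas = np.exp(np.linspace(np.log(kappa_range[0]), np.log(kappa_range[1]), n_kappa))

    grid = np.arange(0.0, 1.0 + 1e-9, weight_step)
    pairs = [(a, b) for a in grid for b in (grid if m else [0.0]) if a + b <= 1 + 1e-9]
    A = np.array([p[0] for p in pairs])
    B = np.array([p[1] for p in pairs])
    G = np.clip(1.0 - A - B, 0.0, 1.0)

    best = -np.inf
    from scipy.special import i0e

    for k in kappas:
        ft = np.exp(k * (cos_t - 1.0)) / (_TWO_PI * i0e(k))  # (n,)
        fnt = (
            np.exp(k * (cos_nt - 1.0)).mean(axis=1) / (_TWO_PI * i0e(k))
            if m
            else np.zeros_like(ft)
        )
        dens = (
            A[:, None] * ft[None, :]
            + B[:, None] * fnt[None, :]
            + G[:, None] / _TWO_PI
        )
        ll = np.log(np.maximum(dens, 1e-300)).sum(axis=1)
        best = max(best, float(ll.max()))
    return best


def em_grid_gap(n_datasets=20, n_trials=200, n_starts=20, seed=0):
    """Worst-case shortfall of the EM optimum vs the exhaustive grid.

    Simulates ``n_datasets`` mixtures with random parameters, fits each by
    multi-start EM and returns ``max(grid_ll - em_ll)`` (positive values
    mean the grid beat EM).  A correct global fit keeps this below ~1e-3.
    """
    rng = np.random.default_rng(seed)
    gaps = []
    for i in range(n_datasets):
        alpha = rng.uniform(0.2, 0.85)
        beta = rng.uniform(0.0, min(0.4, 1.0 - alpha))
        kappa = float(np.exp(rng.uniform(np.log(2.0), np.log(24.0))))
        targets = rng.uniform(-np.pi, np.pi, n_trials)
        nts = rng.uniform(-np.pi, np.pi, (n_trials, 2))
        resp = simulate_responses(
            MixtureParams(alpha=alpha, beta=beta, kappa=kappa),
            targets, nts, seed=rng,
        )
        fit = fit_em(resp, targets, nts, n_starts=n_starts, seed=int(rng.integers(2**31)))
        grid_ll = grid_max_loglik(resp, targets, nts)
        gaps.append(grid_ll - fit.log_likelihood)
    return float(np.max(gaps)), gaps


# ---------------------------------------------------------------------------
# 2. parameter recovery
# ---------------------------------------------------------------------------

def parameter_recovery(
    n_replicates=100, n_trials=500, alpha=0.6, beta=0.3, kappa=8.0,
    n_starts=20, seed=0,
):
    """Bias and mean absolute error of EM estimates on model-generated data."""
    rng = np.random.default_rng(seed)
    p = MixtureParams(alpha=alpha, beta=beta, kappa=kappa)
    targets = rng.uniform(-np.pi, np.pi, (n_replicates, n_trials))
    nts = rng.uniform(-np.pi, np.pi, (n_replicates, n_trials, 2))
    resp = np.stack(
        [simulate_responses(p, targets[c], nts[c], seed=rng) for c in range(n_replicates)]
    )
    fits = fit_em_many(resp, targets, nts, n_starts=n_starts, seed=int(rng.integers(2**31)))
    a = np.array([f.params.alpha for f in fits])
    b = np.array([f.params.beta for f in fits])
    s = np.array([f.sigma for f in fits])
    s_true = kappa_to_sd(kappa)
    return {
        "mae_alpha": float(np.abs(a - alpha).mean()),
        "mae_beta": float(np.abs(b - beta).mean()),
        "mae_sigma": float(np.abs(s - s_true).mean()),
        "bias_alpha": float((a - alpha).mean()),
        "bias_beta": float((b - beta).mean()),
        "bias_sigma": float((s - s_true).mean()),
        "min_loglik_increment": float(
            np.nanmin([f.min_loglik_increment for f in fits])
        ),
    }


# ---------------------------------------------------------------------------
# 3. analytic limits
# ---------------------------------------------------------------------------

def analytic_limits(seed=0, big_n=10**6):
    """Closed-form checks of the circular-statistics core.

    Returns absolute errors for: the uniform limit of the von Mises density,
    quadrature normalisation across concentrations, the kappa <-> sigma
    round trip, and the large-sample circular SD of von Mises draws vs the
    Bessel-ratio closed form.
    """
    uniform_err = abs(vm_pdf(0.3, 0.0, 0.0) - 1.0 / _TWO_PI)

    quad_err = 0.0
    for k in (0.0, 0.5, 2.0, 10.0, 50.0):
        val, _ = integrate.quad(lambda x: vm_pdf(x, 0.0, k), -np.pi, np.pi,
                                limit=200, epsabs=1e-12)
        quad_err = max(quad_err, abs(val - 1.0))

    rt_err = 0.0
    for sigma in np.linspace(0.05, 3.0, 25):
        rt_err = max(rt_err, abs(kappa_to_sd(sd_to_kappa(sigma)) - sigma))

    draws = sample_vm(big_n, 0.0, 8.0, seed=seed)
    closed = math.sqrt(-2.0 * math.log(a1(8.0)))
    sample_err = abs(circ_sd(draws) - closed)

    return {
        "vm_pdf_uniform_error": float(uniform_err),
        "quadrature_error": float(quad_err),
        "roundtrip_error": float(rt_err),
        "sampling_sd_error": float(sample_err),
    }


# ---------------------------------------------------------------------------
# 4. chance calibration and null type-I error
# ---------------------------------------------------------------------------

def chance_calibration(n_replicates=100, n_trials=175, n_chance_reps=10_000, seed=0):
    """Mean chance-corrected precision of purely random responders.

    Should be centred on zero: a subject responding uniformly at random has
    no usable memory and the chance correction removes the small-sample
    inflation of 1/circ_sd exactly in expectation.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_replicates):
        errs = rng.uniform(-np.pi, np.pi, n_trials)
        vals.append(precision(errs, n_chance_reps=n_chance_reps, seed=seed).precision)
    return float(np.mean(vals))


def independence_rms(n_trials=10**5, m=2, seed=0):
    """Nontarget RMS deviation when responses are independent of nontargets."""
    rng = np.random.default_rng(seed)
    resp = rng.uniform(-np.pi, np.pi, n_trials)
    nts = rng.uniform(-np.pi, np.pi, (n_trials, m))
    return nontarget_rms_deviation(resp, nts)


def null_calibration(seed=0, n_reps=1000, n_subjects=30, n_trials=175, m=2,
                     ancova_reps=500):
    """Type-I error of every inferential test under its null, at nominal 5%.

    * chance_rms_test on cohorts whose responses never involve nontargets;
    * regression on age with age-independent outcomes;
    * each ANCOVA term with outcome independent of everything;
    * the dependent-correlation comparison with equal population correlations;
    * the exposure contrast with no group difference.
    """
    rng = np.random.default_rng(seed)
    out = {}

    # chance_rms_test: per-subject RMS of uniform deviations
    rej = 0
    for _ in range(n_reps):
        rms = np.sqrt(
            np.mean(
                rng.uniform(-np.pi, np.pi, (n_subjects, n_trials * m)) ** 2, axis=1
            )
        )
        _, _, p = chance_rms_test(rms)
        rej += p < 0.05
    out["chance_rms_type1"] = rej / n_reps

    # age regression under the null
    ages = np.linspace(19, 77, 60)
    rej = 0
    for _ in range(n_reps):
        r = regress_on_age(rng.normal(size=60), ages)
        rej += r.p < 0.05
    out["regression_type1"] = rej / n_reps

    # ANCOVA terms under a global null
    import pandas as pd

    terms_rej = None
    for _ in range(ancova_reps):
        rows = []
        for s in range(60):
            for load in (1, 3):
                for dim in ("orientation", "color"):
                    rows.append(
                        {
                            "subject_id": s,
                            "age": ages[s],
                            "load": load,
                            "dimension": dim,
                            "y": rng.normal(),
                        }
                    )
        tab = ancova(pd.DataFrame(rows), "y")
        sig = (tab["p"] < 0.05).to_numpy()
        terms_rej = sig.astype(int) if terms_rej is None else terms_rej + sig
    for term, cnt in zip(tab["term"], terms_rej):
        out[f"ancova_{term}_type1"] = cnt / ancova_reps

    # dependent-correlation comparison under equal population correlations
    rho, shared = 0.3, 0.5
    cov = np.array([[1, shared, rho], [shared, 1, rho], [rho, rho, 1]])
    L = np.linalg.cholesky(cov)
    rej = 0
    for _ in range(n_reps):
        x = rng.normal(size=(60, 3)) @ L.T
        _, _, p = compare_dependent_correlations(x[:, 0], x[:, 1], x[:, 2])
        rej += p < 0.05
    out["corr_compare_type1"] = rej / n_reps

    # exposure contrast under the null
    import pandas as pd

    rej = 0
    for _ in range(n_reps):
        df = pd.DataFrame(
            {
                "subject_id": np.arange(60),
                "exposure_ms": np.tile([200, 2000], 30),
                "load": 3,
                "sigma": rng.normal(size=60),
            }
        )
        tab = exposure_contrasts(df, outcomes=("sigma",))
        rej += (tab["p"] < 0.05).iloc[0]
    out["exposure_type1"] = rej / n_reps
    return out


# ---------------------------------------------------------------------------
# 5. end-to-end sign recovery
# ---------------------------------------------------------------------------

def sign_recovery(n_replicates=50, seed=0, n_subjects=60, n_starts=6,
                  n_chance_reps=10_000):
    """Qualitative pattern recovery of the full pipeline on default cohorts.

    For each replicate cohort (age-increasing sigma and beta, flat gamma,
    exposure effect on sigma/gamma only) checks that the pipeline reports:

    * a negative age-precision correlation at both loads, stronger at high
      load;
    * significantly positive age-sigma and age-beta regressions (high load,
      dimension-pooled);
    * a non-significant age-gamma regression (dimension- and load-pooled);
    * a non-significant exposure effect on beta.

    Returns the fraction of replicates satisfying each property and their
    conjunction.
    """
    rng = np.random.default_rng(seed)
    props = {
        "precision_negative_both_loads": 0,
        "precision_stronger_high_load": 0,
        "sigma_age_positive": 0,
        "beta_age_positive": 0,
        "gamma_age_nonsig": 0,
        "exposure_beta_nonsig": 0,
        "all": 0,
    }
    for _ in range(n_replicates):
        spec = CohortSpec(n_subjects=n_subjects, seed=int(rng.integers(2**31)))
        trials, subjects, _ = generate_cohort(spec)
        est = fit_cohort(
            trials, n_starts=n_starts, n_chance_reps=n_chance_reps,
            seed=int(rng.integers(2**31)),
        )
        rep = analyze_cohort(est, subjects, trials=None)

        pa = rep.precision_age
        ok_neg = pa["r_low"] < 0 and pa["r_high"] < 0
        ok_stronger = pa["r_high"] < pa["r_low"]

        per_subj = est[est["load"] == 3].groupby("subject_id").agg(
            age=("age", "first"), sigma=("sigma", "mean"), beta=("beta", "mean")
        )
        r_sig = regress_on_age(per_subj["sigma"].to_numpy(), per_subj["age"].to_numpy())
        r_beta = regress_on_age(per_subj["beta"].to_numpy(), per_subj["age"].to_numpy())
        # gamma flatness, tested the way the cohort analysis reports it:
        # the ANCOVA age main effect per load, pooled over dimensions
        gam_ps = []
        for load in (1, 3):
            tab = ancova(est[est["load"] == load], "gamma", within=("dimension",))
            gam_ps.append(float(tab.loc[tab["term"] == "age", "p"].iloc[0]))

        beta_groups = est[est["load"] == 3].groupby(["subject_id", "exposure_ms"])[
            "beta"
        ].mean().reset_index()
        g200 = beta_groups.loc[beta_groups["exposure_ms"] == 200, "beta"]
        g2000 = beta_groups.loc[beta_groups["exposure_ms"] == 2000, "beta"]
        p_exp_beta = stats.ttest_ind(g200, g2000)[1]

        checks = {
            "precision_negative_both_loads": ok_neg,
            "precision_stronger_high_load": ok_stronger,
            "sigma_age_positive": r_sig.slope > 0 and r_sig.p < 0.05,
            "beta_age_positive": r_beta.slope > 0 and r_beta.p < 0.05,
            "gamma_age_nonsig": all(p >= 0.05 for p in gam_ps),
            "exposure_beta_nonsig": p_exp_beta >= 0.05,
        }
        for k, v in checks.items():
            props[k] += bool(v)
        props["all"] += all(checks.values())
    return {k: v / n_replicates for k, v in props.items()}


# ---------------------------------------------------------------------------
# 6. structural checks
# ---------------------------------------------------------------------------

def structural_checks(seed=0):
    """EM monotonicity, simplex closure, low-load beta and quartile split."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    min_inc = np.inf
    simplex_err = 0.0
    lowload_beta = 0.0
    for i in range(10):
        n = 200
        targets = rng.uniform(-np.pi, np.pi, n)
        nts = rng.uniform(-np.pi, np.pi, (n, 2))
        alpha = rng.uniform(0.3, 0.8)
        p = MixtureParams(
            alpha=alpha,
            beta=rng.uniform(0.0, min(0.3, 1.0 - alpha)),
            kappa=float(np.exp(rng.uniform(np.log(2), np.log(20)))),
        )
        resp = simulate_responses(p, targets, nts, seed=rng)
        fit = fit_em(resp, targets, nts, n_starts=10, seed=i)
        min_inc = min(min_inc, fit.min_loglik_increment)
        q = fit.params
        simplex_err = max(simplex_err, abs(q.alpha + q.beta + q.gamma - 1.0))
        resp0 = simulate_responses(
            MixtureParams(alpha=p.alpha, beta=0.0, kappa=p.kappa), targets, None, seed=rng
        )
        f0 = fit_em(resp0, targets, None, n_starts=10, seed=i)
        min_inc = min(min_inc, f0.min_loglik_increment)
        lowload_beta = max(lowload_beta, abs(f0.params.beta))
        simplex_err = max(
            simplex_err, abs(f0.params.alpha + f0.params.beta + f0.params.gamma - 1.0)
        )

    ages = np.sort(rng.uniform(19, 77, 60))
    df = pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(60)], "age": ages, "y": rng.normal(size=60)}
    )
    q = quartile_summary(df, ["y"])
    return {
        "min_loglik_increment": float(min_inc),
        "simplex_error": float(simplex_err),
        "lowload_beta": float(lowload_beta),
        "quartile_sizes": [int(x) for x in q["n"]],
    }
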