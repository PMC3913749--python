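"""Cohort-level statistics for dual-feature continuous-report studies.

Reproduces the standard inferential workflow for this design: per-cell
mixture fits and precision for every subject x feature dimension x load,
a 3-SD outlier rule, linear regressions of each outcome on age, ANCOVA with
within-subject factors (load, feature dimension) and age as a continuous
covariate, a dependent-correlation comparison of the age-precision
relationship across loads, age-quartile descriptive tables, between-group
exposure-duration contrasts, and (partial) correlations of precision with
span-test scores.

The ANCOVA is implemented in paired-contrast form: for each within-subject
term a per-subject contrast of the cell values is regressed on centred age,
and the intercept (the factor effect) or slope (its interaction with age) is
tested.  Every term then has F(1, n - 2), matching the degrees of freedom of
a repeated-measures ANCOVA with one continuous covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import (
    chance_rms_test,
    error_magnitude_correlation,
    expected_cooccurrence_correlation,
    nontarget_rms_deviation,
    precision,
    recall_error,
)
from .mixture import fit_em_many
from .simulate import DIMENSIONS, LOADS

__all__ = [
    "remove_outliers",
    "regress_on_age",
    "ancova",
    "compare_dependent_correlations",
    "quartile_summary",
    "partial_correlation",
    "exposure_contrasts",
    "fit_cohort",
    "analyze_cohort",
    "AnalysisReport",
]

PARAMS = ("alpha", "beta", "gamma", "sigma", "precision")


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------

def remove_outliers(values, k: float = 3.0):
    """Single-pass outlier rule: drop values more than ``k`` SD from the mean.

    Mean and SD are computed from all values (no iteration); returns a keep
    mask and a log dict with the count and fraction removed.  Idempotent on
    its own output in the sense that the values it keeps are never more than
    ``k`` (original) SDs from the (original) mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("outlier removal needs at least 3 values")
    mu = values.mean()
    sd = values.std(ddof=0)
    keep = np.abs(values - mu) <= k * sd if sd > 0 else np.ones(values.size, bool)
    log = {
        "n": int(values.size),
        "n_removed": int(np.sum(~keep)),
        "fraction_removed": float(np.mean(~keep)),
    }
    return keep, log


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    degenerate: bool = False


def regress_on_age(values, ages) -> RegressionResult:
    """OLS of an outcome on age; two-sided p for a zero slope.

    A constant outcome has no defined correlation; it is returned with
    ``degenerate=True`` and NaN r/p rather than raising.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.size < 3:
        raise ValueError("values and ages must be paired with n >= 3")
    if np.std(values) == 0 or np.std(ages) == 0:
        return RegressionResult(0.0, float(values.mean()), np.nan, np.nan, values.size, True)
    res = stats.linregress(ages, values)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue),
        float(res.pvalue), int(values.size),
    )


def _contrast_test(d, age_centred, term_is_slope):
    """Test intercept (factor effect) or slope (x covariate) of d ~ 1 + age_c.

    Returns (F, p) with F = t^2 on (1, n - 2) df.  Degenerate cases: a
    contrast that is identically zero gives F = 0; a non-zero constant
    contrast has no residual variance and its intercept test is reported as
    F = inf, p = 0.
    """
    d = np.asarray(d, dtype=float)
    if np.allclose(d, d[0]):
        if term_is_slope or np.isclose(d[0], 0.0):
            return 0.0, 1.0
        return float("inf"), 0.0
    fit = sm.OLS(d, sm.add_constant(age_centred)).fit()
    i = 1 if term_is_slope else 0
    t = fit.tvalues[i]
    if not np.isfinite(t):
        return 0.0, 1.0
    return float(t**2), float(fit.pvalues[i])


def ancova(
    estimates: pd.DataFrame,
    outcome: str,
    within=("load", "dimension"),
    covariate: str = "age",
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Repeated-measures ANCOVA with a continuous covariate, contrast form.

    ``estimates`` holds one row per subject x cell with the within-factor
    columns, the outcome and the covariate.  Each within factor must have
    exactly two levels and every subject must have complete cells.  Reports
    F(1, n - 2) and p for: the covariate main effect (on subject means),
    each within factor, each factor x covariate interaction and, with two
    factors, the factor x factor and three-way terms.
    """
    within = [within] if isinstance(within, str) else list(within)
    levels = {f: sorted(estimates[f].unique()) for f in within}
    for f, lv in levels.items():
        if len(lv) != 2:
            raise ValueError(f"within factor {f!r} must have exactly 2 levels, got {lv}")

    cells = list(product(*[levels[f] for f in within]))
    pivot = estimates.pivot_table(
        index=subject_col, columns=within, values=outcome, aggfunc="mean"
    )
    expected_cols = [c if len(within) > 1 else c[0] for c in cells]
    if pivot.isna().any().any() or len(pivot.columns) != len(cells):
        raise ValueError("unbalanced design: missing subject cells")
    Y = pivot[expected_cols].to_numpy()  # (n, n_cells) in `cells` order
    cov = estimates.groupby(subject_col)[covariate].mean().reindex(pivot.index).to_numpy()
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    age_c = cov - cov.mean()

    # contrast weights over cells: factor contrast = mean(high level cells)
    # - mean(low level cells); interaction = double difference
    signs = {f: {lv: s for lv, s in zip(levels[f], (-1.0, 1.0))} for f in within}
    half = len(cells) / 2.0
    contrasts = {}
    for j, f in enumerate(within):
        contrasts[f] = np.array([signs[f][c[j]] / half for c in cells])
    if len(within) == 2:
        f1, f2 = within
        contrasts[f"{f1}:{f2}"] = np.array(
            [signs[f1][c[0]] * signs[f2][c[1]] for c in cells]
        )

    rows = [("age" if covariate == "age" else covariate, *_contrast_test(Y.mean(axis=1), age_c, True))]
    for name, c in contrasts.items():
        d = Y @ c
        rows.append((name, *_contrast_test(d, age_c, False)))
        rows.append((f"{name}:{covariate}", *_contrast_test(d, age_c, True)))
    out = pd.DataFrame(rows, columns=["term", "F", "p"])
    out.insert(1, "df1", 1)
    out.insert(2, "df2", n - 2)
    return out


def compare_dependent_correlations(x1, x2, y):
    """Hotelling-Williams test for two correlations sharing a variable.

    Tests ``corr(x1, y) == corr(x2, y)`` on the same subjects; returns
    ``(t, df, p)`` with ``df = n - 3``.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    y = np.asarray(y, float)
    n = y.size
    if not (x1.size == x2.size == n) or n < 5:
        raise ValueError("all three variables must be paired with n >= 5")
    r12 = stats.pearsonr(x1, y)[0]
    r13 = stats.pearsonr(x2, y)[0]
    r23 = stats.pearsonr(x1, x2)[0]
    if np.isclose(r12, r13):
        return 0.0, n - 3, 1.0
    detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    rbar = 0.5 * (r12 + r13)
    denom = 2 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    p = 2 * stats.t.sf(abs(t), n - 3)
    return float(t), int(n - 3), float(p)


def quartile_summary(
    df: pd.DataFrame,
    outcomes,
    age_col: str = "age",
    id_col: str = "subject_id",
) -> pd.DataFrame:
    """Per-age-quartile means and SDs of the given outcome columns.

    Subjects are sorted by age (ties broken by stable id order) and split
    into four equal-count groups; remainders go to the earlier quartiles
    (7 subjects -> sizes 2, 2, 2, 1).
    """
    if len(df) < 4:
        raise ValueError("need at least 4 subjects for quartiles")
    ordered = df.sort_values([age_col, id_col], kind="stable").reset_index(drop=True)
    groups = np.array_split(np.arange(len(ordered)), 4)
    rows = []
    for q, idx in enumerate(groups, start=1):
        sub = ordered.iloc[idx]
        row = {
            "quartile": q,
            "n": len(sub),
            "age_min": sub[age_col].min(),
            "age_max": sub[age_col].max(),
        }
        for c in outcomes:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = sub[c].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def partial_correlation(x, y, z):
    """First-order partial correlation of x and y controlling for z.

    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``;
    returns ``(r, p)`` with p from a t with ``df = n - 3``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = x.size
    if not (y.size == z.size == n) or n < 4:
        raise ValueError("x, y, z must be paired with n >= 4")
    if min(np.std(x), np.std(y), np.std(z)) == 0:
        raise ValueError("degenerate (constant) variable in partial correlation")
    r_xy = stats.pearsonr(x, y)[0]
    r_xz = stats.pearsonr(x, z)[0]
    r_yz = stats.pearsonr(y, z)[0]
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), df))


def exposure_contrasts(
    estimates: pd.DataFrame,
    outcomes=PARAMS,
    group_col: str = "exposure_ms",
) -> pd.DataFrame:
    """Two-sample t-tests of each outcome between exposure groups, per load."""
    groups = sorted(estimates[group_col].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two exposure groups")
    rows = []
    for load in sorted(estimates["load"].unique()):
        sub = estimates[estimates["load"] == load]
        per_subj = sub.groupby(["subject_id", group_col], as_index=False)[
            [c for c in outcomes if c in sub.columns]
        ].mean()
        for out in outcomes:
            if out not in per_subj.columns:
                continue
            a = per_subj.loc[per_subj[group_col] == groups[0], out].dropna()
            b = per_subj.loc[per_subj[group_col] == groups[1], out].dropna()
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and np.isclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b)
            rows.append(
                {
                    "outcome": out,
                    "load": load,
                    "t": float(t),
                    "df": int(len(a) + len(b) - 2),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-scale fitting and the full analysis
# ---------------------------------------------------------------------------

def fit_cohort(
    trials: pd.DataFrame,
    n_starts: int = 6,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_chance_reps: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the response mixture for every subject x dimension x load cell.

    Cells sharing a trial count are fitted in one vectorised EM batch.
    Returns one row per cell: mixture parameters, sigma, log-likelihood,
    convergence flag, and chance-corrected precision with its chance level.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    cells = []
    for (sid, dim, load), g in trials.groupby(["subject_id", "dimension", "load"], sort=True):
        g = g.sort_values("trial", kind="stable")
        m = 0 if load == 1 else 2
        nts = g[["nontarget1", "nontarget2"]].to_numpy() if m else None
        cells.append(
            {
                "subject_id": sid,
                "dimension": dim,
                "load": int(load),
                "age": float(g["age"].iloc[0]),
                "exposure_ms": int(g["exposure_ms"].iloc[0]),
                "responses": g["response"].to_numpy(),
                "targets": g["target"].to_numpy(),
                "nontargets": nts,
                "m": m,
            }
        )

    # batch cells with identical (n, m)
    fits = {}
    by_shape = {}
    for i, c in enumerate(cells):
        by_shape.setdefault((len(c["responses"]), c["m"]), []).append(i)
    for (n, m), idxs in by_shape.items():
        resp = np.stack([cells[i]["responses"] for i in idxs])
        targ = np.stack([cells[i]["targets"] for i in idxs])
        nts = np.stack([cells[i]["nontargets"] for i in idxs]) if m else None
        batch = fit_em_many(
            resp, targ, nts, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed
        )
        for i, f in zip(idxs, batch):
            fits[i] = f

    rows = []
    for i, c in enumerate(cells):
        fit = fits[i]
        err = recall_error(c["responses"], c["targets"])
        prec = precision(err, n_chance_reps=n_chance_reps, seed=seed)
        rec = fit.to_record(
            subject_id=c["subject_id"],
            dimension=c["dimension"],
            load=c["load"],
            age=c["age"],
            exposure_ms=c["exposure_ms"],
        )
        rec.update(
            precision=prec.precision,
            chance_level=prec.chance_level,
            precision_saturated=prec.saturated,
            min_loglik_increment=fit.min_loglik_increment,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """Bundle of cohort-level results emitted by :func:`analyze_cohort`."""

    regressions: pd.DataFrame
    ancova_tables: dict
    precision_age: dict
    quartiles: pd.DataFrame
    exposure: pd.DataFrame
    span_correlations: pd.DataFrame
    outlier_log: pd.DataFrame
    nontarget: dict = field(default_factory=dict)
    joint_errors: dict = field(default_factory=dict)

    def save(self, outdir):
        """Write every table as CSV (and scalar blocks as two-column CSVs)."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.regressions.to_csv(os.path.join(outdir, "regressions.csv"), index=False)
        for name, tab in self.ancova_tables.items():
            tab.to_csv(os.path.join(outdir, f"ancova_{name}.csv"), index=False)
        self.quartiles.to_csv(os.path.join(outdir, "quartiles.csv"), index=False)
        self.exposure.to_csv(os.path.join(outdir, "exposure_contrasts.csv"), index=False)
        self.span_correlations.to_csv(
            os.path.join(outdir, "span_correlations.csv"), index=False
        )
        self.outlier_log.to_csv(os.path.join(outdir, "outlier_log.csv"), index=False)
        for name, d in (("precision_age", self.precision_age),
                        ("nontarget", self.nontarget),
                        ("joint_errors", self.joint_errors)):
            flat = {k: v for k, v in d.items() if np.isscalar(v)}
            if flat:
                pd.Series(flat).rename("value").to_csv(
                    os.path.join(outdir, f"{name}.csv"), header=True
                )


def _apply_outliers(estimates: pd.DataFrame, k: float = 3.0):
    """Mask per (parameter, dimension, load) cell across subjects; log removals."""
    est = estimates.copy()
    logs = []
    for par in PARAMS:
        if par not in est.columns:
            continue
        est[f"{par}_keep"] = True
        for (dim, load), g in est.groupby(["dimension", "load"]):
            vals = g[par].to_numpy()
            if len(vals) < 3:
                continue
            keep, log = remove_outliers(vals, k)
            est.loc[g.index[~keep], f"{par}_keep"] = False
            logs.append({"parameter": par, "dimension": dim, "load": load, **log})
    return est, pd.DataFrame(logs)


def analyze_cohort(
    estimates: pd.DataFrame,
    subjects: pd.DataFrame,
    trials: pd.DataFrame | None = None,
    outlier_k: float = 3.0,
    cooccurrence_sims: int = 20_000,
    seed: int = 0,
) -> AnalysisReport:
    """Run the full cohort-level inferential pipeline.

    Applies the outlier rule per parameter x dimension x load, regresses
    each outcome on age, runs the load x feature ANCOVAs with age as
    covariate, compares the age-precision correlation between loads,
    produces quartile and exposure-contrast tables, and correlates precision
    with span scores (with age/education partial correlations).  When the
    trial table is supplied, also runs the nonparametric nontarget-deviation
    validation and the cross-feature joint-error analysis.
    """
    est, outlier_log = _apply_outliers(estimates, outlier_k)

    # --- per-parameter age regressions ---------------------------------
    reg_rows = []
    for par in PARAMS:
        for (dim, load), g in est.groupby(["dimension", "load"]):
            kept = g[g[f"{par}_keep"]]
            if par == "beta" and load == 1:
                continue  # structurally zero
            if len(kept) < 3:
                continue
            r = regress_on_age(kept[par].to_numpy(), kept["age"].to_numpy())
            reg_rows.append(
                {
                    "parameter": par,
                    "dimension": dim,
                    "load": load,
                    "slope": r.slope,
                    "r": r.r,
                    "p": r.p,
                    "n": r.n,
                }
            )
    regressions = pd.DataFrame(reg_rows)

    # --- ANCOVAs --------------------------------------------------------
    anc = {}
    for outcome in ("precision", "sigma", "gamma"):
        anc[outcome] = ancova(est, outcome, within=("load", "dimension"))
    anc["beta_high"] = ancova(
        est[est["load"] == 3], "beta", within=("dimension",)
    )

    # --- age-precision correlation by load, and their comparison --------
    per_subject = est.pivot_table(index="subject_id", columns="load", values="precision")
    per_subject["age"] = est.groupby("subject_id")["age"].first()
    pa = {}
    low, high = sorted(c for c in per_subject.columns if c != "age")
    r_low = stats.pearsonr(per_subject["age"], per_subject[low])
    r_high = stats.pearsonr(per_subject["age"], per_subject[high])
    t, df, p = compare_dependent_correlations(
        per_subject[high], per_subject[low], per_subject["age"]
    )
    pa.update(
        r_low=float(r_low[0]), p_low=float(r_low[1]),
        r_high=float(r_high[0]), p_high=float(r_high[1]),
        t_diff=t, df_diff=df, p_diff=p,
    )

    # --- quartiles ------------------------------------------------------
    subj_outcomes = est.pivot_table(
        index="subject_id", columns="load",
        values=[p for p in PARAMS if p in est.columns], aggfunc="mean",
    )
    subj_outcomes.columns = [f"{a}_load{b}" for a, b in subj_outcomes.columns]
    qdf = subj_outcomes.merge(
        subjects.set_index("subject_id"), left_index=True, right_index=True
    ).reset_index()
    outcome_cols = [c for c in subj_outcomes.columns] + [
        c for c in ("span_total", "education_years") if c in qdf.columns
    ]
    quartiles = quartile_summary(qdf, outcome_cols)

    # --- exposure contrasts --------------------------------------------
    exposure = exposure_contrasts(est)

    # --- span correlations / partials ----------------------------------
    span_rows = []
    if "span_total" in subjects.columns:
        merged = qdf
        for load in LOADS:
            col = f"precision_load{load}"
            if col not in merged.columns:
                continue
            for var in ("span_total", "age", "education_years"):
                r, p_ = stats.pearsonr(merged[col], merged[var])
                span_rows.append(
                    {"x": col, "y": var, "kind": "pearson", "r": float(r), "p": float(p_)}
                )
            rp, pp = partial_correlation(
                merged[col], merged["education_years"], merged["age"]
            )
            span_rows.append(
                {"x": col, "y": "education_years", "kind": "partial|age", "r": rp, "p": pp}
            )
        r, p_ = stats.pearsonr(merged["span_total"], merged["age"])
        span_rows.append({"x": "span_total", "y": "age", "kind": "pearson", "r": float(r), "p": float(p_)})
        rp, pp = partial_correlation(
            merged["span_total"], merged["age"], merged["education_years"]
        )
        span_rows.append(
            {"x": "span_total", "y": "age", "kind": "partial|education", "r": rp, "p": pp}
        )
    span_correlations = pd.DataFrame(span_rows)

    report = AnalysisReport(
        regressions=regressions,
        ancova_tables=anc,
        precision_age=pa,
        quartiles=quartiles,
        exposure=exposure,
        span_correlations=span_correlations,
        outlier_log=outlier_log,
    )

    # --- trial-level analyses (need the raw table) ----------------------
    if trials is not None:
        high = trials[trials["load"] == 3]
        rms_rows = []
        for (sid,), g in high.groupby(["subject_id"]):
            rms_rows.append(
                {
                    "subject_id": sid,
                    "age": g["age"].iloc[0],
                    "rms": nontarget_rms_deviation(
                        g["response"].to_numpy(),
                        g[["nontarget1", "nontarget2"]].to_numpy(),
                    ),
                }
            )
        rms_df = pd.DataFrame(rms_rows)
        t, df, p = chance_rms_test(rms_df["rms"])
        age_reg = regress_on_age(rms_df["rms"].to_numpy(), rms_df["age"].to_numpy())
        report.nontarget = {
            "mean_rms": float(rms_df["rms"].mean()),
            "t_vs_chance": t,
            "df": df,
            "p_vs_chance": p,
            "age_r": age_reg.r,
            "age_p": age_reg.p,
            "per_subject": rms_df,
        }
        report.joint_errors = _joint_error_analysis(
            trials, est, cooccurrence_sims, seed
        )

    return report


def _joint_error_analysis(trials, estimates, n_sim, seed):
    """Cross-feature analyses: error-magnitude correlation per load and the
    observed vs expected-if-coupled nontarget-deviation correlation."""
    out = {}
    for load in LOADS:
        rs = []
        for sid, g in trials[trials["load"] == load].groupby("subject_id"):
            piv = {
                dim: g[g["dimension"] == dim].sort_values("trial")
                for dim in DIMENSIONS
            }
            e = {
                dim: recall_error(
                    piv[dim]["response"].to_numpy(), piv[dim]["target"].to_numpy()
                )
                for dim in DIMENSIONS
            }
            if len(e["orientation"]) >= 3:
                rs.append(error_magnitude_correlation(e["orientation"], e["color"]))
        rs = np.asarray(rs)
        t, p = stats.ttest_1samp(rs, 0.0)
        out[f"error_r_mean_load{load}"] = float(np.mean(rs))
        out[f"error_r_t_load{load}"] = float(t)
        out[f"error_r_p_load{load}"] = float(p)

    # observed vs expected nontarget-deviation coupling (high load)
    obs = []
    exp = []
    high = trials[trials["load"] == 3]
    fits = estimates[estimates["load"] == 3].set_index(["subject_id", "dimension"])
    from .metrics import nontarget_abs_deviations
    from .mixture import MixtureParams

    for i, (sid, g) in enumerate(high.groupby("subject_id")):
        mags = {}
        params = {}
        for dim in DIMENSIONS:
            gd = g[g["dimension"] == dim].sort_values("trial")
            mags[dim] = nontarget_abs_deviations(
                gd["response"].to_numpy(), gd[["nontarget1", "nontarget2"]].to_numpy()
            ).ravel()
            row = fits.loc[(sid, dim)]
            params[dim] = MixtureParams(
                alpha=float(row["alpha"]), beta=float(row["beta"]), kappa=float(row["kappa"])
            )
        obs.append(float(stats.pearsonr(mags["orientation"], mags["color"])[0]))
        exp.append(
            expected_cooccurrence_correlation(
                params["orientation"], params["color"], m=2, n_sim=n_sim, seed=seed + i
            )
        )
    obs = np.asarray(obs)
    exp = np.asarray(exp)
    t_obs, p_obs = stats.ttest_1samp(obs, 0.0)
    t_diff, p_diff = stats.ttest_rel(obs, exp)
    out.update(
        nt_dev_r_mean=float(obs.mean()),
        nt_dev_r_t=float(t_obs),
        nt_dev_r_p=float(p_obs),
        expected_coupled_r_mean=float(exp.mean()),
        obs_vs_coupled_t=float(t_diff),
        obs_vs_coupled_p=float(p_diff),
    )
    return out
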