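"""Model-free descriptive statistics for continuous-report data.

Covers the quantities that do not require fitting the response mixture:
per-trial recall error, chance-corrected recall precision (reciprocal
circular SD minus the value expected from a random responder), the
root-mean-square deviation of responses from nontarget feature values (a
nonparametric index of misreporting), and cross-feature error-magnitude
correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .circstats import circ_sd, wrap
from .mixture import MixtureFit

__all__ = [
    "PRECISION_CAP",
    "CHANCE_RMS",
    "PrecisionEstimate",
    "recall_error",
    "chance_precision_level",
    "precision",
    "nontarget_deviation_magnitude",
    "nontarget_abs_deviations",
    "nontarget_rms_deviation",
    "chance_rms_test",
    "error_magnitude_correlation",
    "expected_cooccurrence_correlation",
]

#: Finite cap substituted for 1/0 when a sample has exactly zero circular
#: dispersion, so cohort-level regressions stay defined.  Flagged via
#: :attr:`PrecisionEstimate.saturated`; a 3-SD outlier rule removes such
#: values downstream in any case.
PRECISION_CAP = 1.0e3

#: Expected RMS of a deviation uniformly distributed on (-pi, pi]:
#: sqrt(E[d^2]) = sqrt(pi^2 / 3) = pi / sqrt(3).
CHANCE_RMS = math.pi / math.sqrt(3.0)

_chance_cache: dict = {}


@dataclass(frozen=True)
class PrecisionEstimate:
    """Chance-corrected recall precision (units: 1/radian).

    ``precision`` is ``1 / circ_sd(errors) - chance_level``; zero indicates
    performance at chance.  ``saturated`` marks the degenerate
    zero-dispersion case where the raw reciprocal was capped.
    """

    precision: float
    n_trials: int
    chance_level: float
    saturated: bool = False


def recall_error(response, target):
    """Angular deviation ``wrap(response - target)`` of a report from its target."""
    response = np.asarray(response, dtype=float)
    target = np.asarray(target, dtype=float)
    return wrap(response - target)


def chance_precision_level(n, n_reps=10_000, seed=0):
    """Monte-Carlo mean of ``1/circ_sd`` for ``n`` uniform-random errors.

    This is the precision a subject responding at random would score before
    chance correction; it depends only on the sample size.  Results are
    cached per ``(n, n_reps, seed)`` since the same trial counts recur for
    every subject in a cohort.
    """
    key = (int(n), int(n_reps), int(seed))
    if key in _chance_cache:
        return _chance_cache[key]
    if n < 2:
        raise ValueError("chance level needs n >= 2")
    rng = np.random.default_rng(seed)
    # chunk so n * n_reps never materialises more than ~2e7 floats at once
    chunk = max(1, int(2e7) // int(n))
    recips = np.empty(int(n_reps))
    done = 0
    while done < n_reps:
        b = min(chunk, int(n_reps) - done)
        ang = rng.uniform(-np.pi, np.pi, size=(b, int(n)))
        r = np.hypot(np.cos(ang).mean(axis=1), np.sin(ang).mean(axis=1))
        r = np.clip(r, 1e-300, 1.0)
        sd = np.sqrt(-2.0 * np.log(r))
        recips[done : done + b] = np.where(sd > 0, 1.0 / np.maximum(sd, 1e-12), PRECISION_CAP)
        done += b
    level = float(recips.mean())
    _chance_cache[key] = level
    return level


def precision(errors, n_chance_reps=10_000, seed=0) -> PrecisionEstimate:
    """Chance-corrected recall precision of a sample of errors.

    ``1/circ_sd(errors)`` minus the Monte-Carlo expectation of the same
    statistic for a random responder with the same number of trials.  An
    infinitely dispersed sample (vanishing resultant) contributes a raw
    reciprocal of 0; a zero-dispersion sample is capped at
    :data:`PRECISION_CAP` and flagged.
    """
    errors = np.atleast_1d(np.asarray(errors, dtype=float))
    if errors.size < 2:
        raise ValueError("precision requires at least 2 errors")
    sd = circ_sd(errors)
    saturated = False
    if sd == 0.0:
        raw = PRECISION_CAP
        saturated = True
    elif math.isinf(sd):
        raw = 0.0
    else:
        raw = 1.0 / sd
    chance = chance_precision_level(errors.size, n_chance_reps, seed)
    return PrecisionEstimate(
        precision=float(raw - chance),
        n_trials=int(errors.size),
        chance_level=float(chance),
        saturated=saturated,
    )


def _nontarget_devs(responses, nontargets):
    responses = np.atleast_1d(np.asarray(responses, dtype=float))
    nontargets = np.asarray(nontargets, dtype=float)
    if nontargets.ndim == 1:
        nontargets = nontargets[:, None]
    if nontargets.shape[0] != responses.size:
        raise ValueError("one row of nontargets per response required")
    if nontargets.shape[1] < 1:
        raise ValueError("trials have no nontargets")
    return wrap(responses[:, None] - nontargets)


def nontarget_deviation_magnitude(responses, nontargets):
    """Per-trial RMS magnitude of deviations from the nontarget feature values."""
    d = _nontarget_devs(responses, nontargets)
    return np.sqrt(np.mean(d**2, axis=1))


def nontarget_abs_deviations(responses, nontargets):
    """Absolute deviation of each response from each nontarget, shape (n, m).

    Column ``i`` corresponds to nontarget item ``i``; keeping the item
    correspondence is what allows cross-feature coupling of misreports to be
    detected (a misreported item yields a jointly small deviation in both
    feature dimensions for the same column).
    """
    return np.abs(_nontarget_devs(responses, nontargets))


def nontarget_rms_deviation(responses, nontargets) -> float:
    """Root-mean-square deviation of responses from nontarget features.

    Pooled over all trial x nontarget pairs.  If responses are unrelated to
    the nontargets this converges to ``pi/sqrt(3)`` (about 1.814 rad);
    values below that indicate nontarget features attracted responses.
    """
    d = _nontarget_devs(responses, nontargets)
    return float(np.sqrt(np.mean(d**2)))


def chance_rms_test(per_subject_rms):
    """One-sample t-test of subject RMS nontarget deviations against chance.

    Tests the per-subject RMS values against ``pi/sqrt(3)``; a significantly
    lower mean indicates misreporting of nontargets at the cohort level.
    Returns ``(t, df, p)`` with a two-sided p.
    """
    vals = np.asarray(per_subject_rms, dtype=float)
    if vals.size < 3:
        raise ValueError("chance_rms_test requires at least 3 subjects")
    mean = float(np.mean(vals))
    if np.std(vals) <= 1e-12 * max(1.0, abs(mean)):
        # zero-variance degenerate sample: define t from the mean alone
        if np.isclose(mean, CHANCE_RMS):
            return 0.0, int(vals.size - 1), 1.0
        return float(np.sign(mean - CHANCE_RMS) * np.inf), int(vals.size - 1), 0.0
    t, p = stats.ttest_1samp(vals, CHANCE_RMS)
    return float(t), int(vals.size - 1), float(p)


def error_magnitude_correlation(errors_dim1, errors_dim2) -> float:
    """Pearson correlation of absolute wrapped error between two feature dimensions.

    Inputs are paired by trial (same trials, two feature reports).  Symmetric
    in its arguments.
    """
    e1 = np.abs(wrap(np.asarray(errors_dim1, dtype=float)))
    e2 = np.abs(wrap(np.asarray(errors_dim2, dtype=float)))
    if e1.shape != e2.shape:
        raise ValueError("error vectors must be paired by trial (unequal lengths)")
    if e1.size < 3:
        raise ValueError("need at least 3 paired trials")
    return float(stats.pearsonr(e1, e2)[0])


def _params_of(fit):
    return fit.params if isinstance(fit, MixtureFit) else fit


def expected_cooccurrence_correlation(
    fit_dim1, fit_dim2, m: int, n_sim: int = 50_000, seed: int = 0
) -> float:
    """Expected cross-feature nontarget-deviation correlation under coupling.

    Monte-Carlo benchmark for the hypothesis that misreports in the two
    feature dimensions occur *together*: a single shared uniform draw decides
    each trial's generating component in both dimensions (maximal coupling of
    the misreport indicators at ``min(beta_1, beta_2)``, remaining mass
    allocated to preserve each dimension's marginal rates) with a shared
    nontarget index when both dimensions misreport.  Feature values are drawn
    uniformly, response noise is von Mises at each dimension's fitted
    concentration.  The returned statistic is the Pearson correlation of the
    absolute response-to-nontarget deviations across dimensions, paired per
    (trial, nontarget item) — the item correspondence is what carries the
    coupling signal.  Deterministic for a given seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    p1 = _params_of(fit_dim1)
    p2 = _params_of(fit_dim2)
    rng = np.random.default_rng(seed)

    devs = []
    u = rng.uniform(size=n_sim)
    j_shared = rng.integers(0, m, size=n_sim)
    for p in (p1, p2):
        targets = rng.uniform(-np.pi, np.pi, size=n_sim)
        nts = rng.uniform(-np.pi, np.pi, size=(n_sim, m))
        # component from the shared draw: [0, beta) -> nontarget,
        # [beta, beta + alpha) -> target, rest -> uniform
        is_nt = u < p.beta
        is_t = (~is_nt) & (u < p.beta + p.alpha)
        centre = np.where(is_t, targets, 0.0)
        centre[is_nt] = nts[np.nonzero(is_nt)[0], j_shared[is_nt]]
        resp = wrap(centre + rng.vonmises(0.0, max(p.kappa, 0.0), size=n_sim))
        is_u = ~(is_nt | is_t)
        resp[is_u] = rng.uniform(-np.pi, np.pi, size=int(is_u.sum()))
        devs.append(nontarget_abs_deviations(resp, nts).ravel())

    r = stats.pearsonr(devs[0], devs[1])[0]
    return float(r)
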