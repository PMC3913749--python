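"""Three-component mixture model of continuous-report responses.

A response on a continuous circular scale is modelled as arising from one of
three sources: a von Mises distribution centred on the target feature value
(probability ``alpha``), a von Mises centred on one of the ``m`` nontarget
feature values (probability ``beta``, split evenly across nontargets), or a
uniform "random guess" distribution (probability ``gamma = 1 - alpha -
beta``).  A single concentration ``kappa`` is shared by the target and
nontarget components:

    p(x) = alpha * phi_kappa(x - theta)
         + (beta / m) * sum_i phi_kappa(x - phi_i)
         + gamma / (2 * pi)

Maximum-likelihood estimates are obtained by expectation-maximization,
restarted from a grid of initial values (plus optional random restarts) to
guard against local maxima.  The fitted concentration is also reported as the
more familiar circular standard deviation ``sigma``.

Trials with no nontargets (single-item arrays) reduce to a two-component
target + uniform model with ``beta`` fixed at exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator

from .circstats import KAPPA_MAX, a1_inv, kappa_to_sd, wrap

__all__ = [
    "TrialRecord",
    "MixtureParams",
    "MixtureFit",
    "VonMisesMixture",
    "log_likelihood",
    "responsibilities",
    "fit_em",
    "fit_em_many",
    "simulate_responses",
]

_TWO_PI = 2.0 * np.pi

#: Fits on fewer trials than this emit a warning (the smallest per-condition
#: cell in a typical dual-feature design is 25 trials).
MIN_TRIALS = 20


@dataclass(frozen=True)
class TrialRecord:
    """One continuous-report trial in one feature dimension.

    ``response`` and ``target`` are wrapped angles; ``nontargets`` holds the
    feature values of the other array items (empty for single-item trials).
    """

    response: float
    target: float
    nontargets: tuple = ()


@dataclass(frozen=True)
class MixtureParams:
    """Mixture weights and concentration of the three-component model.

    ``gamma`` is derived as ``1 - alpha - beta`` when not given explicitly;
    the three weights always sum to 1 (checked to 1e-12).
    """

    alpha: float
    beta: float
    kappa: float
    gamma: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.gamma is None:
            object.__setattr__(self, "gamma", 1.0 - self.alpha - self.beta)
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} is not a probability")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-12:
            raise ValueError("alpha + beta + gamma must equal 1")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass(frozen=True)
class MixtureFit:
    """Result of a maximum-likelihood fit of the response mixture."""

    params: MixtureParams
    sigma: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_starts: int
    n_trials: int
    #: smallest per-iteration log-likelihood increment seen over all starts;
    #: EM guarantees this is >= 0 up to floating-point rounding.
    min_loglik_increment: float = field(default=np.nan)

    def to_record(self, **extra) -> dict:
        """Flat key-value record suitable for a delimited-text table row."""
        rec = dict(extra)
        rec.update(
            alpha=self.params.alpha,
            beta=self.params.beta,
            gamma=self.params.gamma,
            kappa=self.params.kappa,
            sigma=self.sigma,
            log_likelihood=self.log_likelihood,
            converged=self.converged,
            n_trials=self.n_trials,
        )
        return rec


def _prepare(responses, targets, nontargets):
    """Validate and wrap trial arrays; return deviations matrix (n, 1 + m).

    Column 0 holds response - target deviations, columns 1.. hold
    response - nontarget deviations.  All trials must share the same m.
    """
    responses = np.atleast_1d(np.asarray(responses, dtype=float))
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    if responses.shape != targets.shape or responses.ndim != 1:
        raise ValueError("responses and targets must be equal-length 1-D arrays")
    n = responses.size
    if nontargets is None:
        nt = np.empty((n, 0))
    else:
        nt = np.asarray(nontargets, dtype=float)
        if nt.ndim == 1:
            nt = nt[:, None]
        if nt.shape[0] != n:
            raise ValueError("nontargets must have one row per trial (heterogeneous trials)")
        if nt.size and not np.all(np.isfinite(nt)):
            raise ValueError("nontarget angles must be finite (heterogeneous trials not supported)")
    dev = np.empty((n, 1 + nt.shape[1]))
    dev[:, 0] = wrap(responses - targets)
    if nt.shape[1]:
        dev[:, 1:] = wrap(responses[:, None] - nt)
    return dev, nt.shape[1]


def trials_to_arrays(trials):
    """Convert a sequence of :class:`TrialRecord` to (responses, targets, nontargets)."""
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    m = len(trials[0].nontargets)
    if any(len(t.nontargets) != m for t in trials):
        raise ValueError("all trials must share the same number of nontargets")
    responses = np.array([t.response for t in trials], dtype=float)
    targets = np.array([t.target for t in trials], dtype=float)
    nontargets = np.array([t.nontargets for t in trials], dtype=float).reshape(len(trials), m)
    return responses, targets, nontargets if m else None


def _check_model(params: MixtureParams, m: int):
    if m == 0 and params.beta > 0:
        raise ValueError("beta > 0 is invalid when trials have no nontargets")


def _densities(dev_cos, alpha, beta, gamma, kappa, m):
    """Per-trial component densities given cos(deviations) of shape (n, 1+m)."""
    f = np.exp(kappa * (dev_cos - 1.0)) / (_TWO_PI * special.i0e(kappa))
    p_t = alpha * f[:, 0]
    p_nt = (beta / m) * f[:, 1:] if m else np.empty((dev_cos.shape[0], 0))
    p_u = np.full(dev_cos.shape[0], gamma / _TWO_PI)
    return p_t, p_nt, p_u


def log_likelihood(params: MixtureParams, responses, targets, nontargets=None) -> float:
    """Total log-likelihood (nats) of the mixture over a set of trials."""
    dev, m = _prepare(responses, targets, nontargets)
    _check_model(params, m)
    p_t, p_nt, p_u = _densities(
        np.cos(dev), params.alpha, params.beta, params.gamma, params.kappa, m
    )
    tot = p_t + (p_nt.sum(axis=1) if m else 0.0) + p_u
    return float(np.sum(np.log(np.maximum(tot, 1e-300))))


def responsibilities(params: MixtureParams, responses, targets, nontargets=None):
    """Posterior probability of each generating component, per trial.

    Returns an array of shape ``(n, m + 2)`` ordered as
    ``[target, nontarget_1 .. nontarget_m, uniform]``; rows sum to 1.
    """
    dev, m = _prepare(responses, targets, nontargets)
    _check_model(params, m)
    p_t, p_nt, p_u = _densities(
        np.cos(dev), params.alpha, params.beta, params.gamma, params.kappa, m
    )
    joint = np.column_stack([p_t, p_nt, p_u])
    tot = joint.sum(axis=1, keepdims=True)
    return joint / np.maximum(tot, 1e-300)


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

# Deterministic grid of starting values; random extras are appended when
# n_starts exceeds the grid size.
_GRID_ALPHA = (0.3, 0.6, 0.9)
_GRID_BETA = (0.0, 0.2)
_GRID_KAPPA = (1.0, 4.0, 16.0)


def _start_values(m, n_starts, rng):
    grid = [
        (a0, b0, k0)
        for a0 in _GRID_ALPHA
        for b0 in (_GRID_BETA if m else (0.0,))
        for k0 in _GRID_KAPPA
    ]
    starts = grid[: min(n_starts, len(grid))]
    while len(starts) < n_starts:
        a0 = rng.uniform(0.1, 0.95)
        b0 = rng.uniform(0.0, 1.0 - a0) if m else 0.0
        k0 = float(np.exp(rng.uniform(np.log(0.5), np.log(50.0))))
        starts.append((a0, b0, k0))
    arr = np.array(starts, dtype=float)
    return arr[:, 0], arr[:, 1], arr[:, 2]


def _em_batch(dev, m, alpha0, beta0, kappa0, tol, max_iter):
    """Run EM for C data sets x S starts simultaneously.

    Parameters
    ----------
    dev : ndarray (C, n, 1 + m)
        Wrapped deviations (response - target, response - nontarget_i).
    alpha0, beta0, kappa0 : ndarray (S,)
        Shared starting values applied to every data set.

    Returns
    -------
    dict of per-(C, S) arrays: alpha, beta, gamma, kappa, loglik, n_iter,
    converged, min_increment.
    """
    C, n, K = dev.shape
    S = alpha0.size
    B = C * S
    cell = np.repeat(np.arange(C), S)

    cosd = np.cos(dev)
    cos_b = cosd[cell]  # (B, n, K)

    a = np.tile(alpha0, C).astype(float)
    b = np.tile(beta0, C).astype(float)
    k = np.tile(kappa0, C).astype(float)
    g = 1.0 - a - b

    ll = np.full(B, -np.inf)
    n_iter = np.zeros(B, dtype=int)
    converged = np.zeros(B, dtype=bool)
    min_inc = np.full(B, np.inf)
    active = np.ones(B, dtype=bool)

    for _ in range(max_iter):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        ca = cos_b[idx]
        ka = k[idx]

        f = np.exp(ka[:, None, None] * (ca - 1.0)) / (
            _TWO_PI * special.i0e(ka)
        )[:, None, None]
        p_t = a[idx, None] * f[:, :, 0]
        p_u = (g[idx] / _TWO_PI)[:, None]
        if m:
            p_nt = (b[idx] / m)[:, None, None] * f[:, :, 1:]
            tot = p_t + p_nt.sum(axis=2) + p_u
        else:
            tot = p_t + p_u
        np.maximum(tot, 1e-300, out=tot)
        ll_new = np.log(tot).sum(axis=1)

        inc = ll_new - ll[idx]
        finite_prev = np.isfinite(ll[idx])
        min_inc[idx[finite_prev]] = np.minimum(
            min_inc[idx[finite_prev]], inc[finite_prev]
        )
        ll[idx] = ll_new
        n_iter[idx] += 1

        done = finite_prev & (np.abs(inc) < tol)
        converged[idx[done]] = True
        active[idx[done]] = False

        # M-step.  The von Mises components have mean fixed at zero (about
        # the target/nontarget feature value), so the concentration update
        # solves A1(kappa) = weighted mean cosine of the component-assigned
        # deviations; a non-positive mean cosine maximises at kappa = 0.
        w_t = p_t / tot
        a_new = w_t.mean(axis=1)
        if m:
            w_nt = p_nt / tot[:, :, None]
            b_new = w_nt.sum(axis=(1, 2)) / n
            w_cos = (w_t * ca[:, :, 0]).sum(axis=1) + (w_nt * ca[:, :, 1:]).sum(axis=(1, 2))
            w_sum = w_t.sum(axis=1) + w_nt.sum(axis=(1, 2))
        else:
            b_new = np.zeros_like(a_new)
            w_cos = (w_t * ca[:, :, 0]).sum(axis=1)
            w_sum = w_t.sum(axis=1)
        rbar = w_cos / np.maximum(w_sum, 1e-12)
        k_new = a1_inv(np.clip(rbar, 0.0, 1.0 - 1e-15))
        k_new = np.where(w_sum < 1e-9, 0.0, np.minimum(k_new, KAPPA_MAX))

        g_new = 1.0 - a_new - b_new
        neg = g_new < 0
        if np.any(neg):
            scale = (a_new[neg] + b_new[neg])
            a_new[neg] /= scale
            b_new[neg] /= scale
            g_new[neg] = 0.0

        upd = ~done
        a[idx[upd]] = a_new[upd]
        b[idx[upd]] = b_new[upd]
        g[idx[upd]] = g_new[upd]
        k[idx[upd]] = k_new[upd]

    shape = (C, S)
    return dict(
        alpha=a.reshape(shape),
        beta=b.reshape(shape),
        gamma=g.reshape(shape),
        kappa=k.reshape(shape),
        loglik=ll.reshape(shape),
        n_iter=n_iter.reshape(shape),
        converged=converged.reshape(shape),
        min_increment=np.where(np.isfinite(min_inc), min_inc, np.nan).reshape(shape),
    )


def _best_fit(res, c, n_starts, n_trials) -> MixtureFit:
    """Pick the best start (ties -> lowest start index) for data set ``c``."""
    s = int(np.argmax(res["loglik"][c]))
    params = MixtureParams(
        alpha=float(res["alpha"][c, s]),
        beta=float(res["beta"][c, s]),
        kappa=float(res["kappa"][c, s]),
        gamma=float(res["gamma"][c, s]),
    )
    inc = res["min_increment"][c]
    inc = float(np.nanmin(inc)) if np.any(np.isfinite(inc)) else np.nan
    return MixtureFit(
        params=params,
        sigma=kappa_to_sd(params.kappa),
        log_likelihood=float(res["loglik"][c, s]),
        n_iterations=int(res["n_iter"][c, s]),
        converged=bool(res["converged"][c, s]),
        n_starts=n_starts,
        n_trials=n_trials,
        min_loglik_increment=inc,
    )


def fit_em(
    responses,
    targets,
    nontargets=None,
    n_starts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    seed=None,
) -> MixtureFit:
    """Fit the response mixture by multi-start expectation-maximization.

    Starts from a deterministic grid of initial values (plus random extras
    beyond the grid size) and returns the best fit across starts.  Within
    each start the log-likelihood is non-decreasing across iterations;
    convergence is declared when the improvement drops below ``tol`` nats.

    Fewer than 20 trials triggers a warning (not an error).  With no
    nontargets the nontarget weight is fixed at exactly 0.
    """
    dev, m = _prepare(responses, targets, nontargets)
    n = dev.shape[0]
    if n < MIN_TRIALS:
        warnings.warn(
            f"fitting on only {n} trials; estimates may be unstable", stacklevel=2
        )
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    a0, b0, k0 = _start_values(m, n_starts, np.random.default_rng(seed))
    res = _em_batch(dev[None], m, a0, b0, k0, tol, max_iter)
    return _best_fit(res, 0, n_starts, n)


def fit_em_many(
    responses,
    targets,
    nontargets=None,
    n_starts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    seed=None,
) -> list:
    """Fit many same-shape data sets at once (vectorised over sets and starts).

    ``responses`` and ``targets`` have shape ``(C, n)``; ``nontargets`` is
    ``(C, n, m)`` or None.  Returns a list of ``C`` :class:`MixtureFit`.
    Equivalent to calling :func:`fit_em` per data set but far faster, which
    matters when fitting every subject x dimension x load cell of a cohort.
    """
    responses = np.asarray(responses, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if responses.ndim != 2 or responses.shape != targets.shape:
        raise ValueError("responses and targets must be (C, n) arrays")
    C, n = responses.shape
    if nontargets is None:
        m = 0
        dev = wrap(responses - targets)[:, :, None]
    else:
        nontargets = np.asarray(nontargets, dtype=float)
        if nontargets.ndim != 3 or nontargets.shape[:2] != (C, n):
            raise ValueError("nontargets must be a (C, n, m) array")
        m = nontargets.shape[2]
        dev = np.concatenate(
            [
                wrap(responses - targets)[:, :, None],
                wrap(responses[:, :, None] - nontargets),
            ],
            axis=2,
        )
    if n < MIN_TRIALS:
        warnings.warn(
            f"fitting on only {n} trials; estimates may be unstable", stacklevel=2
        )
    a0, b0, k0 = _start_values(m, n_starts, np.random.default_rng(seed))
    res = _em_batch(dev, m, a0, b0, k0, tol, max_iter)
    return [_best_fit(res, c, n_starts, n) for c in range(C)]


def simulate_responses(
    params: MixtureParams,
    targets,
    nontargets=None,
    seed=None,
    return_components: bool = False,
):
    """Draw responses from the generative mixture, one per trial.

    Each trial's generating component is drawn with probabilities
    ``(alpha, beta, gamma)``; target/nontarget responses are von Mises about
    the chosen feature value with concentration ``kappa`` (the nontarget
    chosen uniformly among the ``m``), and uniform responses are uniform on
    the circle.  Deterministic for a given ``seed``.

    With ``return_components=True`` also returns the internal component
    labels (0 = target, 1 = nontarget, 2 = uniform).
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    n = targets.size
    if nontargets is None:
        nt = np.empty((n, 0))
    else:
        nt = np.asarray(nontargets, dtype=float)
        if nt.ndim == 1:
            nt = nt[:, None]
    m = nt.shape[1]
    _check_model(params, m)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    u = rng.uniform(size=n)
    comp = np.full(n, 2, dtype=int)  # uniform
    comp[u < params.alpha] = 0
    comp[(u >= params.alpha) & (u < params.alpha + params.beta)] = 1

    centre = targets.copy()
    if m:
        j = rng.integers(0, m, size=n)
        is_nt = comp == 1
        centre[is_nt] = nt[np.nonzero(is_nt)[0], j[is_nt]]
    noise = rng.vonmises(0.0, max(params.kappa, 0.0), size=n)
    resp = wrap(centre + noise)
    resp[comp == 2] = wrap(rng.uniform(-np.pi, np.pi, size=int(np.sum(comp == 2))))
    if return_components:
        return resp, comp
    return resp


class VonMisesMixture(BaseEstimator):
    """Sklearn-style estimator for the three-component response mixture.

    Parameters
    ----------
    n_starts : int
        Number of EM starting points (deterministic grid, then random).
    tol : float
        Convergence threshold on the per-iteration log-likelihood
        improvement, in nats.
    max_iter : int
        Iteration cap per start.
    random_state : int or None
        Seed for the random extra starts.

    Attributes (after :meth:`fit`)
    ------------------------------
    alpha_, beta_, gamma_, kappa_ : float
        Maximum-likelihood mixture parameters.
    sigma_ : float
        Circular SD equivalent of ``kappa_``.
    log_likelihood_ : float
        Maximised total log-likelihood (nats).
    n_iter_, converged_, fit_ : EM diagnostics and the full
        :class:`MixtureFit` record.

    Examples
    --------
    >>> est = VonMisesMixture(n_starts=10, random_state=0)
    >>> est.fit(responses, targets, nontargets)    # doctest: +SKIP
    >>> est.alpha_, est.sigma_                      # doctest: +SKIP
    """

    def __init__(self, n_starts=20, tol=1e-6, max_iter=10_000, random_state=None):
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, responses, targets, nontargets=None):
        fit = fit_em(
            responses,
            targets,
            nontargets,
            n_starts=self.n_starts,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.random_state,
        )
        self.fit_ = fit
        self.alpha_ = fit.params.alpha
        self.beta_ = fit.params.beta
        self.gamma_ = fit.params.gamma
        self.kappa_ = fit.params.kappa
        self.sigma_ = fit.sigma
        self.log_likelihood_ = fit.log_likelihood
        self.n_iter_ = fit.n_iterations
        self.converged_ = fit.converged
        return self

    def _params(self) -> MixtureParams:
        if not hasattr(self, "fit_"):
            raise AttributeError("estimator is not fitted yet")
        return self.fit_.params

    def score(self, responses, targets, nontargets=None) -> float:
        """Mean per-trial log-likelihood of new data under the fitted model."""
        n = np.atleast_1d(np.asarray(responses)).size
        return log_likelihood(self._params(), responses, targets, nontargets) / n

    def predict_proba(self, responses, targets, nontargets=None):
        """Posterior component responsibilities ``(n, m + 2)`` for new trials."""
        return responsibilities(self._params(), responses, targets, nontargets)

    def sample(self, targets, nontargets=None, seed=None, return_components=False):
        """Simulate responses from the fitted model (see :func:`simulate_responses`)."""
        return simulate_responses(
            self._params(), targets, nontargets, seed=seed,
            return_components=return_components,
        )
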