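"""Circular-data primitives for continuous-report analysis.

Feature values, responses and errors in a continuous-report task live on the
circle; everything downstream (the response mixture model, precision, the
nontarget-deviation statistics) is built on the small set of operations here:
wrapping to the canonical interval, the orientation double-angle map, the
circular standard deviation of Fisher (1993), the von Mises density, and the
conversion between the von Mises concentration ``kappa`` and the circular
standard deviation ``sigma``.

Conventions
-----------
* All angles are radians on the half-open interval ``(-pi, pi]``; the
  boundary ``-pi`` wraps to ``+pi``.
* A mean resultant length of zero (and ``kappa = 0``) yields ``math.inf``
  as the circular SD rather than an error, so that reciprocal precision is
  well-defined (it becomes 0).
* ``kappa`` is dimensionless and non-negative; ``kappa = 0`` is the uniform
  distribution on the circle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

__all__ = [
    "KAPPA_MAX",
    "wrap",
    "orientation_to_angle",
    "angle_to_orientation",
    "resultant_length",
    "circ_mean",
    "circ_sd",
    "vm_pdf",
    "vm_logpdf",
    "a1",
    "a1_inv",
    "kappa_to_sd",
    "sd_to_kappa",
    "sample_vm",
]

_TWO_PI = 2.0 * np.pi

#: Upper cap on the concentration parameter.  Beyond this the von Mises is
#: numerically a point mass (sigma < 1e-2) and the EM M-step can otherwise
#: chase degenerate spikes.
KAPPA_MAX = 1.0e4


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def wrap(x):
    """Wrap angles to the canonical interval ``(-pi, pi]``.

    Parameters
    ----------
    x : float or array_like
        Angle(s) in radians; must be finite.

    Returns
    -------
    float or ndarray
        ``x + 2*pi*k`` for the integer ``k`` placing the result in
        ``(-pi, pi]``.  Idempotent.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("angles must be finite")
    w = np.pi - np.mod(np.pi - x, _TWO_PI)
    return float(w) if w.ndim == 0 else w


def orientation_to_angle(deg):
    """Map bar orientations in degrees ``[0, 180)`` onto the full circle.

    Orientation is a 180-degree-periodic feature; doubling maps its parameter
    space onto the full ``2*pi`` circle so that circular statistics apply.
    """
    deg = np.asarray(deg, dtype=float)
    if np.any(deg < 0) or np.any(deg >= 180):
        raise ValueError("orientation must lie in [0, 180) degrees")
    return wrap(2.0 * np.deg2rad(deg))


def angle_to_orientation(angle):
    """Inverse of :func:`orientation_to_angle`: radians back to degrees in ``[0, 180)``."""
    angle = np.asarray(wrap(angle), dtype=float)
    deg = np.rad2deg(np.mod(angle, _TWO_PI)) / 2.0
    deg = np.where(deg >= 180.0, deg - 180.0, deg)
    return float(deg) if deg.ndim == 0 else deg


def resultant_length(angles, axis=None):
    """Mean resultant length ``Rbar`` of a sample of angles (1 = no dispersion)."""
    angles = np.asarray(angles, dtype=float)
    c = np.mean(np.cos(angles), axis=axis)
    s = np.mean(np.sin(angles), axis=axis)
    return np.hypot(c, s)


def circ_mean(angles, axis=None):
    """Circular mean direction of a sample of angles."""
    angles = np.asarray(angles, dtype=float)
    c = np.mean(np.cos(angles), axis=axis)
    s = np.mean(np.sin(angles), axis=axis)
    return wrap(np.arctan2(s, c))


def circ_sd(angles):
    """Circular standard deviation, ``sqrt(-2 ln Rbar)`` (Fisher 1993).

    Returns ``math.inf`` when the resultant vanishes (e.g. angles placed
    symmetrically around the circle); requires at least two angles.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValueError("circ_sd requires at least 2 angles")
    r = resultant_length(angles)
    # a resultant at rounding-noise level is a vanishing resultant
    if r <= 1e-12:
        return math.inf
    # rounding can push Rbar infinitesimally above 1 for zero-dispersion data
    r = min(r, 1.0)
    return float(abs(np.sqrt(-2.0 * np.log(r))))


def vm_pdf(x, mu, kappa):
    """von Mises density ``exp(kappa*cos(x - mu)) / (2*pi*I0(kappa))``.

    Evaluated through exponentially scaled Bessel functions so it remains
    finite for arbitrarily large ``kappa``. ``kappa = 0`` gives the uniform
    density ``1/(2*pi)``.
    """
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    d = np.exp(kappa * (np.cos(x - mu) - 1.0)) / (_TWO_PI * special.i0e(kappa))
    return float(d) if d.ndim == 0 else d


def vm_logpdf(x, mu, kappa):
    """Log of :func:`vm_pdf`, numerically stable for large ``kappa``."""
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    ld = kappa * (np.cos(x - mu) - 1.0) - np.log(_TWO_PI * special.i0e(kappa))
    return float(ld) if ld.ndim == 0 else ld


def a1(kappa):
    """Bessel-function ratio ``A1(kappa) = I1(kappa)/I0(kappa)``.

    This is the mean resultant length of the von Mises distribution with
    concentration ``kappa``; computed with scaled Bessel functions so it is
    stable well beyond ``kappa ~ 700``.
    """
    kappa = np.asarray(kappa, dtype=float)
    r = special.i1e(kappa) / special.i0e(kappa)
    return float(r) if r.ndim == 0 else r


def a1_inv(r):
    """Invert ``A1``: the concentration whose mean resultant length is ``r``.

    Uses the Best/Fisher piecewise series as the starting value and polishes
    with safeguarded Newton steps on ``A1(kappa) - r`` (``A1`` is smooth and
    strictly increasing, so Newton converges quadratically).  ``r = 0`` maps
    to 0 and ``r -> 1`` saturates at :data:`KAPPA_MAX`.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).copy()
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("resultant length must lie in [0, 1]")
    r = np.clip(r, 0.0, 1.0 - 1e-15)

    with np.errstate(divide="ignore"):
        k = np.where(
            r < 0.53,
            2.0 * r + r**3 + 5.0 * r**5 / 6.0,
            np.where(
                r < 0.85,
                -0.4 + 1.39 * r + 0.43 / (1.0 - r),
                1.0 / np.maximum(r**3 - 4.0 * r**2 + 3.0 * r, 1e-300),
            ),
        )
    k = np.clip(k, 0.0, KAPPA_MAX)

    for _ in range(6):
        a = a1(k)
        # dA1/dkappa = 1 - A1^2 - A1/kappa (limit 1/2 at kappa = 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            da = np.where(k > 1e-12, 1.0 - a**2 - a / np.maximum(k, 1e-12), 0.5)
        da = np.maximum(da, 1e-12)
        k = np.clip(k - (a - r) / da, 0.0, KAPPA_MAX)

    k = np.where(r <= 0.0, 0.0, k)
    return float(k[0]) if scalar else k


def kappa_to_sd(kappa):
    """Circular SD of a von Mises: ``sqrt(-2 ln A1(kappa))``.

    Strictly decreasing in ``kappa``; returns ``math.inf`` at ``kappa = 0``.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    scalar = kappa.ndim == 0
    kappa = np.atleast_1d(kappa)
    with np.errstate(divide="ignore"):
        sd = np.sqrt(-2.0 * np.log(a1(kappa)))
    sd = np.where(kappa == 0.0, np.inf, sd)
    return float(sd[0]) if scalar else sd


def sd_to_kappa(sigma):
    """Numerical inverse of :func:`kappa_to_sd`.

    ``sigma`` must be positive; very large ``sigma`` maps to ``kappa`` near
    zero.  Round-trips with :func:`kappa_to_sd` to better than 1e-6 over the
    working range ``sigma`` in ``[0.05, 3]``.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return a1_inv(np.exp(-0.5 * sigma**2))


def sample_vm(n, mu, kappa, seed=None):
    """Draw ``n`` i.i.d. von Mises(mu, kappa) angles, wrapped to ``(-pi, pi]``.

    ``kappa = 0`` reduces to the uniform distribution on the circle.  The
    same ``seed`` always yields the same draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = _as_rng(seed)
    return wrap(rng.vonmises(float(mu), kappa, size=int(n)))
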