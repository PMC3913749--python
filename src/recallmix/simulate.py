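"""Synthetic aging-cohort generator for the dual-feature report design.

Generates full trial tables with the structure of a dual-feature
continuous-report study: two memory loads (1 and 3 items), two feature
dimensions per trial (orientation, mapped onto the full circle, and colour
as a hue angle), two between-subject exposure-duration groups (2 s vs
200 ms) matched for age, 25 low-load and 175 high-load trials per subject,
and responses drawn from the three-component mixture with age-dependent
parameters.

The generative age structure is sign-faithful to what aging studies of this
design report: the circular SD ``sigma`` of the target/nontarget response
noise and the misreport rate ``beta`` increase linearly with age, the random
guess rate ``gamma`` is flat in age, and brief (200 ms) exposure inflates
``sigma`` (both loads) and ``gamma`` (high load) but not ``beta``.  The
magnitudes of the age slopes are free parameters of the generator (no
published generative coefficients exist); the defaults make the young-to-old
contrast detectable in a 60-subject cohort and match reported young/old
misreport rates (about 5% -> 19% for orientation, 1% -> 8% for colour).

Everything is deterministic given the cohort seed: the same
:class:`CohortSpec` regenerates byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circstats import sd_to_kappa, wrap
from .mixture import MixtureParams

__all__ = [
    "DIMENSIONS",
    "LOADS",
    "LinearAgeMap",
    "SubjectSpec",
    "CohortSpec",
    "default_age_maps",
    "generate_array",
    "generate_subject",
    "generate_cohort",
]

DIMENSIONS = ("orientation", "color")
LOADS = (1, 3)

#: Nontargets per trial at each load.
_M = {1: 0, 3: 2}

TRIAL_COLUMNS = [
    "subject_id",
    "age",
    "exposure_ms",
    "load",
    "trial",
    "dimension",
    "target",
    "nontarget1",
    "nontarget2",
    "response",
]


@dataclass(frozen=True)
class LinearAgeMap:
    """Linear age -> parameter map with Gaussian subject-level noise.

    ``value = intercept + slope * age + N(0, noise_sd)``, clipped to
    ``[lower, upper]``.  Ages are in years.
    """

    intercept: float
    slope: float
    noise_sd: float
    lower: float
    upper: float

    def draw(self, age: float, rng: np.random.Generator) -> float:
        v = self.intercept + self.slope * age + rng.normal(0.0, self.noise_sd)
        return float(np.clip(v, self.lower, self.upper))


def default_age_maps() -> dict:
    """Default generative age maps, keyed by ``(parameter, dimension, load)``.

    sigma (radians) rises with age and with load; beta (high load only)
    rises with age, more steeply for orientation than colour; gamma is flat
    in age.  Intercepts are expressed at age 0 so that
    ``intercept + slope * age`` is the population mean at a given age.
    """
    maps = {}
    # sigma: low load ~0.26 -> 0.49 (orientation) across ages 19..77
    maps[("sigma", "orientation", 1)] = LinearAgeMap(0.18, 0.0040, 0.05, 0.05, 2.0)
    maps[("sigma", "color", 1)] = LinearAgeMap(0.20, 0.0040, 0.05, 0.05, 2.0)
    # sigma: high load ~0.60 -> 1.07
    maps[("sigma", "orientation", 3)] = LinearAgeMap(0.45, 0.0080, 0.08, 0.10, 2.5)
    maps[("sigma", "color", 3)] = LinearAgeMap(0.42, 0.0070, 0.08, 0.10, 2.5)
    # beta: only defined at load 3; ~0.05 -> 0.19 (orientation), 0.01 -> 0.08
    maps[("beta", "orientation", 3)] = LinearAgeMap(0.004, 0.0024, 0.030, 0.0, 0.6)
    maps[("beta", "color", 3)] = LinearAgeMap(-0.013, 0.0012, 0.020, 0.0, 0.6)
    # gamma: flat in age
    maps[("gamma", "orientation", 1)] = LinearAgeMap(0.03, 0.0, 0.02, 0.005, 0.5)
    maps[("gamma", "color", 1)] = LinearAgeMap(0.03, 0.0, 0.02, 0.005, 0.5)
    maps[("gamma", "orientation", 3)] = LinearAgeMap(0.12, 0.0, 0.04, 0.01, 0.5)
    maps[("gamma", "color", 3)] = LinearAgeMap(0.10, 0.0, 0.04, 0.01, 0.5)
    return maps


@dataclass(frozen=True)
class SubjectSpec:
    """Generative description of one synthetic subject."""

    subject_id: str
    age: float
    exposure_ms: int
    education_years: float
    span_scores: dict
    params: dict  # (dimension, load) -> MixtureParams
    sigma: dict  # (dimension, load) -> generating circular SD


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic aging cohort.

    Defaults emulate the reference design: 60 subjects aged 19-77, 25
    low-load and 175 high-load trials, exposure groups (2 s vs 200 ms)
    matched for age, age-increasing sigma and beta, flat gamma, and an
    exposure effect on sigma and (high-load) gamma only.  ``coupling`` in
    [0, 1] shares the misreport indicator across the two feature dimensions
    (0 = independent misreports, 1 = maximal coupling).
    """

    n_subjects: int = 60
    trials_low: int = 25
    trials_high: int = 175
    age_range: tuple = (19.0, 77.0)
    coupling: float = 0.0
    exposure_effect: bool = True
    exposure_sigma_mult: float = 1.25
    exposure_gamma_add: float = 0.05
    age_maps: dict = field(default_factory=default_age_maps)
    seed: int = 0

    def to_manifest(self) -> dict:
        """Plain-dict form (age maps flattened) for exact regeneration."""
        d = asdict(self)
        d["age_maps"] = {
            "|".join(map(str, k)): list(asdict(v).values())
            for k, v in self.age_maps.items()
        }
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        maps = {}
        for k, v in d["age_maps"].items():
            param, dim, load = k.split("|")
            maps[(param, dim, int(load))] = LinearAgeMap(*v)
        d["age_maps"] = maps
        return cls(**d)


def generate_array(load: int, rng=None):
    """Feature values for one memory array at the given load.

    Each item's orientation and colour are independent uniform draws on the
    circle; one item is designated the target uniformly at random.  Returns
    ``{dimension: (target, nontargets)}`` with ``nontargets`` an array of
    the other items' values (empty at load 1).
    """
    if load not in _M:
        raise ValueError(f"unsupported load {load}; must be one of {sorted(_M)}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    probe = int(rng.integers(0, load))
    out = {}
    for dim in DIMENSIONS:
        vals = wrap(rng.uniform(-np.pi, np.pi, size=load))
        out[dim] = (float(vals[probe]), np.delete(vals, probe))
    return out


def _draw_subject_params(age, exposure_ms, spec: CohortSpec, rng) -> tuple:
    """Per-cell mixture parameters and sigmas for one subject."""
    params = {}
    sigmas = {}
    for dim in DIMENSIONS:
        for load in LOADS:
            sigma = spec.age_maps[("sigma", dim, load)].draw(age, rng)
            beta = (
                spec.age_maps[("beta", dim, load)].draw(age, rng)
                if ("beta", dim, load) in spec.age_maps
                else 0.0
            )
            gamma = spec.age_maps[("gamma", dim, load)].draw(age, rng)
            if spec.exposure_effect and exposure_ms == 200:
                sigma *= spec.exposure_sigma_mult
                if load == 3:
                    gamma = min(gamma + spec.exposure_gamma_add, 0.6)
            if beta + gamma > 0.95:  # keep a valid simplex with alpha >= 0.05
                scale = 0.95 / (beta + gamma)
                beta *= scale
                gamma *= scale
            params[(dim, load)] = MixtureParams(
                alpha=1.0 - beta - gamma, beta=beta, kappa=sd_to_kappa(sigma)
            )
            sigmas[(dim, load)] = sigma
    return params, sigmas


def _draw_spans(age, education_years, rng) -> dict:
    """Span-test scores with a negative age trend and positive education trend."""
    def span(base, age_slope, edu_slope, sd, lo=2, hi=18):
        v = base + age_slope * age + edu_slope * (education_years - 14.0)
        return int(np.clip(np.rint(v + rng.normal(0.0, sd)), lo, hi))

    scores = {
        "digit_forward": span(11.5, -0.030, 0.25, 2.2),
        "digit_backward": span(8.5, -0.030, 0.25, 2.0),
        "corsi_forward": span(8.5, -0.020, 0.15, 1.5),
        "corsi_backward": span(8.0, -0.025, 0.15, 1.5),
    }
    scores["digit_total"] = scores["digit_forward"] + scores["digit_backward"]
    scores["corsi_total"] = scores["corsi_forward"] + scores["corsi_backward"]
    scores["span_total"] = scores["digit_total"] + scores["corsi_total"]
    return scores


def _subject_specs(spec: CohortSpec, rng) -> list:
    n = spec.n_subjects
    ages = np.sort(rng.uniform(*spec.age_range, size=n))
    # assign exposure within consecutive age pairs so the two groups have
    # matched age distributions
    exposures = np.empty(n, dtype=int)
    pairs = n // 2
    block = rng.permuted(np.tile([2000, 200], (pairs, 1)), axis=1)
    exposures[: 2 * pairs] = block.ravel()
    if n % 2:
        exposures[-1] = int(rng.choice([2000, 200]))
    subjects = []
    for i in range(n):
        age = float(ages[i])
        edu = float(np.clip(16.0 - 0.045 * (age - 19.0) + rng.normal(0.0, 1.5), 8.0, 22.0))
        params, sigmas = _draw_subject_params(age, int(exposures[i]), spec, rng)
        subjects.append(
            SubjectSpec(
                subject_id=f"S{i + 1:03d}",
                age=age,
                exposure_ms=int(exposures[i]),
                education_years=edu,
                span_scores=_draw_spans(age, edu, rng),
                params=params,
                sigma=sigmas,
            )
        )
    return subjects


def _simulate_cell(n, m, params_by_dim, coupling, rng):
    """Simulate one (load) cell for both dimensions with optional coupling.

    Returns per-dimension (targets, nontargets, responses).
    """
    u_shared = rng.uniform(size=n)
    shared = rng.uniform(size=n) < coupling
    j_shared = rng.integers(0, max(m, 1), size=n)
    out = {}
    for dim in DIMENSIONS:
        p = params_by_dim[dim]
        targets = wrap(rng.uniform(-np.pi, np.pi, size=n))
        nts = wrap(rng.uniform(-np.pi, np.pi, size=(n, m))) if m else np.empty((n, 0))
        u = np.where(shared, u_shared, rng.uniform(size=n))
        # misreport interval first so shared draws couple misreports at
        # min(beta_1, beta_2); target next preserves both marginals
        is_nt = (u < p.beta) if m else np.zeros(n, dtype=bool)
        is_t = (~is_nt) & (u < p.beta + p.alpha)
        is_u = ~(is_nt | is_t)
        centre = np.where(is_t, targets, 0.0)
        if m:
            j_own = rng.integers(0, m, size=n)
            j = np.where(shared, j_shared, j_own)
            centre[is_nt] = nts[np.nonzero(is_nt)[0], j[is_nt]]
        resp = wrap(centre + rng.vonmises(0.0, p.kappa, size=n))
        resp[is_u] = wrap(rng.uniform(-np.pi, np.pi, size=int(is_u.sum())))
        out[dim] = (targets, nts, resp)
    return out


def generate_subject(
    subject: SubjectSpec,
    trials_low: int = 25,
    trials_high: int = 175,
    coupling: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Trial rows for one subject: both loads, both feature dimensions.

    Responses in each (dimension x load) cell follow that cell's mixture
    parameters; ``coupling`` optionally shares the misreport indicator (and
    the misreported item) across dimensions.  Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for load, n in ((1, trials_low), (3, trials_high)):
        m = _M[load]
        cell = _simulate_cell(
            n, m, {d: subject.params[(d, load)] for d in DIMENSIONS}, coupling, rng
        )
        for dim in DIMENSIONS:
            targets, nts, resp = cell[dim]
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject.subject_id,
                        "age": subject.age,
                        "exposure_ms": subject.exposure_ms,
                        "load": load,
                        "trial": np.arange(n),
                        "dimension": dim,
                        "target": targets,
                        "nontarget1": nts[:, 0] if m else np.nan,
                        "nontarget2": nts[:, 1] if m else np.nan,
                        "response": resp,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def generate_cohort(spec: CohortSpec):
    """Generate a full synthetic cohort.

    Returns
    -------
    trials : DataFrame
        One row per trial x feature dimension (see ``TRIAL_COLUMNS``).
    subjects : DataFrame
        One row per subject: age, exposure group, education, span scores.
    truth : DataFrame
        The generating mixture parameters per subject x dimension x load,
        for parameter-recovery validation.
    """
    root = np.random.default_rng(spec.seed)
    subjects = _subject_specs(spec, root)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(len(subjects))

    trial_frames = []
    subj_rows = []
    truth_rows = []
    for subj, ss in zip(subjects, child_seeds):
        trial_frames.append(
            generate_subject(
                subj,
                spec.trials_low,
                spec.trials_high,
                spec.coupling,
                seed=np.random.default_rng(ss),
            )
        )
        row = {
            "subject_id": subj.subject_id,
            "age": subj.age,
            "exposure_ms": subj.exposure_ms,
            "education_years": subj.education_years,
        }
        row.update(subj.span_scores)
        subj_rows.append(row)
        for (dim, load), p in subj.params.items():
            truth_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "dimension": dim,
                    "load": load,
                    "alpha": p.alpha,
                    "beta": p.beta,
                    "gamma": p.gamma,
                    "kappa": p.kappa,
                    "sigma": subj.sigma[(dim, load)],
                }
            )
    trials = pd.concat(trial_frames, ignore_index=True)
    return trials, pd.DataFrame(subj_rows), pd.DataFrame(truth_rows)
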