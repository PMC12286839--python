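"""Circular-statistics engine: mean vectors, dispersion, tests, intervals.

This module implements the second-stage circular statistics used throughout
the behavioural and electrophysiological analyses:

* per-trajectory and population mean vectors (first trigonometric moment),
  with the population vector weighting each animal's mean direction by its
  directedness r;
* Moore's modified Rayleigh test for populations of (direction, length)
  vectors, with a seeded Monte-Carlo permutation null;
* the classic Rayleigh test for circular uniformity;
* the Mardia-Watson-Wheeler uniform-scores two-sample test;
* a likelihood-ratio test for a common von Mises mean direction between two
  samples;
* percentile-bootstrap confidence intervals for the population mean
  direction, and the circular standard deviation.

Angles are compass degrees throughout (see :mod:`mothcompass.angles`).
All statistics are rotation-equivariant: rotating every input by a common
offset rotates reported directions by that offset and leaves every test
statistic unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .angles import circ_diff, to_unit_vectors, vector_to_compass, wrap360

__all__ = [
    "MeanVector",
    "MooreResult",
    "TestResult",
    "circ_mean_vector",
    "population_mean_vector",
    "circ_sd",
    "circ_sd_from_r",
    "moore_r_star",
    "moore_rayleigh_test",
    "rayleigh_test",
    "mardia_watson_wheeler",
    "vonmises_lr_common_mean",
    "vonmises_kappa_mle",
    "vonmises_logpdf",
    "circ_confidence_interval",
    "bonferroni",
    "results_table",
]

_EPS_R = 1e-12


@dataclass
class MeanVector:
    """Mean direction ``alpha`` (compass degrees) and resultant length ``r``.

    ``undefined`` is set (and ``alpha`` is NaN) when r is numerically zero,
    in which case the direction carries no information.
    """

    alpha: float
    r: float
    n: int
    undefined: bool = False

    def __post_init__(self):
        if not self.undefined and not 0.0 <= self.r <= 1.0 + 1e-9:
            raise ValueError(f"resultant length r={self.r} outside [0, 1]")


@dataclass
class MooreResult:
    R_star: float
    p_value: float
    n: int
    alpha_pop: float
    ci95_half_angle: float


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    extra: dict = field(default_factory=dict)


def circ_mean_vector(angles, weights=None) -> MeanVector:
    """(Weighted) mean vector of a set of compass angles.

    r is the resultant length divided by the total weight, so equal weights
    reduce exactly to the unweighted mean vector.  An exactly antipodal
    configuration gives r = 0 and an undefined direction (flagged, not an
    exception).
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("need at least one angle")
    if weights is None:
        w = np.ones_like(angles)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        if w.shape != angles.shape:
            raise ValueError("weights must match angles in length")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(w > 0):
            raise ValueError("weights must not all be zero")
    c, s = to_unit_vectors(angles)
    C, S = float(np.sum(w * c)), float(np.sum(w * s))
    r = float(np.hypot(C, S) / np.sum(w))
    if r < _EPS_R:
        return MeanVector(alpha=float("nan"), r=0.0, n=angles.size, undefined=True)
    return MeanVector(alpha=float(vector_to_compass(C, S)), r=min(r, 1.0), n=angles.size)


def population_mean_vector(vectors) -> MeanVector:
    """Population mean vector over per-animal mean vectors.

    Each animal contributes a vector of length r in its mean direction
    ("weighting the mean directions and mean directedness"); the population
    r is the length of the average of those vectors.
    """
    alphas, rs = _split_vectors(vectors)
    c, s = to_unit_vectors(alphas)
    C, S = float(np.sum(rs * c)), float(np.sum(rs * s))
    r = float(np.hypot(C, S) / len(alphas))
    if r < _EPS_R:
        return MeanVector(alpha=float("nan"), r=0.0, n=len(alphas), undefined=True)
    return MeanVector(alpha=float(vector_to_compass(C, S)), r=r, n=len(alphas))


def circ_sd_from_r(rbar) -> float:
    """Circular standard deviation sqrt(-2 ln rbar), in degrees."""
    rbar = float(rbar)
    if rbar <= 0.0:
        return float("inf")
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(min(rbar, 1.0)))))


def circ_sd(angles) -> float:
    """Circular s.d. of a sample of compass angles, in degrees.

    Returns inf (flagged infinite dispersion) for a vanishing resultant.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size < 2:
        raise ValueError("need at least two angles")
    mv = circ_mean_vector(angles)
    return circ_sd_from_r(mv.r)


# ---------------------------------------------------------------------------
# Moore's modified Rayleigh test
# ---------------------------------------------------------------------------


def _split_vectors(vectors):
    alphas = np.array([v.alpha for v in vectors], dtype=float)
    rs = np.array([v.r for v in vectors], dtype=float)
    if np.any((rs < 0) | (rs > 1 + 1e-9)):
        raise ValueError("all vector lengths must lie in [0, 1]")
    return alphas, rs


def moore_r_star(vectors) -> float:
    """Moore's R*: rank-weighted resultant of second-stage vectors.

    Vectors are ranked by length (average ranks on ties); the statistic is
    the length of the sum of rank-weighted unit vectors, normalised by
    n^(3/2).  For n identical unit vectors this equals
    ``sum(1..n) / n^(3/2)`` and it is invariant under common rotation.
    """
    alphas, rs = _split_vectors(vectors)
    n = alphas.size
    ranks = stats.rankdata(rs, method="average")
    c, s = to_unit_vectors(alphas)
    X = np.sum(ranks * c)
    Y = np.sum(ranks * s)
    return float(np.hypot(X, Y) / n**1.5)


def moore_null_sample(n, n_permutations, rng) -> np.ndarray:
    """Monte-Carlo sample of the null distribution of Moore's R* at size n.

    Under the null the direction of each vector is uniform and independent of
    its length, so the rank pairing is exchangeable: R* is distributed as the
    rank-weighted resultant of n uniformly random unit vectors.
    """
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_permutations, n))
    ranks = np.arange(1, n + 1, dtype=float)
    X = np.cos(theta) @ ranks
    Y = np.sin(theta) @ ranks
    return np.hypot(X, Y) / n**1.5


def moore_rayleigh_test(
    vectors, n_permutations: int = 10_000, seed: int = 0,
    n_boot: int = 10_000, ci_level: float = 0.95,
) -> MooreResult:
    """One-sided Moore's modified Rayleigh test on second-stage mean vectors.

    The p-value is the one-sided exceedance probability of the observed R*
    under a seeded Monte-Carlo permutation null (ranks re-paired with
    uniformly redrawn directions), with the +1 correction so p is never
    exactly 0.  Also reports the r-weighted population direction and its
    percentile-bootstrap 95% CI half-angle (NaN when n < 5).
    """
    vectors = list(vectors)
    if len(vectors) < 2:
        raise ValueError("Moore's test needs at least two vectors")
    R = moore_r_star(vectors)
    rng = np.random.default_rng(seed)
    null = moore_null_sample(len(vectors), n_permutations, rng)
    p = (1.0 + np.count_nonzero(null >= R)) / (n_permutations + 1.0)
    pop = population_mean_vector(vectors)
    if len(vectors) >= 5:
        ci = circ_confidence_interval(
            vectors, level=ci_level, n_boot=n_boot,
            seed=int(rng.integers(2**31 - 1)),
        )
    else:
        ci = float("nan")
    return MooreResult(R_star=R, p_value=float(p), n=len(vectors),
                       alpha_pop=pop.alpha, ci95_half_angle=ci)


# ---------------------------------------------------------------------------
# Rayleigh test
# ---------------------------------------------------------------------------


def rayleigh_test(angles) -> TestResult:
    """Classic one-sample Rayleigh test for circular uniformity.

    Uses the standard series approximation of the p-value
    (Zar / Fisher: p = exp(-Z)[1 + (2Z - Z^2)/(4n) - ...]).
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    n = angles.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least two angles")
    mv = circ_mean_vector(angles)
    Z = n * mv.r**2
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z**2) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n**2)
    )
    return TestResult(statistic=float(Z), df=None,
                      p_value=float(np.clip(p, 0.0, 1.0)), method="rayleigh",
                      extra={"n": n, "r": mv.r, "alpha": mv.alpha})


# ---------------------------------------------------------------------------
# Mardia-Watson-Wheeler uniform-scores test
# ---------------------------------------------------------------------------


def mardia_watson_wheeler(sample_a, sample_b) -> TestResult:
    """Two-sample Mardia-Watson-Wheeler (uniform scores) test.

    Pools both samples, converts ranks (average ranks on cross-sample ties)
    to uniform scores beta = 2*pi*rank/N and compares the per-sample score
    resultants.  W is referred to chi-square with 2 d.f.  Sample sizes below
    10 trigger a warning (the chi-square approximation degrades).
    """
    a = np.atleast_1d(np.asarray(sample_a, dtype=float))
    b = np.atleast_1d(np.asarray(sample_b, dtype=float))
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two angles")
    if min(n1, n2) < 10:
        warnings.warn("Mardia-Watson-Wheeler: sample below recommended size 10; "
                      "chi-square approximation may be poor", stacklevel=2)
    N = n1 + n2
    pooled = wrap360(np.concatenate([a, b]))
    ranks = stats.rankdata(pooled, method="average")
    beta = 2.0 * np.pi * ranks / N
    C1 = np.sum(np.cos(beta[:n1]))
    S1 = np.sum(np.sin(beta[:n1]))
    C2 = np.sum(np.cos(beta[n1:]))
    S2 = np.sum(np.sin(beta[n1:]))
    W = 2.0 * ((C1**2 + S1**2) / n1 + (C2**2 + S2**2) / n2)
    return TestResult(statistic=float(W), df=2,
                      p_value=float(stats.chi2.sf(W, 2)), method="MWW",
                      extra={"n1": n1, "n2": n2})


# ---------------------------------------------------------------------------
# von Mises maximum likelihood and the common-mean likelihood-ratio test
# ---------------------------------------------------------------------------


def _bessel_ratio(kappa):
    """A(kappa) = I1(kappa)/I0(kappa), the von Mises mean resultant length."""
    kappa = np.asarray(kappa, dtype=float)
    return special.i1e(kappa) / special.i0e(kappa)


def vonmises_kappa_mle(rbar) -> float:
    """Invert A(kappa) = rbar (ML concentration estimate).

    Fisher's piecewise approximation refined by Newton iterations on
    A(kappa) - rbar, using A'(k) = 1 - A/k - A^2.
    """
    r = float(rbar)
    if r <= 0.0:
        return 0.0
    if r >= 1.0 - 1e-12:
        return 1e8
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    for _ in range(25):
        A = float(_bessel_ratio(k))
        dA = 1.0 - A / k - A * A
        if dA <= 0:
            break
        step = (A - r) / dA
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * (1.0 + k):
            k = k_new
            break
        k = k_new
    return float(max(k, 0.0))


def _log_i0(kappa):
    return np.log(special.i0e(kappa)) + kappa


def vonmises_logpdf(theta_deg, mu_deg, kappa):
    """Log density of the von Mises distribution on compass degrees.

    Density with respect to the angle in radians (integrates to 1 over a
    full turn of radians).
    """
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - mu_deg)
    return kappa * np.cos(d) - np.log(2.0 * np.pi) - _log_i0(kappa)


def _vm_profile_loglik(mu_deg, means, rbars, ns):
    """Profile log-likelihood over kappa_j of samples with common mean mu."""
    total = 0.0
    for mb, rb, n in zip(means, rbars, ns):
        t = rb * np.cos(np.deg2rad(mb - mu_deg))
        k = vonmises_kappa_mle(t) if t > 0 else 0.0
        total += n * (k * t - np.log(2.0 * np.pi) - _log_i0(k))
    return total


def vonmises_lr_common_mean(sample_a, sample_b) -> TestResult:
    """Likelihood-ratio test for equal von Mises mean directions.

    H0: both samples share one mean direction (each with its own
    concentration); H1: separate means.  2*(logL1 - logL0) is referred to
    chi-square with 1 d.f.  Near-uniform samples make the concentration
    estimate unstable and trigger a warning.
    """
    a = np.atleast_1d(np.asarray(sample_a, dtype=float))
    b = np.atleast_1d(np.asarray(sample_b, dtype=float))
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs at least five angles")
    means, rbars, ns = [], [], []
    logL1 = 0.0
    for s in (a, b):
        mv = circ_mean_vector(s)
        if mv.r < 0.05:
            warnings.warn("near-uniform sample: kappa estimate unstable",
                          stacklevel=2)
        means.append(mv.alpha if not mv.undefined else 0.0)
        rbars.append(mv.r)
        ns.append(s.size)
        k = vonmises_kappa_mle(mv.r)
        logL1 += s.size * (k * mv.r - np.log(2.0 * np.pi) - _log_i0(k))

    # The H0 optimum lies on (a neighbourhood of) the arc between the two
    # sample means; profile out the kappas and maximise over mu on a grid
    # refined by golden-section.
    delta = circ_diff(means[1], means[0])
    grid = means[0] + delta * np.linspace(-0.25, 1.25, 61)
    vals = np.array([_vm_profile_loglik(m, means, rbars, ns) for m in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda m: -_vm_profile_loglik(m, means, rbars, ns),
                          bounds=(min(lo, hi), max(lo, hi)), method="bounded",
                          options={"xatol": 1e-6})
    logL0 = -res.fun
    stat = max(2.0 * (logL1 - logL0), 0.0)
    return TestResult(statistic=float(stat), df=1,
                      p_value=float(stats.chi2.sf(stat, 1)),
                      method="vonmises_lr",
                      extra={"mu0": float(wrap360(res.x)),
                             "mu_a": means[0], "mu_b": means[1]})


# ---------------------------------------------------------------------------
# Bootstrap confidence interval for the population mean direction
# ---------------------------------------------------------------------------


def circ_confidence_interval(vectors, level: float = 0.95,
                             n_boot: int = 10_000, seed: int = 0) -> float:
    """Percentile-bootstrap CI half-angle for the weighted population direction.

    Resamples animals (their (alpha, r) mean vectors) with replacement,
    recomputes the r-weighted population direction, and returns half the
    angular width of the central ``level`` interval of the bootstrap
    directions about the point estimate, in degrees.
    """
    vectors = list(vectors)
    n = len(vectors)
    if n < 5:
        raise ValueError("confidence interval needs at least five vectors")
    alphas, rs = _split_vectors(vectors)
    pop = population_mean_vector(vectors)
    if pop.undefined:
        return 180.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    c, s = to_unit_vectors(alphas)
    C = np.sum(rs[idx] * c[idx], axis=1)
    S = np.sum(rs[idx] * s[idx], axis=1)
    ok = np.hypot(C, S) > _EPS_R
    boot_dirs = vector_to_compass(C[ok], S[ok])
    d = circ_diff(boot_dirs, pop.alpha)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(d, [tail, 1.0 - tail])
    return float((hi - lo) / 2.0)


def bonferroni(p_values):
    """Bonferroni adjustment: multiply by family size, cap at 1."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(np.minimum(p * p.size, 1.0))


def results_table(results, p_adjusted=None) -> pd.DataFrame:
    """Serialize test results: one row per test (method, statistic, df, p...)."""
    if p_adjusted is None:
        p_adjusted = [float("nan")] * len(results)
    rows = []
    for res, padj in zip(results, p_adjusted):
        n = res.extra.get("n", res.extra.get("n1"))
        rows.append({"method": res.method, "statistic": res.statistic,
                     "df": res.df, "p_raw": res.p_value, "p_adjusted": padj,
                     "n": n})
    return pd.DataFrame(rows)
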