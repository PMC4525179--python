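"""Interaction-strength distributions and community-matrix assembly.

A trophic link contributes a pair of coefficients to the community matrix:
the (negative) effect X of the consumer on the resource and the (positive)
effect Y of the resource on the consumer.  The pair distribution
Z = (X, Y) is summarized by its five moments (mu_x, mu_y, sigma_x,
sigma_y, rho_xy).  Placing a Z-draw on every link of a web and zeros
elsewhere yields the community matrix M; the statistics of its full upper
and lower triangles (zeros included) — mu_U, mu_L, sigma_U, sigma_L,
rho_UL — are what the stability approximation consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .webgen import FoodWeb, SeedLike, _rng

__all__ = [
    "StrengthDistribution",
    "CommunityMatrix",
    "TriangularMoments",
    "sample_pairs",
    "build_community_matrix",
    "moments_from_Z",
    "empirical_triangular_moments",
    "bodysize_standin",
]

_FAMILIES = {"gaussian_copula_lognormal", "truncated_gaussian", "point_mass"}


@dataclass
class StrengthDistribution:
    """Bivariate pair distribution Z = (X, Y) with X < 0 < Y.

    mu_x / mu_y are the marginal means, sigma_x / sigma_y the marginal
    standard deviations and rho_xy the Pearson correlation.  The family
    tag selects the sign-safe sampling recipe used to realize these
    moments exactly.
    """

    mu_x: float
    mu_y: float
    sigma_x: float = 0.0
    sigma_y: float = 0.0
    rho_xy: float = 0.0
    family: str = "gaussian_copula_lognormal"

    def __post_init__(self) -> None:
        if not self.mu_x < 0:
            raise ValueError(f"mu_x must be negative, got {self.mu_x}")
        if not self.mu_y > 0:
            raise ValueError(f"mu_y must be positive, got {self.mu_y}")
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(self.rho_xy) > 1:
            raise ValueError(f"|rho_xy| must be <= 1, got {self.rho_xy}")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "point_mass" and (self.sigma_x or self.sigma_y or self.rho_xy):
            raise ValueError("point_mass requires sigma_x = sigma_y = rho_xy = 0")


# ---------------------------------------------------------------------------
# samplers

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of log-space normal with given arithmetic mean/sd."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _lognormal_copula_r(s_u: float, s_v: float, target: float) -> float:
    """Gaussian-copula (log-space) correlation giving Pearson correlation
    ``target`` between two lognormals with log-sds s_u, s_v (closed form)."""
    denom = np.sqrt(np.expm1(s_u**2) * np.expm1(s_v**2))
    arg = 1.0 + target * denom
    if arg <= 0:
        raise ValueError(
            f"correlation {target} not attainable for lognormal marginals "
            f"(lower bound {(np.exp(-s_u * s_v) - 1) / denom:.4f})"
        )
    r = np.log(arg) / (s_u * s_v)
    if abs(r) > 1:
        raise ValueError(
            f"correlation {target} not attainable for lognormal marginals "
            f"(requires log-space correlation {r:.4f})"
        )
    return r


def _truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Pre-truncation (loc, scale) of a normal truncated to (0, inf) whose
    post-truncation mean/sd hit the targets (solved numerically)."""

    def eqs(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a = -loc / scale
        m, v = stats.truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, msg = optimize.fsolve(
        eqs, x0=[mean, np.log(sd)], full_output=True
    )
    if ier != 1:
        raise ValueError(f"cannot calibrate truncated-normal marginal: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def _gauss_copula_corr(
    ppf_u, ppf_v, mom_u: tuple[float, float], mom_v: tuple[float, float], r: float,
    nodes: int = 48,
) -> float:
    """Pearson correlation induced by a Gaussian copula with parameter r on
    marginals given by their ppfs (Gauss-Legendre quadrature on the square)."""
    x, w = np.polynomial.legendre.leggauss(nodes)
    u = (x + 1) / 2.0
    wu = w / 2.0
    zu = stats.norm.ppf(u)
    fu = ppf_u(u)
    fv = ppf_v(u)
    if abs(r) == 1.0:
        e_uv = np.sum(wu * fu * (fv if r > 0 else fv[::-1]))
    else:
        # E[f(U) g(V)], (Z1, Z2) standard bivariate normal with corr r,
        # via V | Z1 = z ~ Phi(r z + sqrt(1-r^2) Z2)
        zz = r * zu[:, None] + np.sqrt(1 - r * r) * zu[None, :]
        g = ppf_v(stats.norm.cdf(zz))
        e_uv = np.sum(wu[:, None] * wu[None, :] * fu[:, None] * g)
    mu_u, sd_u = mom_u
    mu_v, sd_v = mom_v
    return (e_uv - mu_u * mu_v) / (sd_u * sd_v)


def _sample_gaussian_copula_lognormal(
    Z: StrengthDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    if Z.sigma_x == 0 or Z.sigma_y == 0:
        if Z.rho_xy != 0 and (Z.sigma_x == 0 or Z.sigma_y == 0):
            raise ValueError("rho_xy must be 0 when a marginal is degenerate")
        x = np.full(n, Z.mu_x) if Z.sigma_x == 0 else None
        y = np.full(n, Z.mu_y) if Z.sigma_y == 0 else None
        if x is None:
            mu, s = _lognormal_params(-Z.mu_x, Z.sigma_x)
            x = -np.exp(rng.normal(mu, s, n))
        if y is None:
            mu, s = _lognormal_params(Z.mu_y, Z.sigma_y)
            y = np.exp(rng.normal(mu, s, n))
        return np.column_stack([x, y])
    mu_u, s_u = _lognormal_params(-Z.mu_x, Z.sigma_x)
    mu_v, s_v = _lognormal_params(Z.mu_y, Z.sigma_y)
    # X = -|X|, so the lognormal magnitudes must correlate at -rho_xy
    r = _lognormal_copula_r(s_u, s_v, -Z.rho_xy)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(n)
    x = -np.exp(mu_u + s_u * z1)
    y = np.exp(mu_v + s_v * z2)
    return np.column_stack([x, y])


def _sample_truncated_gaussian(
    Z: StrengthDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    loc_u, sc_u = _truncnorm_params(-Z.mu_x, Z.sigma_x)
    loc_v, sc_v = _truncnorm_params(Z.mu_y, Z.sigma_y)
    au, av = -loc_u / sc_u, -loc_v / sc_v

    def ppf_u(q):
        return stats.truncnorm.ppf(q, au, np.inf, loc=loc_u, scale=sc_u)

    def ppf_v(q):
        return stats.truncnorm.ppf(q, av, np.inf, loc=loc_v, scale=sc_v)

    target = -Z.rho_xy  # magnitudes correlate at -rho_xy
    if target == 0.0:
        r = 0.0
    else:
        def f(r):
            return _gauss_copula_corr(
                ppf_u, ppf_v, (-Z.mu_x, Z.sigma_x), (Z.mu_y, Z.sigma_y), r
            ) - target

        lo, hi = (-0.999999, 0.0) if target < 0 else (0.0, 0.999999)
        if f(lo) * f(hi) > 0:
            raise ValueError(
                f"correlation {Z.rho_xy} not attainable for truncated-normal marginals"
            )
        r = optimize.brentq(f, lo, hi, xtol=1e-10)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(n)
    x = -ppf_u(stats.norm.cdf(z1))
    y = ppf_v(stats.norm.cdf(z2))
    return np.column_stack([x, y])


def sample_pairs(Z: StrengthDistribution, n: int, seed: SeedLike = None) -> np.ndarray:
    """Draw n independent (x, y) pairs from Z as an (n, 2) array.

    Sign-safe families guarantee x < 0 and y > 0 for every draw while
    matching all five target moments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    if Z.family == "point_mass":
        return np.column_stack([np.full(n, Z.mu_x), np.full(n, Z.mu_y)])
    if Z.family == "gaussian_copula_lognormal":
        return _sample_gaussian_copula_lognormal(Z, n, rng)
    return _sample_truncated_gaussian(Z, n, rng)


# ---------------------------------------------------------------------------
# community matrix

@dataclass
class CommunityMatrix:
    """Dense community matrix M built on a food web.

    In the stored ordering of an acyclic web the upper triangle holds the
    consumer-on-resource effects (<= 0) and the lower triangle the
    resource-on-consumer effects (>= 0); the diagonal is -d.
    """

    S: int
    M: np.ndarray
    d: float = 0.0
    web_ref: Optional[FoodWeb] = None
    ordering: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (self.S, self.S):
            raise ValueError(f"M must be {self.S}x{self.S}")
        if self.ordering is None:
            self.ordering = np.arange(self.S)


def build_community_matrix(
    web: FoodWeb, Z: StrengthDistribution, d: float = 0.0, seed: SeedLike = None
) -> CommunityMatrix:
    """Parameterize a web: one Z-pair per link, zeros elsewhere, diagonal -d.

    For each link K_ij = 1 a pair (x, y) is drawn and placed as
    M_ij = x (effect of consumer j on resource i) and M_ji = y.  Mutual
    predation (K_ij = K_ji = 1, possible in cyclic webs) superposes the
    two interactions: each entry is the sum of the negative effect from
    one link and the positive effect from the other.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    ri, cj = np.nonzero(web.K)
    M = np.zeros((web.S, web.S))
    if ri.size:
        pairs = sample_pairs(Z, ri.size, seed)
        np.add.at(M, (ri, cj), pairs[:, 0])
        np.add.at(M, (cj, ri), pairs[:, 1])
    np.fill_diagonal(M, -d)
    return CommunityMatrix(web.S, M, d=d, web_ref=web)


# ---------------------------------------------------------------------------
# triangular moments

@dataclass
class TriangularMoments:
    """Moments of the full matrix triangles, zeros included.

    mu_U / mu_L are the means of all S(S-1)/2 upper- / lower-triangular
    off-diagonal entries, sigma_U / sigma_L their standard deviations and
    rho_UL the correlation of opposing pairs (M_ij, M_ji), i < j.
    """

    mu_U: float
    mu_L: float
    sigma_U: float
    sigma_L: float
    rho_UL: float
    degenerate: bool = False

    @property
    def cov_UL(self) -> float:
        return self.rho_UL * self.sigma_U * self.sigma_L


def moments_from_Z(Z: StrengthDistribution, C: float) -> TriangularMoments:
    """Analytic triangle moments of a cascade-parameterized matrix.

    A triangle entry is 0 with probability 1 - C and a Z-draw with
    probability C (Bernoulli mixture); opposing entries share the same
    Bernoulli indicator.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError("C must be a probability")
    mu_U = C * Z.mu_x
    mu_L = C * Z.mu_y
    var_U = C * Z.sigma_x**2 + C * (1 - C) * Z.mu_x**2
    var_L = C * Z.sigma_y**2 + C * (1 - C) * Z.mu_y**2
    cov = C * Z.rho_xy * Z.sigma_x * Z.sigma_y + C * (1 - C) * Z.mu_x * Z.mu_y
    sigma_U, sigma_L = np.sqrt(var_U), np.sqrt(var_L)
    if sigma_U == 0 or sigma_L == 0:
        return TriangularMoments(mu_U, mu_L, sigma_U, sigma_L, 0.0, degenerate=True)
    return TriangularMoments(mu_U, mu_L, sigma_U, sigma_L, cov / (sigma_U * sigma_L))


def empirical_triangular_moments(
    mat: Union[CommunityMatrix, np.ndarray],
    ordering: Optional[Sequence[int]] = None,
) -> TriangularMoments:
    """Measure the five triangle moments of a matrix in a given ordering.

    The matrix is permuted by ``ordering`` (species listed in display
    order), the diagonal excluded, and the moments taken over all
    S(S-1)/2 upper (resp. lower) entries and the opposing pairs.
    """
    M = mat.M if isinstance(mat, CommunityMatrix) else np.asarray(mat, dtype=float)
    if ordering is not None:
        ordering = np.asarray(ordering)
        M = M[np.ix_(ordering, ordering)]
    iu, ju = np.triu_indices(M.shape[0], k=1)
    upper = M[iu, ju]
    lower = M[ju, iu]
    mu_U, mu_L = upper.mean(), lower.mean()
    sigma_U, sigma_L = upper.std(), lower.std()
    if sigma_U == 0 or sigma_L == 0:
        return TriangularMoments(mu_U, mu_L, sigma_U, sigma_L, 0.0, degenerate=True)
    cov = np.mean(upper * lower) - mu_U * mu_L
    return TriangularMoments(mu_U, mu_L, sigma_U, sigma_L, cov / (sigma_U * sigma_L))


# ---------------------------------------------------------------------------
# body-size stand-in

_SCENARIOS = {
    # moments chosen to emulate a body-size-scaling parameterization:
    # unit-scale negative effects, ~20% conversion efficiency, strongly
    # negatively correlated pairs, moderate tails (CV = 0.5).
    "default": dict(mu_x=-1.0, mu_y=0.2, sigma_x=0.5, sigma_y=0.1, rho_xy=-0.7),
    # positive effects an order of magnitude weaker than negative ones
    "weak_positive": dict(mu_x=-1.0, mu_y=0.05, sigma_x=0.5, sigma_y=0.025, rho_xy=-0.7),
    # dominance reversed: positive effects outweigh negative ones
    "strong_positive": dict(mu_x=-0.2, mu_y=1.0, sigma_x=0.1, sigma_y=0.5, rho_xy=-0.7),
}


def bodysize_standin(scenario: str = "default", **overrides) -> StrengthDistribution:
    """Synthetic stand-in for a body-size-derived pair distribution.

    The moments are configuration, not science: they give a sign-safe
    distribution in the regime the scenario names — ``default`` and
    ``weak_positive`` are negative-dominant (|mu_x| C > mu_y C),
    ``strong_positive`` reverses the dominance.  Any moment can be
    overridden by keyword.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be one of {sorted(_SCENARIOS)}")
    params = {**_SCENARIOS[scenario], **overrides}
    return StrengthDistribution(family="gaussian_copula_lognormal", **params)
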