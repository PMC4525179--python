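"""Analytic stability approximation via the signal/noise decomposition.

The community matrix is split as M = A + B: A carries the triangular means
(all upper entries mu_U, all lower entries mu_L, zero diagonal) and B the
zero-mean residual.  The spectrum of A lies on a circle in the complex
plane with closed-form eigenvalues; the spectrum of B approximately fills
an ellipse generalizing the elliptic law to unequal triangle variances.
The real part of the leading eigenvalue of M is approximated by

    Re(lambda_M,1)  ~  Re(lambda_A,1) + r_h(B) - d,

which is the minimum per-capita self-regulation that would stabilize the
community.  May's criterion and the elliptic-law estimate of Tang et al.
are provided as comparison baselines.

Closed form for A
-----------------
The eigenvector recurrence of A closes when q^S = mu_L / mu_U, giving the
S eigenvalues

    lambda_k = (mu_U q_k - mu_L) / (1 - q_k),

with q_k the complex S-th roots of mu_L / mu_U.  All q_k lie on the circle
|q| = r = |mu_L/mu_U|^(1/S), and the Moebius map above sends that circle to
the circle with centre c_A = (mu_U r^2 - mu_L)/(1 - r^2) and radius
r_A = |mu_U - mu_L| r / |1 - r^2|.  In the food-web case (mu_U < 0 < mu_L,
-mu_U > mu_L) the bulk of the eigenvalues sits just right of the imaginary
axis and 0 <= Re(lambda_A,1) <= -mu_U with Re(lambda_A,1) ~ c_A + r_A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .strengths import (
    CommunityMatrix,
    StrengthDistribution,
    TriangularMoments,
    empirical_triangular_moments,
    moments_from_Z,
)

__all__ = [
    "CircleSpec",
    "EllipseSpec",
    "StabilityPrediction",
    "mean_matrix_spectrum",
    "noise_ellipse",
    "predict_stability",
    "numeric_leading_eigenvalue",
    "may_prediction",
    "tang_prediction",
    "regime_check",
    "build_mean_matrix",
]

DENSE_EIG_LIMIT = 2000  # largest S for which full dense eigendecomposition is attempted


@dataclass
class CircleSpec:
    """Spectrum of the deterministic mean matrix A."""

    c_A: float
    r_A: float
    eigenvalues: np.ndarray
    re_leading: float
    degenerate: bool = False
    method: str = "closed_form"


@dataclass
class EllipseSpec:
    """Ellipse filled by the spectrum of the zero-mean noise matrix B."""

    alpha: float
    r_h: float
    r_v: float
    center: tuple = (0.0, 0.0)
    low_confidence: bool = False


@dataclass
class StabilityPrediction:
    """Predicted Re(lambda_M,1) with its components and comparison values."""

    re_lambda_A: float
    r_h_B: float
    predicted: float
    regime: str
    may_value: float
    tang_value: float
    moments: TriangularMoments
    circle: CircleSpec
    ellipse: EllipseSpec
    d: float = 0.0
    numeric_value: Optional[float] = None
    flags: list = field(default_factory=list)


def build_mean_matrix(mu_U: float, mu_L: float, S: int) -> np.ndarray:
    """Explicit S x S matrix with mu_U above and mu_L below the diagonal."""
    return np.triu(np.full((S, S), float(mu_U)), 1) + np.tril(
        np.full((S, S), float(mu_L)), -1
    )


def mean_matrix_spectrum(mu_U: float, mu_L: float, S: int) -> CircleSpec:
    """Closed-form spectrum of the mean matrix A.

    Falls back to dense eigendecomposition in the degenerate case
    mu_L / mu_U = 1 (the Moebius image passes through the pole and the
    circle degenerates).
    """
    if S < 2:
        raise ValueError("S must be >= 2")
    if mu_U == 0.0 and mu_L == 0.0:
        raise ValueError("mu_U and mu_L must not both be zero")
    if mu_U == 0.0 or mu_L == 0.0:
        # strictly triangular -> nilpotent: every eigenvalue is 0
        eig = np.zeros(S, dtype=complex)
        return CircleSpec(0.0, 0.0, eig, 0.0)
    ratio = mu_L / mu_U
    if ratio == 1.0:
        eig = np.linalg.eigvals(build_mean_matrix(mu_U, mu_L, S))
        return CircleSpec(
            np.nan, np.nan, eig, float(eig.real.max()),
            degenerate=True, method="numeric_fallback",
        )
    r = abs(ratio) ** (1.0 / S)
    k = np.arange(S)
    ang = (np.angle(complex(ratio)) + 2.0 * np.pi * k) / S
    q = r * np.exp(1j * ang)
    eig = (mu_U * q - mu_L) / (1.0 - q)
    re_leading = float(eig.real.max())
    if abs(1.0 - r * r) < 1e-12:
        # |mu_L| = |mu_U| with opposite signs: the circle degenerates to the
        # vertical line Re = -(mu_U + mu_L)/2; eigenvalues remain exact.
        return CircleSpec(np.nan, np.inf, eig, re_leading, degenerate=True)
    c_A = (mu_U * r * r - mu_L) / (1.0 - r * r)
    r_A = abs(mu_U - mu_L) * r / abs(1.0 - r * r)
    return CircleSpec(float(c_A), float(r_A), eig, re_leading)


def noise_ellipse(
    sigma_U: float, sigma_L: float, cov_UL: float, S: int
) -> EllipseSpec:
    """Generalized-elliptic-law semi-axes for the noise matrix B.

    alpha = S (sigma_U^2 - sigma_L^2) / log(sigma_U^2 / sigma_L^2), with
    the removable singularity at equal variances evaluated as S sigma^2;
    r_h = (alpha + cov_UL (S-1)) / sqrt(alpha) and r_v the mirror image.
    At equal variances this is exactly the elliptic law.
    """
    if sigma_U < 0 or sigma_L < 0:
        raise ValueError("standard deviations must be non-negative")
    if abs(cov_UL) > sigma_U * sigma_L + 1e-12:
        raise ValueError("|cov_UL| must be <= sigma_U * sigma_L")
    if sigma_U == 0.0 and sigma_L == 0.0:
        return EllipseSpec(0.0, 0.0, 0.0)
    if sigma_U == 0.0 or sigma_L == 0.0:
        # log ratio diverges; the limit of alpha (and of both semi-axes) is 0
        return EllipseSpec(0.0, 0.0, 0.0, low_confidence=True)
    vU, vL = sigma_U**2, sigma_L**2
    if vU == vL:
        alpha = S * vU
    else:
        alpha = S * (vU - vL) / np.log(vU / vL)
    sq = np.sqrt(alpha)
    r_h = (alpha + cov_UL * (S - 1)) / sq
    r_v = (alpha - cov_UL * (S - 1)) / sq
    return EllipseSpec(float(alpha), float(r_h), float(r_v))


def regime_check(mu_U: float, mu_L: float) -> str:
    """negative_dominant iff the mean negative effect outweighs the positive."""
    return "negative_dominant" if -mu_U > mu_L else "positive_dominant"


def _may_tang_from_moments(
    mom: TriangularMoments, S: int, d: float
) -> tuple[float, float]:
    """May and Tang et al. baselines, treating off-diagonal entries as
    exchangeable: E = (mu_U + mu_L)/2, V = (sigma_U^2 + sigma_L^2)/2 +
    (mu_U - mu_L)^2/4, pair correlation (cov_UL - (mu_U-mu_L)^2/4)/V."""
    E = (mom.mu_U + mom.mu_L) / 2.0
    split = (mom.mu_U - mom.mu_L) ** 2 / 4.0
    V = (mom.sigma_U**2 + mom.sigma_L**2) / 2.0 + split
    if V <= 0:
        raise ValueError("exchangeable variance V must be positive")
    rho = (mom.cov_UL - split) / V
    may = np.sqrt(S * V) - d
    tang = np.sqrt(S * V) * (1.0 + rho) - E - d
    return float(may), float(tang)


def may_prediction(S: int, C: float, Z: StrengthDistribution, d: float = 0.0) -> float:
    """May's complexity criterion sqrt(S V) - d (ignores means and pair
    correlation)."""
    return _may_tang_from_moments(moments_from_Z(Z, C), S, d)[0]


def tang_prediction(S: int, C: float, Z: StrengthDistribution, d: float = 0.0) -> float:
    """Tang et al.'s elliptic-law estimate sqrt(S V)(1 + rho) - E - d for an
    unstructured (exchangeable) random web."""
    return _may_tang_from_moments(moments_from_Z(Z, C), S, d)[1]


def _predict_from_moments(
    mom: TriangularMoments, S: int, d: float
) -> StabilityPrediction:
    regime = regime_check(mom.mu_U, mom.mu_L)
    circle = mean_matrix_spectrum(mom.mu_U, mom.mu_L, S)
    ellipse = noise_ellipse(mom.sigma_U, mom.sigma_L, mom.cov_UL, S)
    predicted = circle.re_leading + ellipse.r_h - d
    may, tang = _may_tang_from_moments(mom, S, d)
    flags = []
    if regime == "positive_dominant":
        flags.append(
            "positive_dominant: stability governed by a complex pair; the "
            "spectrum of M is flipped around the imaginary axis"
        )
    if circle.degenerate:
        flags.append("mean-matrix circle degenerate")
    if ellipse.low_confidence:
        flags.append("noise ellipse low-confidence (a triangle variance is 0)")
    return StabilityPrediction(
        re_lambda_A=circle.re_leading,
        r_h_B=ellipse.r_h,
        predicted=float(predicted),
        regime=regime,
        may_value=may,
        tang_value=tang,
        moments=mom,
        circle=circle,
        ellipse=ellipse,
        d=d,
        flags=flags,
    )


def predict_stability(
    target: Union[CommunityMatrix, int],
    Z: Optional[StrengthDistribution] = None,
    C: Optional[float] = None,
    d: Optional[float] = None,
    ordering: Optional[Sequence[int]] = None,
) -> StabilityPrediction:
    """Approximate Re(lambda_M,1) = Re(lambda_A,1) + r_h(B) - d.

    Two modes:

    * analytic — ``predict_stability(S, Z=Z, C=C, d=d)``: triangle moments
      computed from the pair distribution and connectance;
    * empirical — ``predict_stability(mat, ordering=perm)``: moments
      measured on the community matrix after permuting species by
      ``ordering`` (the most-upper-triangular order for cyclic webs);
      ``d`` defaults to the matrix's own self-regulation.
    """
    if isinstance(target, CommunityMatrix):
        mat = target
        mom = empirical_triangular_moments(mat, ordering)
        return _predict_from_moments(mom, mat.S, mat.d if d is None else d)
    S = int(target)
    if Z is None or C is None:
        raise ValueError("analytic mode requires Z and C")
    return _predict_from_moments(moments_from_Z(Z, C), S, 0.0 if d is None else d)


def numeric_leading_eigenvalue(
    mat: Union[CommunityMatrix, np.ndarray], dense_limit: int = DENSE_EIG_LIMIT
) -> complex:
    """Eigenvalue of maximal real part from a full dense eigendecomposition.

    Ties in the real part are broken by the larger imaginary part, so a
    leading conjugate pair is reported by its upper member.
    """
    M = mat.M if isinstance(mat, CommunityMatrix) else np.asarray(mat, dtype=float)
    if M.shape[0] > dense_limit:
        raise ValueError(f"S={M.shape[0]} exceeds dense eigendecomposition limit")
    if not np.isfinite(M).all():
        raise ValueError("matrix contains non-finite entries")
    eig = np.linalg.eigvals(M)
    order = np.lexsort((eig.imag, eig.real))
    return complex(eig[order[-1]])
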