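"""Closed-form spectra, the generalized ellipse and the stability prediction."""

import numpy as np
import pytest

import webstab as ws


def _hausdorff(a, b):
    a, b = np.asarray(a), np.asarray(b)
    d1 = max(np.min(np.abs(a[i] - b)) for i in range(len(a)))
    d2 = max(np.min(np.abs(b[i] - a)) for i in range(len(b)))
    return max(d1, d2)


def test_closed_form_matches_dense_eigendecomposition():
    """100 random (mu_U, mu_L) pairs across sizes: closed-form multiset equals
    the dense spectrum of the explicit matrix to 1e-8."""
    rng = np.random.default_rng(20)
    for case in range(100):
        S = int(rng.choice([5, 20, 50, 200]))
        mu_U = float(rng.uniform(-2, 2)) or 0.5
        mu_L = float(rng.uniform(-2, 2)) or -0.5
        if mu_L / mu_U == 1.0:
            continue
        spec = ws.mean_matrix_spectrum(mu_U, mu_L, S)
        dense = np.linalg.eigvals(ws.build_mean_matrix(mu_U, mu_L, S))
        assert _hausdorff(spec.eigenvalues, dense) < 1e-8


def test_closed_form_eigenvalues_lie_on_circle():
    rng = np.random.default_rng(21)
    for case in range(20):
        S = int(rng.choice([10, 50, 200]))
        mu_U = float(rng.uniform(-2, -0.1))
        mu_L = float(rng.uniform(0.05, -mu_U))
        spec = ws.mean_matrix_spectrum(mu_U, mu_L, S)
        assert not spec.degenerate
        assert np.max(np.abs(np.abs(spec.eigenvalues - spec.c_A) - spec.r_A)) < 1e-8


def test_skew_symmetric_case_purely_imaginary():
    spec = ws.mean_matrix_spectrum(-1.0, 1.0, 40)
    assert spec.degenerate
    assert np.max(np.abs(spec.eigenvalues.real)) < 1e-10
    assert spec.re_leading == pytest.approx(0.0, abs=1e-10)


def test_equal_means_fallback_is_rank_one_shift():
    # A = mu (J - I): eigenvalues S-1 and -1 (S-1 times), scaled by mu
    spec = ws.mean_matrix_spectrum(1.0, 1.0, 30)
    assert spec.method == "numeric_fallback"
    vals = np.sort(spec.eigenvalues.real)
    assert vals[-1] == pytest.approx(29.0, abs=1e-8)
    assert np.allclose(vals[:-1], -1.0, atol=1e-8)


def test_nilpotent_when_one_mean_zero():
    for mu_U, mu_L in [(0.0, 0.7), (-0.7, 0.0)]:
        spec = ws.mean_matrix_spectrum(mu_U, mu_L, 25)
        assert np.max(np.abs(spec.eigenvalues)) < 1e-10


def test_leading_real_part_bounds_negative_dominant():
    """0 <= Re(lambda_A,1) <= -mu_U whenever -mu_U > mu_L > 0."""
    rng = np.random.default_rng(22)
    for case in range(100):
        S = int(rng.integers(10, 1000))
        mu_U = float(rng.uniform(-2, -0.01))
        mu_L = float(rng.uniform(1e-6, -mu_U))
        re1 = ws.mean_matrix_spectrum(mu_U, mu_L, S).re_leading
        assert -1e-10 <= re1 <= -mu_U + 1e-10


def test_leading_approximation_c_plus_r():
    rng = np.random.default_rng(23)
    for case in range(20):
        S = int(rng.integers(100, 1500))
        mu_U = float(rng.uniform(-2, -0.1))
        mu_L = float(rng.uniform(0.02, -mu_U * 0.9))
        spec = ws.mean_matrix_spectrum(mu_U, mu_L, S)
        assert spec.re_leading == pytest.approx(spec.c_A + spec.r_A, rel=0.02)


def test_bulk_eigenvalues_have_nonnegative_real_part():
    """Negative-dominant regime: all but o(S) eigenvalues of A sit at or right
    of the imaginary axis; the few large-modulus ones are negative."""
    spec = ws.mean_matrix_spectrum(-1.0, 0.2, 500)
    re = spec.eigenvalues.real
    mod = np.abs(spec.eigenvalues)
    assert np.mean(re >= -1e-10) > 0.9
    neg = re < -1e-10
    assert 0 < neg.sum() < 0.1 * 500
    assert mod[neg].min() > 10 * np.median(mod)


def test_spectrum_mirror_under_regime_flip():
    """A(mu_U, mu_L) and -A(-mu_L, -mu_U)^T share their spectrum: the
    positive-dominant spectrum is the negative-dominant one flipped around
    the imaginary axis."""
    a = ws.mean_matrix_spectrum(-1.0, 0.5, 50).eigenvalues
    b = ws.mean_matrix_spectrum(-0.5, 1.0, 50).eigenvalues
    assert _hausdorff(np.sort_complex(a), np.sort_complex(-b)) < 1e-8


def test_regime_check():
    assert ws.regime_check(-1.0, 0.5) == "negative_dominant"
    assert ws.regime_check(-0.5, 1.0) == "positive_dominant"


# ---------------------------------------------------------------------------
# noise ellipse

def test_ellipse_equal_variances_is_elliptic_law():
    ell = ws.noise_ellipse(0.5, 0.5, 0.0, 400)
    assert ell.r_h == ell.r_v == pytest.approx(np.sqrt(400 * 0.25))
    rho = -0.6
    ell2 = ws.noise_ellipse(0.5, 0.5, rho * 0.25, 400)
    assert ell2.r_h == pytest.approx(np.sqrt(400 * 0.25) * (1 + rho * 399 / 400))


def test_ellipse_continuous_at_equal_variances():
    eps = 1e-9
    a = ws.noise_ellipse(1.0, 1.0, -0.3, 500)
    b = ws.noise_ellipse(1.0 + eps, 1.0, -0.3, 500)
    assert abs(a.r_h - b.r_h) < 1e-6 and abs(a.r_v - b.r_v) < 1e-6


def test_ellipse_degenerate_cases():
    assert ws.noise_ellipse(0.0, 0.0, 0.0, 100).r_h == 0.0
    one_sided = ws.noise_ellipse(1.0, 0.0, 0.0, 100)
    assert one_sided.low_confidence and one_sided.r_h == 0.0
    with pytest.raises(ValueError):
        ws.noise_ellipse(1.0, 1.0, 2.0, 100)


def test_ellipse_against_sampled_noise_matrices():
    """r_h tracks the observed leading real part of mean-zero matrices with
    the same triangle statistics (Monte-Carlo oracle)."""
    S, sU, sL, rho = 1000, 2.0, 1.0, -0.5
    cov = rho * sU * sL
    ell = ws.noise_ellipse(sU, sL, cov, S)
    rng = np.random.default_rng(24)
    iu, ju = np.triu_indices(S, 1)
    obs = []
    for rep in range(20):
        z = rng.standard_normal((iu.size, 2))
        u = sU * z[:, 0]
        l = sL * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])
        B = np.zeros((S, S))
        B[iu, ju] = u
        B[ju, iu] = l
        obs.append(np.linalg.eigvals(B).real.max())
    assert abs(ell.r_h - np.mean(obs)) / np.mean(obs) < 0.10


# ---------------------------------------------------------------------------
# prediction and baselines

def test_point_mass_prediction_is_circle_only(complete_cascade_web, point_mass_Z):
    mat = ws.build_community_matrix(complete_cascade_web, point_mass_Z, d=0.2, seed=0)
    pred = ws.predict_stability(mat)
    assert pred.r_h_B == 0.0
    assert pred.predicted == pytest.approx(pred.re_lambda_A - 0.2)


def test_analytic_prediction_tracks_numeric(default_Z):
    rng = np.random.default_rng(25)
    errs = []
    for rep in range(8):
        S, C = 500, float(rng.uniform(0.15, 0.3))
        web = ws.generate_cascade(S, C, seed=rng)
        mat = ws.build_community_matrix(web, default_Z, seed=rng)
        obs = ws.numeric_leading_eigenvalue(mat).real
        pred = ws.predict_stability(S, Z=default_Z, C=C)
        errs.append(abs(pred.predicted - obs) / abs(obs))
    assert np.median(errs) < 0.05


def test_prediction_diagonal_shift_identity(default_Z):
    p0 = ws.predict_stability(500, Z=default_Z, C=0.2, d=0.0)
    p1 = ws.predict_stability(500, Z=default_Z, C=0.2, d=0.7)
    assert p1.predicted == pytest.approx(p0.predicted - 0.7, abs=1e-12)


def test_positive_dominant_prediction_flagged():
    strong = ws.bodysize_standin("strong_positive")
    pred = ws.predict_stability(200, Z=strong, C=0.2)
    assert pred.regime == "positive_dominant"
    assert any("positive_dominant" in f for f in pred.flags)


def test_may_tang_relationship(default_Z):
    """With zero exchangeable pair correlation the ellipse degenerates to the
    circle and tang = may - E.  rho~ = 0 requires cov_UL to offset the
    mean-split term (mu_U - mu_L)^2/4: at C=1 choose rho_xy sigma_x sigma_y
    = (mu_x - mu_y)^2/4."""
    Z = ws.StrengthDistribution(-1.0, 1.0, 2.0, 2.0, 0.25)
    C, S = 1.0, 300
    may = ws.may_prediction(S, C, Z)
    tang = ws.tang_prediction(S, C, Z)
    E = (Z.mu_x + Z.mu_y) / 2.0
    assert tang == pytest.approx(may - E, abs=1e-9)


def test_tang_accurate_on_unstructured_webs(default_Z):
    """Randomly oriented pairs (no cascade hierarchy) are the exchangeable
    regime where the elliptic-law estimate applies."""
    S, C = 500, 0.2
    errs = []
    for rep in range(5):
        rng = np.random.default_rng(100 + rep)
        iu, ju = np.triu_indices(S, 1)
        link = rng.random(iu.size) < C
        pairs = ws.sample_pairs(default_Z, int(link.sum()), rng)
        flip = rng.random(int(link.sum())) < 0.5
        x = np.where(flip, pairs[:, 1], pairs[:, 0])
        y = np.where(flip, pairs[:, 0], pairs[:, 1])
        M = np.zeros((S, S))
        M[iu[link], ju[link]] = x
        M[ju[link], iu[link]] = y
        obs = np.linalg.eigvals(M).real.max()
        errs.append(abs(ws.tang_prediction(S, C, default_Z) - obs) / abs(obs))
    assert np.median(errs) < 0.05


def test_numeric_leading_eigenvalue_basics():
    assert ws.numeric_leading_eigenvalue(np.diag([-1.0, -2.0, 3.0])) == 3.0 + 0j
    rng = np.random.default_rng(26)
    M = rng.standard_normal((60, 60))
    lead = ws.numeric_leading_eigenvalue(M)
    eig = np.linalg.eigvals(M)
    # spectrum closed under conjugation; reported member has imag >= 0
    assert np.min(np.abs(eig - np.conj(lead))) < 1e-10
    assert lead.imag >= 0 or abs(lead.imag) < 1e-12
    perm = rng.permutation(60)
    assert ws.numeric_leading_eigenvalue(M[np.ix_(perm, perm)]) == pytest.approx(
        lead, abs=1e-10
    )
    with pytest.raises(ValueError):
        ws.numeric_leading_eigenvalue(np.array([[np.nan, 0], [0, 1.0]]))
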