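"""Geometry statistics: hand-checked values, bounds and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latentgeom import (
    GaussianCode,
    InvalidCodeError,
    UndefinedMetricError,
    geometry_summary,
    neural_latent_correlation,
    noise_covariance,
    participation_ratio,
    snf,
    ssf,
    theoretical_error,
)
from conftest import random_valid_code


class TestParticipationRatio:
    @pytest.mark.parametrize(
        "diag, expected",
        [
            ([1.0, 1.0, 1.0], 3.0),     # isotropic: full dimension
            ([1.0, 0.0, 0.0], 1.0),     # rank one
            ([3.0, 1.0], 1.6),          # (3+1)^2 / (9+1)
        ],
    )
    def test_diagonal_cases(self, diag, expected):
        assert participation_ratio(np.diag(diag)) == pytest.approx(expected)

    def test_rejects_zero_trace(self):
        with pytest.raises(InvalidCodeError):
            participation_ratio(np.zeros((3, 3)))

    def test_bounds_on_random_psd(self, rng):
        for _ in range(20):
            a = rng.standard_normal((5, 5))
            pr = participation_ratio(a @ a.T)
            assert 1.0 - 1e-12 <= pr <= 5.0 + 1e-12


class TestCorrelation:
    def test_zero_phi(self):
        code = GaussianCode(psi=np.eye(3), phi=np.zeros((3, 2)),
                            omega=np.eye(2))
        assert neural_latent_correlation(code) == 0.0

    def test_perfect_scalar_code(self):
        # x = z in one dimension: c = omega^2 / (omega * omega) = 1
        code = GaussianCode(psi=[[2.0]], phi=[[2.0]], omega=[[2.0]])
        assert neural_latent_correlation(code) == pytest.approx(1.0)

    @pytest.mark.parametrize("d", [2, 3, 4, 5])
    def test_whitened_code_is_one_over_d(self, d):
        om = np.diag(np.linspace(2.0, 1.0, d))
        code = GaussianCode(psi=np.eye(d), phi=np.sqrt(om), omega=om)
        assert neural_latent_correlation(code) == pytest.approx(1.0 / d)


class TestNoiseCovariance:
    def test_noiseless_linear_code_is_zero(self, rng):
        a = rng.standard_normal((5, 3))
        om = np.eye(3)
        code = GaussianCode(psi=a @ a.T, phi=a, omega=om)
        assert np.allclose(noise_covariance(code), 0.0, atol=1e-10)

    def test_additive_noise_recovered(self):
        sigma2 = 0.7
        d = 4
        code = GaussianCode(psi=(1 + sigma2) * np.eye(d), phi=np.eye(d),
                            omega=np.eye(d))
        assert np.allclose(noise_covariance(code), sigma2 * np.eye(d))

    def test_zero_phi_returns_psi(self, rng):
        psi = np.diag([2.0, 1.0, 0.5])
        code = GaussianCode(psi=psi, phi=np.zeros((3, 2)), omega=np.eye(2))
        assert np.allclose(noise_covariance(code), psi)


class TestFactorizations:
    def test_ssf_single_latent_is_one(self, rng):
        phi = rng.standard_normal((4, 1))
        code = GaussianCode(psi=phi @ phi.T + np.eye(4), phi=phi,
                            omega=[[1.0]])
        assert ssf(code) == pytest.approx(1.0)

    def test_ssf_whitened_equality(self):
        # phi^T phi proportional to omega -> Cauchy-Schwarz equality
        om = np.diag([4.0, 2.0, 1.0])
        code = GaussianCode(psi=np.eye(3), phi=np.sqrt(om), omega=om)
        assert ssf(code) == pytest.approx(1.0)

    def test_ssf_identity_code_hand_value(self):
        # x = z, omega = diag(3,1): f = (Tr om^2)^2 / (Tr om * Tr om^3)
        om = np.diag([3.0, 1.0])
        code = GaussianCode(psi=om, phi=om, omega=om)
        assert ssf(code) == pytest.approx(100.0 / 112.0)

    def test_ssf_undefined_for_zero_phi(self):
        code = GaussianCode(psi=np.eye(2), phi=np.zeros((2, 2)),
                            omega=np.eye(2))
        with pytest.raises(UndefinedMetricError):
            ssf(code)

    def test_snf_infinite_for_noiseless(self, rng):
        code = random_valid_code(rng, noiseless=True)
        assert np.isinf(snf(code))

    @pytest.mark.parametrize("sigma2", [1.0, 4.0])
    def test_snf_isotropic_noise(self, sigma2):
        d = 3
        code = GaussianCode(psi=(1 + sigma2) * np.eye(d), phi=np.eye(d),
                            omega=np.eye(d))
        assert snf(code) == pytest.approx(1.0 / sigma2)


class TestGeometrySummary:
    def test_matches_individual_metrics(self, noisy_identity_code):
        s = geometry_summary(noisy_identity_code)
        assert s.c == neural_latent_correlation(noisy_identity_code)
        assert s.pr == participation_ratio(noisy_identity_code.psi)
        assert s.f == ssf(noisy_identity_code)
        assert s.s == snf(noisy_identity_code)

    def test_whitened_composite(self):
        d = 4
        om = np.diag([5.0, 2.5, 1.0, 0.5])
        code = GaussianCode(psi=np.eye(d), phi=np.sqrt(om), omega=om)
        s = geometry_summary(code)
        assert s.c == pytest.approx(1.0 / d)
        assert s.pr == pytest.approx(d)
        assert s.f == pytest.approx(1.0)
        assert np.isinf(s.s)


class TestTheoreticalError:
    def test_arctan_one_gives_quarter(self):
        # fewshot + irreducible = 2 gives arctan(1)/pi = 1/4 exactly:
        # f=1, s=2 (irreducible 1.5) and c^2 PR = pi/4 at p=4 (fewshot 0.5)
        from latentgeom import GeometrySummary
        summary = GeometrySummary(c=float(np.sqrt(np.pi) / 2), pr=1.0,
                                  f=1.0, s=2.0)
        pred = theoretical_error(summary, 4)
        assert pred.fewshot_term == pytest.approx(0.5)
        assert pred.irreducible_term == pytest.approx(1.5)
        assert pred.e_g == pytest.approx(0.25)

    def test_perfect_code_large_p_goes_to_zero(self):
        d = 3
        om = np.eye(d)
        code = GaussianCode(psi=np.eye(d), phi=np.eye(d), omega=om)
        s = geometry_summary(code)
        assert theoretical_error(s, 10**9).e_g < 1e-3

    def test_chance_flag_for_uninformative_code(self):
        from latentgeom import GeometrySummary
        zero = GeometrySummary(c=0.0, pr=3.0, f=0.8, s=1.0)
        pred = theoretical_error(zero, 100)
        assert pred.e_g == 0.5 and pred.chance

    def test_strictly_decreasing_in_p(self, rng):
        s = geometry_summary(random_valid_code(rng))
        errs = [theoretical_error(s, p).e_g for p in (1, 5, 20, 100, 1000)]
        assert np.all(np.diff(errs) < 0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000),
       a=st.floats(0.1, 10.0), b=st.floats(0.1, 10.0))
def test_metrics_scale_invariant(seed, a, b):
    """psi -> a^2 psi, phi -> ab phi, omega -> b^2 omega leaves all metrics
    and the predicted error unchanged."""
    rng = np.random.default_rng(seed)
    code = random_valid_code(rng)
    scaled = GaussianCode(psi=a**2 * code.psi, phi=a * b * code.phi,
                          omega=b**2 * code.omega)
    s0, s1 = geometry_summary(code), geometry_summary(scaled)
    assert s1.c == pytest.approx(s0.c, rel=1e-9)
    assert s1.pr == pytest.approx(s0.pr, rel=1e-9)
    assert s1.f == pytest.approx(s0.f, rel=1e-9)
    assert s1.s == pytest.approx(s0.s, rel=1e-9)
    assert theoretical_error(s1, 50).e_g == pytest.approx(
        theoretical_error(s0, 50).e_g, rel=1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_random_code_bounds(seed):
    """On random realizable codes: f in (0, 1], PR in [1, n], e_g in [0, 0.5)."""
    rng = np.random.default_rng(seed)
    code = random_valid_code(rng)
    s = geometry_summary(code)
    assert 0.0 < s.f <= 1.0 + 1e-8
    assert 1.0 - 1e-9 <= s.pr <= code.n + 1e-9
    assert s.c >= 0.0
    for p in (1, 10, 1000):
        e = theoretical_error(s, p).e_g
        assert 0.0 <= e < 0.5
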