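"""Synthetic generators: spectra, sampling, codes, estimation, projections."""

import numpy as np
import pytest

from latentgeom import (
    LinearCodeSpec,
    MlpSpec,
    PowerLawSpectrumSpec,
    apply_code,
    estimate_covariances,
    geometry_summary,
    power_law_omega,
    random_projection,
    sample_gaussian_latents,
    theoretical_error,
    zscore_columns,
)
from latentgeom.synth import make_random_mlp


class TestPowerLawOmega:
    def test_alpha_zero_is_scaled_identity(self):
        om = power_law_omega(PowerLawSpectrumSpec(d=6, alpha=0.0, scale=5.0))
        assert np.allclose(om, 5.0 * np.eye(6))

    def test_condition_number(self):
        om = power_law_omega(PowerLawSpectrumSpec(d=40, alpha=1.0))
        eigs = np.diag(om)
        assert eigs[0] / eigs[-1] == pytest.approx(40.0)
        assert eigs[0] == pytest.approx(5.0)

    def test_rotation_preserves_spectrum(self, rng):
        spec = PowerLawSpectrumSpec(d=5, alpha=0.7, rotate=True)
        om = power_law_omega(spec, rng)
        expected = 5.0 * np.arange(1, 6.0) ** -0.7
        assert np.allclose(np.sort(np.linalg.eigvalsh(om))[::-1], expected)


class TestSampleLatents:
    def test_reproducible(self):
        om = power_law_omega(PowerLawSpectrumSpec(d=4, alpha=0.5))
        z1 = sample_gaussian_latents(om, 10, np.random.default_rng(5))
        z2 = sample_gaussian_latents(om, 10, np.random.default_rng(5))
        assert np.array_equal(z1, z2)

    def test_moments_converge(self, rng):
        om = np.diag([4.0, 1.0])
        Z = sample_gaussian_latents(om, 100_000, rng)
        assert np.allclose(np.cov(Z, rowvar=False), om, atol=0.08)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=4 * 2 / np.sqrt(100_000))


class TestApplyCode:
    def test_identity_linear_code(self, rng):
        Z = rng.standard_normal((20, 3))
        X = apply_code(Z, LinearCodeSpec(a_matrix=np.eye(3)))
        assert np.array_equal(X, Z)

    def test_whitening_yields_identity_covariance(self, rng):
        om = np.diag([9.0, 4.0, 1.0])
        Z = sample_gaussian_latents(om, 50_000, rng)
        X = apply_code(Z, LinearCodeSpec(whiten=True), omega=om)
        assert np.allclose(np.cov(X, rowvar=False), np.eye(3), atol=0.05)

    def test_relu_outputs_nonnegative(self, rng):
        Z = rng.standard_normal((50, 4))
        stages = apply_code(Z, MlpSpec(nonlinearity="relu"), rng)
        relu_stages = [x for name, x in stages if name.startswith("relu")]
        assert relu_stages and all(np.all(x >= 0) for x in relu_stages)

    def test_mlp_stage_widths_double(self, rng):
        Z = rng.standard_normal((10, 4))
        stages = dict(apply_code(Z, MlpSpec(), rng))
        assert stages["linear1"].shape[1] == 8
        assert stages["linear2"].shape[1] == 16
        assert stages["linear3"].shape[1] == 32

    def test_exclusive_spec_fields(self):
        with pytest.raises(ValueError):
            LinearCodeSpec(a_matrix=np.eye(2), whiten=True)


class TestEstimateCovariances:
    def test_x_equals_z(self, rng):
        Z = rng.standard_normal((100, 3))
        code = estimate_covariances(Z, Z)
        assert np.allclose(code.psi, code.omega)
        assert np.allclose(code.phi, code.phi.T)
        assert np.allclose(code.psi, code.phi)

    def test_constant_column_gives_zero_rows(self, rng):
        X = rng.standard_normal((50, 3))
        X[:, 1] = 2.5
        code = estimate_covariances(X, rng.standard_normal((50, 2)))
        assert np.allclose(code.psi[1], 0.0)
        assert np.allclose(code.phi[1], 0.0)

    def test_generative_round_trip_small(self, rng):
        # scaled-down consistency check (the full-size one is in acceptance)
        from conftest import random_valid_code
        from latentgeom.readout import sample_joint
        code = random_valid_code(rng, n=5, d=3)
        X, Z = sample_joint(code, 40_000, rng)
        est = estimate_covariances(X, Z)
        s_true, s_est = geometry_summary(code), geometry_summary(est)
        assert s_est.c == pytest.approx(s_true.c, rel=0.05)
        assert s_est.pr == pytest.approx(s_true.pr, rel=0.05)
        assert s_est.f == pytest.approx(s_true.f, rel=0.05)

    def test_rejects_single_sample(self, rng):
        with pytest.raises(ValueError):
            estimate_covariances(rng.standard_normal((1, 2)),
                                 rng.standard_normal((1, 2)))


class TestRandomProjection:
    def test_orthogonal_full_dim_preserves_metrics(self, rng):
        Z = rng.standard_normal((2000, 3))
        X = Z @ rng.standard_normal((6, 3)).T
        projs = random_projection(X, 6, 1, rng, orthogonalize=True)
        s0 = geometry_summary(estimate_covariances(X, Z))
        s1 = geometry_summary(estimate_covariances(projs[0], Z))
        assert s1.c == pytest.approx(s0.c, rel=1e-9)
        assert s1.pr == pytest.approx(s0.pr, rel=1e-9)

    def test_projection_bounds_pr(self, rng):
        X = rng.standard_normal((500, 30))
        for proj in random_projection(X, 4, 3, rng):
            code = estimate_covariances(proj, rng.standard_normal((500, 2)))
            assert geometry_summary(code).pr <= 4 + 1e-9

    def test_rejects_expanding_projection(self, rng):
        with pytest.raises(ValueError):
            random_projection(rng.standard_normal((10, 3)), 5, 1, rng)


class TestZScore:
    def test_standard_columns_unchanged(self, rng):
        M = rng.standard_normal((5000, 3))
        M = (M - M.mean(0)) / M.std(0, ddof=1)
        assert np.allclose(zscore_columns(M), M, atol=1e-10)

    def test_constant_column_with_floor(self):
        M = np.ones((10, 2))
        M[:, 1] = np.arange(10)
        out = zscore_columns(M, sd_floor=0.5)
        assert np.allclose(out[:, 0], 0.0)

    def test_floor_halves_matched_sd(self, rng):
        col = rng.standard_normal(1000)
        col = (col - col.mean()) / col.std(ddof=1) * 0.02
        out = zscore_columns(col[:, None], sd_floor=0.02)
        assert out.std(ddof=1) == pytest.approx(0.5, rel=1e-6)


class TestRandomMlpCode:
    def test_deterministic_representations(self, rng):
        Z = np.random.default_rng(0).standard_normal((30, 5))
        net = make_random_mlp(5, MlpSpec(), np.random.default_rng(11))
        r1 = net.representations(Z)
        r2 = net.representations(Z)
        for (n1, x1), (n2, x2) in zip(r1, r2):
            assert n1 == n2 and np.array_equal(x1, x2)

    def test_theory_tracks_error_through_random_layers(self, rng):
        # the analytical error stays predictive on non-Gaussian MLP responses
        from latentgeom import LabeledDataset, empirical_task_error, \
            make_labels, sample_tasks
        d = 10
        om = power_law_omega(PowerLawSpectrumSpec(d=d, alpha=0.2, scale=1.0))
        Z = sample_gaussian_latents(om, 1500, rng)
        stages = apply_code(Z, MlpSpec(), rng)
        battery = sample_tasks(d, 60, rng)
        Y = make_labels(Z, battery)
        for name, X in stages[-2:]:
            Xc = X - X.mean(axis=0)
            code = estimate_covariances(X, Z)
            theory = theoretical_error(geometry_summary(code), 500).e_g
            tr = LabeledDataset(X=Xc[:500], Z=Z[:500], Y=Y[:500])
            te = LabeledDataset(X=Xc[500:], Z=Z[500:], Y=Y[500:])
            _, emp, _ = empirical_task_error(tr, te)
            assert emp == pytest.approx(theory, abs=0.05)


class TestSaveDataset:
    def test_writes_matrices_and_manifest(self, rng, tmp_path):
        import json
        from latentgeom.synth import save_dataset
        X = rng.standard_normal((20, 4))
        Z = rng.standard_normal((20, 2))
        Y = np.where(rng.standard_normal((20, 3)) > 0, 1, -1)
        save_dataset(tmp_path, X, Z, Y, manifest={"seed": 7}, name="toy")
        assert np.allclose(np.loadtxt(tmp_path / "toy_X.tsv"), X)
        assert np.allclose(np.loadtxt(tmp_path / "toy_Y.tsv"), Y)
        info = json.loads((tmp_path / "toy.json").read_text())
        assert info["p"] == 20 and info["n"] == 4 and info["d"] == 2
        assert info["n_tasks"] == 3 and info["manifest"]["seed"] == 7
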