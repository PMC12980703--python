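"""Second-order reweighting estimator: term matrices, cumulants, reweighting."""

import numpy as np
import pytest

from netperturb.ensembles import BeadEnsemble, ProjectedEnsemble
from netperturb.networks import (
    ENM_HARMONIC,
    GO_LJ,
    Contact,
    InteractionNetwork,
    apply_perturbation,
    lj_energy,
)
from netperturb.perturbation import (
    KB_KJ_PER_MOL_K,
    PerturbationBasis,
    TermMatrix,
    build_basis,
    evaluate_terms,
    kish_ess,
    load_basis,
    log_density_ratio,
    psi_second_order,
    reweight_frames,
    save_basis,
)

RMIN = 2.0 ** (1.0 / 6.0)
KBT300 = KB_KJ_PER_MOL_K * 300.0


def gaussian_term_basis(rng, n_frames=4000, skew=True):
    """Basis built from a small synthetic contact-energy sample."""
    L = rng.normal(size=(n_frames, 3)) @ np.array(
        [[0.5, 0.2, 0.0], [0.0, 0.4, 0.1], [0.0, 0.0, 0.3]]
    )
    if skew:
        L = L + 0.3 * L**2  # non-Gaussian so the third cumulant is nonzero
    tm = TermMatrix(values=L, temperature_K=300.0, kBT_kJmol=KBT300)
    return build_basis(tm)


class TestEvaluateTerms:
    def test_lj_minimum_in_kbt_units(self):
        sigma = 0.5
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = RMIN * sigma
        net = InteractionNetwork(
            [Contact(0, 1, GO_LJ, strength=KBT300, geometry=sigma)], 2, GO_LJ
        )
        tm = evaluate_terms(BeadEnsemble(coords), net, temperature_K=300.0)
        assert tm.values[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_enm_at_equilibrium_column_is_zero(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 0] = 0.5
        net = InteractionNetwork(
            [Contact(0, 1, ENM_HARMONIC, 500.0, 0.5)], 2, ENM_HARMONIC
        )
        tm = evaluate_terms(BeadEnsemble(coords), net)
        np.testing.assert_array_equal(tm.values, 0.0)

    def test_matches_naive_double_loop(self, rng):
        coords = rng.normal(scale=0.5, size=(10, 6, 3)) + 2.0
        pairs = [(0, 3), (1, 4), (0, 5), (2, 5), (1, 3)]
        net = InteractionNetwork(
            [Contact(i, j, GO_LJ, float(rng.uniform(2, 12)), float(rng.uniform(0.3, 0.6)))
             for i, j in pairs], 6, GO_LJ)
        tm = evaluate_terms(BeadEnsemble(coords), net, temperature_K=300.0)
        for f in range(10):
            for k, c in enumerate(net.contacts):
                r = np.linalg.norm(coords[f, c.j] - coords[f, c.i])
                expected = lj_energy(c.strength, c.geometry, r) / KBT300
                assert tm.values[f, k] == pytest.approx(expected, abs=1e-12)

    def test_overlapping_beads_rejected(self):
        coords = np.zeros((1, 2, 3))
        net = InteractionNetwork([Contact(0, 1, GO_LJ, 5.0, 0.4)], 2, GO_LJ)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_terms(BeadEnsemble(coords), net)


class TestBuildBasis:
    def test_constant_columns_give_zero_covariance(self):
        L = np.tile([1.5, -2.0], (20, 1))
        basis = build_basis(TermMatrix(L, 300.0, KBT300))
        np.testing.assert_allclose(basis.covariance, 0.0, atol=1e-14)
        np.testing.assert_allclose(basis.eigenvalues, 0.0, atol=1e-14)

    def test_eigendecomposition_reconstructs_covariance(self, rng):
        basis = gaussian_term_basis(rng)
        rebuilt = basis.eigenvectors @ np.diag(basis.eigenvalues) @ basis.eigenvectors.T
        np.testing.assert_allclose(rebuilt, basis.covariance, atol=1e-10)

    def test_centered_projections_have_zero_mean(self, rng):
        basis = gaussian_term_basis(rng)
        means = basis.frame_weights @ basis.centered_eigenprojections
        np.testing.assert_allclose(means, 0.0, atol=1e-8)

    def test_sampled_covariance_recovers_known_eigenvalues(self, rng):
        # frames drawn with covariance [[2,1],[1,2]] -> eigenvalues (3, 1)
        root = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        L = rng.normal(size=(50_000, 2)) @ root.T
        basis = build_basis(TermMatrix(L, 300.0, KBT300))
        np.testing.assert_allclose(np.sort(basis.eigenvalues)[::-1], [3.0, 1.0],
                                   rtol=0.03)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            build_basis(TermMatrix(np.ones((1, 2)), 300.0, KBT300))


class TestLogDensityRatio:
    def test_zero_lambda_gives_zeros(self, rng):
        basis = gaussian_term_basis(rng)
        np.testing.assert_array_equal(log_density_ratio(basis, np.zeros(3)), 0.0)

    def test_scalar_case_reduces_to_known_formula(self, rng):
        L = rng.normal(1.0, 0.7, size=(500, 1))
        basis = build_basis(TermMatrix(L, 300.0, KBT300))
        lam = np.array([0.2])
        var = np.var(L)
        expected = 0.2 * (L[:, 0] - L.mean()) - 0.5 * 0.04 * var
        np.testing.assert_allclose(log_density_ratio(basis, lam), expected, atol=1e-10)

    def test_eigen_and_direct_forms_agree(self, rng):
        basis = gaussian_term_basis(rng)
        for _ in range(5):
            lam = rng.uniform(-0.3, 0.3, size=3)
            np.testing.assert_allclose(
                log_density_ratio(basis, lam, form="eigen"),
                log_density_ratio(basis, lam, form="direct"),
                atol=1e-10,
            )

    def test_second_order_normalization_and_remainder_scaling(self, rng):
        # <exp(log-ratio)> must be 1 up to the third-order remainder, which
        # shrinks ~8x when lambda is halved
        basis = gaussian_term_basis(rng, n_frames=2000, skew=True)
        lam = np.array([0.12, -0.1, 0.08])

        def normalization_error(lam):
            ratio = log_density_ratio(basis, lam)
            return abs(np.average(np.exp(ratio), weights=basis.frame_weights) - 1.0)

        err_full = normalization_error(lam)
        err_half = normalization_error(lam / 2)
        assert err_full < 0.05
        assert 4.0 < err_full / err_half < 16.0


class TestPsi:
    def test_zero_lambda(self, rng):
        basis = gaussian_term_basis(rng)
        assert psi_second_order(basis, np.zeros(3)) == 0.0

    def test_scalar_formula(self, rng):
        L = rng.normal(2.0, 0.5, size=(300, 1))
        basis = build_basis(TermMatrix(L, 300.0, KBT300))
        lam = 0.15
        expected = lam * L.mean() + 0.5 * lam**2 * np.var(L)
        assert psi_second_order(basis, [lam]) == pytest.approx(expected, abs=1e-12)

    def test_third_order_error_scaling_vs_exact_average(self, rng):
        # psi_2(lam) vs ln<exp(lam.L)> on a fixed skewed sample: the
        # remainder is the third cumulant term, so halving lambda divides
        # the error by ~8
        basis = gaussian_term_basis(rng, n_frames=2000, skew=True)
        L = basis.centered_eigenprojections @ basis.eigenvectors.T + basis.mean
        lam = np.array([0.1, 0.08, -0.12])

        def err(lam):
            exact = np.log(np.mean(np.exp(L @ lam)))
            return abs(psi_second_order(basis, lam) - exact)

        ratio = err(lam) / err(lam / 2)
        assert 6.0 < ratio < 10.0


class TestReweight:
    def test_zero_lambda_keeps_weights(self, rng):
        basis = gaussian_term_basis(rng)
        proj = ProjectedEnsemble(rng.normal(size=(basis.n_frames, 2)))
        out = reweight_frames(proj, basis, np.zeros(3))
        np.testing.assert_allclose(out.frame_weights,
                                   np.full(basis.n_frames, 1.0 / basis.n_frames))

    def test_weights_normalized_and_non_negative(self, rng):
        basis = gaussian_term_basis(rng)
        proj = ProjectedEnsemble(rng.normal(size=(basis.n_frames, 2)))
        out = reweight_frames(proj, basis, np.array([0.2, -0.1, 0.05]))
        assert np.all(out.frame_weights >= 0)
        assert out.frame_weights.sum() == pytest.approx(1.0)

    def test_harmonic_toy_matches_perturbed_gaussian(self, rng):
        # 1-D oscillator: V = 1/2 k x^2, L = V/kBT.  Scaling the strength by
        # (1+lam) gives an exactly solvable Gaussian with variance
        # kBT / (k (1+lam)).
        k = 80.0  # kJ/mol/nm^2
        var0 = KBT300 / k
        x = rng.normal(0.0, np.sqrt(var0), size=100_000)
        L = 0.5 * k * x**2 / KBT300
        basis = build_basis(TermMatrix(L[:, None], 300.0, KBT300))
        proj = ProjectedEnsemble(x[:, None])
        for lam in (0.15, -0.15, 0.3):
            out = reweight_frames(proj, basis, np.array([lam]))
            w = out.normalized_weights()
            mean = w @ x
            var = w @ (x - mean) ** 2
            assert var == pytest.approx(var0 / (1.0 + lam), rel=0.02)

    def test_strengthening_contracts_like_resimulation(self, rng):
        # sign contract: reweighting with +lam and re-sampling the network
        # perturbed by apply_perturbation(+lam) must move the mean contact
        # energy in the same direction
        from netperturb.toysampler import SamplerConfig, chain_model_for_network, sample_mc

        reference = np.array(
            [[0.0, 0, 0], [0.38, 0, 0], [0.76, 0, 0], [0.76, 0.45, 0],
             [0.38, 0.45, 0], [0.0, 0.45, 0]]
        )
        net = InteractionNetwork(
            [Contact(0, 5, GO_LJ, 6.0, 0.45 / RMIN),
             Contact(1, 4, GO_LJ, 6.0, 0.45 / RMIN),
             Contact(2, 3, GO_LJ, 6.0, 0.45 / RMIN)], 6, GO_LJ)
        model = chain_model_for_network(reference, net)
        cfg = SamplerConfig(n_steps=400_000, burn_in=40_000, thinning=50, seed=5)
        base = sample_mc(model, cfg)
        lam = np.full(3, 0.4)
        terms = evaluate_terms(base, net)
        basis = build_basis(terms)
        rew = reweight_frames(BeadEnsemble(base.coords), basis, lam)
        mean_energy_rew = rew.normalized_weights() @ terms.values.sum(axis=1)

        stronger = apply_perturbation(net, lam)
        resampled = sample_mc(model.with_network(stronger),
                              SamplerConfig(n_steps=400_000, burn_in=40_000,
                                            thinning=50, seed=6))
        terms_strong = evaluate_terms(resampled, net)  # same unperturbed yardstick
        mean_energy_resim = terms_strong.values.sum(axis=1).mean()
        mean_energy_base = terms.values.sum(axis=1).mean()
        assert mean_energy_rew < mean_energy_base
        assert mean_energy_resim < mean_energy_base

    def test_frame_count_mismatch(self, rng):
        basis = gaussian_term_basis(rng)
        proj = ProjectedEnsemble(rng.normal(size=(7, 2)))
        with pytest.raises(ValueError, match="frame count"):
            reweight_frames(proj, basis, np.zeros(3))


def test_kish_ess_uniform_weights():
    assert kish_ess(np.full(50, 0.02)) == pytest.approx(50.0)
    assert kish_ess([1.0, 0.0, 0.0]) == pytest.approx(1.0)


def test_basis_save_load_round_trip(tmp_path, rng):
    basis = gaussian_term_basis(rng, n_frames=100)
    path = tmp_path / "basis.h5"
    save_basis(basis, path)
    back = load_basis(path)
    for name in ("mean", "covariance", "eigenvectors", "eigenvalues",
                 "centered_eigenprojections", "frame_weights"):
        np.testing.assert_array_equal(getattr(back, name), getattr(basis, name))
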