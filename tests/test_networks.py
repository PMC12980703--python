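"""Interaction-network model, energy kernels, construction, comparison."""

import numpy as np
import pytest

from netperturb.ensembles import BeadEnsemble
from netperturb.networks import (
    ENM_HARMONIC,
    GO_LJ,
    Contact,
    InteractionNetwork,
    apply_perturbation,
    build_uniform_network,
    enm_energy,
    laplacian_spectrum_distance,
    lj_energy,
    network_from_tsv,
    network_pearson,
    network_to_tsv,
    set_equilibrium_from_ensemble,
)

RMIN = 2.0 ** (1.0 / 6.0)


class TestEnergyKernels:
    def test_lj_minimum_depth(self):
        assert lj_energy(1.0, 1.0, RMIN) == pytest.approx(-1.0, abs=1e-14)

    def test_lj_zero_crossing(self):
        assert lj_energy(9.4, 0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_lj_direct_arithmetic(self):
        assert lj_energy(2.0, 1.0, 2.0) == pytest.approx(8 * (2**-12 - 2**-6))

    def test_lj_unique_minimum_on_fine_grid(self):
        r = np.linspace(0.3, 3.0, 20_001)
        e = lj_energy(3.7, 0.8, r)
        k = np.argmin(e)
        assert r[k] == pytest.approx(RMIN * 0.8, abs=2e-4)
        assert e[k] == pytest.approx(-3.7, abs=1e-6)

    def test_lj_rejects_zero_distance(self):
        with pytest.raises(ValueError, match="r > 0"):
            lj_energy(1.0, 1.0, 0.0)

    def test_enm_at_equilibrium_zero(self):
        assert enm_energy(500.0, 0.5, 0.5) == 0.0

    def test_enm_direct_arithmetic(self):
        assert enm_energy(500.0, 0.5, 0.6) == pytest.approx(2.5)

    def test_enm_symmetry(self, rng):
        for delta in rng.uniform(0, 0.3, size=5):
            assert enm_energy(120.0, 0.5, 0.5 + delta) == pytest.approx(
                enm_energy(120.0, 0.5, 0.5 - delta)
            )


class TestConstruction:
    def test_empty_network_is_error(self):
        structure = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0], [15.0, 0, 0]])
        with pytest.raises(ValueError, match="empty network"):
            build_uniform_network(structure, kind=GO_LJ)

    def test_collinear_enumeration(self):
        structure = np.array([[0.0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]])
        net = build_uniform_network(structure, kind=GO_LJ, cutoff_lo=0.3,
                                    cutoff_hi=1.1, min_seq_sep=1)
        assert net.n_contacts == 3
        net2 = build_uniform_network(structure, kind=GO_LJ, cutoff_lo=0.3,
                                     cutoff_hi=1.1, min_seq_sep=2)
        assert net2.n_contacts == 1
        (c,) = net2.contacts
        assert (c.i, c.j) == (0, 2)
        assert c.geometry == pytest.approx(1.0 / RMIN)

    def test_uniform_strength_default(self, toy_model):
        assert np.all(toy_model.network.strengths() == 9.4)

    def test_go_minimum_at_observed_distance(self, rng):
        structure = rng.normal(scale=0.4, size=(8, 3))
        net = build_uniform_network(structure, kind=GO_LJ)
        for c in net.contacts:
            r = np.linalg.norm(structure[c.j] - structure[c.i])
            assert RMIN * c.geometry == pytest.approx(r, rel=1e-12)

    def test_enm_defaults(self, rng):
        structure = rng.normal(scale=0.25, size=(8, 3))
        net = build_uniform_network(structure, kind=ENM_HARMONIC)
        assert net.kind == ENM_HARMONIC
        assert np.all(net.strengths() == 500.0)
        for c in net.contacts:
            r = np.linalg.norm(structure[c.j] - structure[c.i])
            assert c.geometry == pytest.approx(r)
            assert r <= 0.9


class TestEquilibriumRefit:
    def test_two_frame_mean_distance(self):
        coords = np.zeros((2, 4, 3))
        coords[0, 1, 0] = 0.4
        coords[1, 1, 0] = 0.6
        coords[:, 2, 1] = 0.5
        coords[:, 3, 2] = 1.0
        net = InteractionNetwork(
            [Contact(0, 1, GO_LJ, 9.4, 0.35)], n_beads=4, kind=GO_LJ
        )
        refit = set_equilibrium_from_ensemble(net, BeadEnsemble(coords))
        assert refit.contacts[0].geometry == pytest.approx(0.5 / RMIN)
        assert refit.contacts[0].strength == 9.4

    def test_idempotent(self, rng):
        coords = rng.normal(scale=0.4, size=(6, 5, 3))
        net = build_uniform_network(coords[0], kind=ENM_HARMONIC,
                                    cutoff_lo=0.0, cutoff_hi=5.0)
        e = BeadEnsemble(coords)
        once = set_equilibrium_from_ensemble(net, e)
        twice = set_equilibrium_from_ensemble(once, e)
        np.testing.assert_allclose(once.geometries(), twice.geometries(), atol=1e-14)


class TestPerturbation:
    def test_zero_lambda_is_identity(self, toy_model):
        net = toy_model.network
        out = apply_perturbation(net, np.zeros(net.n_contacts))
        np.testing.assert_array_equal(out.strengths(), net.strengths())
        np.testing.assert_array_equal(out.geometries(), net.geometries())
        assert out.pairs().tolist() == net.pairs().tolist()

    def test_single_contact_scaling(self):
        net = InteractionNetwork([Contact(0, 1, GO_LJ, 10.0, 0.4)], 2, GO_LJ)
        out = apply_perturbation(net, [0.5])
        assert out.contacts[0].strength == pytest.approx(15.0)

    def test_floor_clamp(self):
        net = InteractionNetwork([Contact(0, 1, GO_LJ, 10.0, 0.4)], 2, GO_LJ)
        out = apply_perturbation(net, [-0.999], strength_floor=0.1)
        assert out.contacts[0].strength == 0.1

    def test_wrong_length_rejected(self, toy_model):
        with pytest.raises(ValueError, match="lambda"):
            apply_perturbation(toy_model.network, [0.1])


class TestComparison:
    def _nets(self, strengths_a, strengths_b):
        contacts = [(0, 1), (0, 2), (1, 3)]
        na = InteractionNetwork(
            [Contact(i, j, GO_LJ, s, 0.4) for (i, j), s in zip(contacts, strengths_a)],
            4, GO_LJ)
        nb = InteractionNetwork(
            [Contact(i, j, GO_LJ, s, 0.4) for (i, j), s in zip(contacts, strengths_b)],
            4, GO_LJ)
        return na, nb

    def test_pearson_identity_and_affine(self):
        na, nb = self._nets([1, 2, 3], [1, 2, 3])
        assert network_pearson(na, nb) == pytest.approx(1.0)
        na, nb = self._nets([1, 2, 3], [5, 7, 9])  # 2a + 3
        assert network_pearson(na, nb) == pytest.approx(1.0)

    def test_pearson_reversed(self):
        na, nb = self._nets([1, 2, 3], [3, 2, 1])
        assert network_pearson(na, nb) == pytest.approx(-1.0)

    def test_pearson_zero_variance_reported(self):
        na, nb = self._nets([1, 2, 3], [2, 2, 2])
        with pytest.raises(ValueError, match="zero variance"):
            network_pearson(na, nb)

    def test_pearson_pair_mismatch(self):
        na, _ = self._nets([1, 2, 3], [1, 2, 3])
        other = InteractionNetwork([Contact(0, 3, GO_LJ, 1.0, 0.4)], 4, GO_LJ)
        with pytest.raises(ValueError, match="pair lists"):
            network_pearson(na, other)

    def test_laplacian_identical_zero(self):
        na, nb = self._nets([1, 2, 3], [1, 2, 3])
        assert laplacian_spectrum_distance(na, nb) == pytest.approx(0.0, abs=1e-12)

    def test_laplacian_scaling_law(self):
        alpha = 1.7
        na, nb = self._nets([1, 2, 3], [alpha, 2 * alpha, 3 * alpha])
        L = np.zeros((4, 4))
        for (i, j), s in zip([(0, 1), (0, 2), (1, 3)], [1, 2, 3]):
            L[i, j] = L[j, i] = -s
        L -= np.diag(L.sum(axis=1))
        spectrum = np.sort(np.linalg.eigvalsh(L))
        expected = (alpha - 1) * np.linalg.norm(spectrum)
        assert laplacian_spectrum_distance(na, nb) == pytest.approx(expected, rel=1e-10)

    def test_laplacian_path_graph_brute_force(self):
        # 3-node paths: unit weights vs weight 2 on edge (1,2)
        na = InteractionNetwork(
            [Contact(0, 1, GO_LJ, 1.0, 0.4), Contact(1, 2, GO_LJ, 1.0, 0.4)], 3, GO_LJ)
        nb = InteractionNetwork(
            [Contact(0, 1, GO_LJ, 1.0, 0.4), Contact(1, 2, GO_LJ, 2.0, 0.4)], 3, GO_LJ)
        La = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1.0]])
        Lb = np.array([[1, -1, 0], [-1, 3, -2], [0, -2, 2.0]])
        expected = np.linalg.norm(
            np.sort(np.linalg.eigvalsh(La)) - np.sort(np.linalg.eigvalsh(Lb))
        )
        assert laplacian_spectrum_distance(na, nb) == pytest.approx(expected, rel=1e-12)

    def test_laplacian_pseudometric_on_random_triples(self, rng):
        def rand_net():
            return InteractionNetwork(
                [Contact(i, j, GO_LJ, float(rng.uniform(0.5, 5)), 0.4)
                 for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]], 4, GO_LJ)
        for _ in range(10):
            a, b, c = rand_net(), rand_net(), rand_net()
            dab = laplacian_spectrum_distance(a, b)
            dba = laplacian_spectrum_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert laplacian_spectrum_distance(a, c) <= (
                dab + laplacian_spectrum_distance(b, c) + 1e-10
            )

    def test_laplacian_normalized_variant_is_scale_free(self):
        na, nb = self._nets([1, 2, 3], [2, 4, 6])
        raw = laplacian_spectrum_distance(na, nb, normalize=False)
        assert raw > 0
        # same shape up to a common scale: normalized distance is strictly
        # smaller and uses the joint-mean-rescaled weights
        norm = laplacian_spectrum_distance(na, nb, normalize=True)
        assert 0 < norm < raw

    def test_bead_count_mismatch(self):
        na = InteractionNetwork([Contact(0, 1, GO_LJ, 1.0, 0.4)], 2, GO_LJ)
        nb = InteractionNetwork([Contact(0, 1, GO_LJ, 1.0, 0.4)], 3, GO_LJ)
        with pytest.raises(ValueError, match="bead count"):
            laplacian_spectrum_distance(na, nb)


def test_tsv_round_trip(tmp_path, toy_model):
    path = tmp_path / "net.tsv"
    network_to_tsv(toy_model.network, path)
    back = network_from_tsv(path)
    assert back.kind == toy_model.network.kind
    assert back.n_beads == toy_model.network.n_beads
    np.testing.assert_allclose(back.strengths(), toy_model.network.strengths())
    np.testing.assert_allclose(back.geometries(), toy_model.network.geometries(),
                               rtol=1e-9)


def test_contact_validation():
    with pytest.raises(ValueError, match="i < j"):
        Contact(2, 1, GO_LJ, 1.0, 0.4)
    with pytest.raises(ValueError, match="distinct"):
        Contact(1, 1, GO_LJ, 1.0, 0.4)
    with pytest.raises(ValueError, match="strength"):
        Contact(0, 1, GO_LJ, -1.0, 0.4)
    with pytest.raises(ValueError, match="duplicate"):
        InteractionNetwork(
            [Contact(0, 1, GO_LJ, 1.0, 0.4), Contact(0, 1, GO_LJ, 2.0, 0.4)],
            2, GO_LJ)
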