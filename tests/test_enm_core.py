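import numpy as np
import pytest

import porenm as pn
from porenm.errors import (
    DisconnectedNetworkError,
    ParameterError,
    SpecificationError,
)

# --- independent oracles ---------------------------------------------------


def brute_force_pairs(coords, cutoff):
    """O(N^2) contact enumeration, independent of the KD-tree path."""
    pairs = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                pairs.append((i, j))
    return pairs


def oracle_hessian(coords, pairs, k=1.0):
    """Element-wise Hessian assembly, written independently of build_hessian."""
    n = len(coords)
    hessian = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        d = coords[j] - coords[i]
        length_sq = float((d**2).sum())
        for a in range(3):
            for b in range(3):
                val = k * d[a] * d[b] / length_sq
                hessian[3 * i + a, 3 * i + b] += val
                hessian[3 * j + a, 3 * j + b] += val
                hessian[3 * i + a, 3 * j + b] -= val
                hessian[3 * j + a, 3 * i + b] -= val
    return hessian


def ring24_coords():
    """24 nodes on a circle, spaced so 1st and 2nd neighbours are in contact."""
    n = 24
    radius = 4.0 / (2.0 * np.sin(np.pi / n))
    angles = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
    )


# --- build_spring_network ---------------------------------------------------


class TestBuildSpringNetwork:
    def test_dimer_one_spring(self):
        network = pn.build_spring_network(pn.make_dimer(5.0), cutoff=8.0, k=1.0)
        assert network.n_springs == 1
        spring = network.springs[0]
        assert spring.rest_length == pytest.approx(5.0)
        assert spring.k == 1.0
        assert spring.tag == "contact"

    def test_dimer_beyond_cutoff(self):
        assert pn.build_spring_network(pn.make_dimer(8.5), cutoff=8.0).n_springs == 0

    def test_cutoff_is_inclusive(self):
        assert pn.build_spring_network(pn.make_dimer(8.0), cutoff=8.0).n_springs == 1

    def test_matches_brute_force_on_hexamer(self, hexamer):
        network = pn.build_spring_network(hexamer, cutoff=8.0)
        expected = brute_force_pairs(hexamer.coords, 8.0)
        assert [(s.i, s.j) for s in network.springs] == expected

    def test_rest_lengths_within_cutoff(self, hexamer_networks):
        network, _ = hexamer_networks
        for s in network.springs:
            if s.tag == "contact":
                assert s.rest_length <= network.cutoff

    def test_invalid_parameters(self, hexamer):
        with pytest.raises(ParameterError):
            pn.build_spring_network(hexamer, cutoff=-1.0)
        with pytest.raises(ParameterError):
            pn.build_spring_network(hexamer, k=0.0)


# --- add_bridge_springs -----------------------------------------------------


class TestAddBridgeSprings:
    def test_hexamer_adds_six(self, hexamer_networks):
        unbound, bound = hexamer_networks
        assert bound.n_springs - unbound.n_springs == 6
        assert bound.count("bridge") == 6

    def test_trimer_adds_three(self):
        spec = pn.OligomerSpec(n_subunits=3, ring_radius=9.0, pore_radius=6.5)
        s = pn.make_cn_oligomer(spec)
        donor, acceptor = pn.bridge_residues(spec)
        network = pn.build_spring_network(s)
        bound = pn.add_bridge_springs(
            network, s, pn.BridgeSpec(donor=(donor, "LYS"), acceptor=(acceptor, "ARG"))
        )
        assert bound.count("bridge") == 3

    def test_missing_residue_names_chain(self, hexamer, hexamer_networks):
        network, _ = hexamer_networks
        with pytest.raises(SpecificationError, match="9999"):
            pn.add_bridge_springs(
                network, hexamer, pn.BridgeSpec(donor=(9999, None), acceptor=(1, None))
            )

    def test_wrong_residue_name_guard(self, hexamer, hexamer_networks, hexamer_spec):
        network, _ = hexamer_networks
        donor, acceptor = pn.bridge_residues(hexamer_spec)
        with pytest.raises(SpecificationError):
            pn.add_bridge_springs(
                network,
                hexamer,
                pn.BridgeSpec(donor=(donor, "ARG"), acceptor=(acceptor, "ARG")),
            )

    def test_duplicate_pair_increments_stiffness(self):
        # bridge distance below the cutoff: the pair already has a contact spring
        spec = pn.OligomerSpec(target_bridge_distance=6.5)
        s = pn.make_cn_oligomer(spec)
        donor, acceptor = pn.bridge_residues(spec)
        network = pn.build_spring_network(s)
        bound = pn.add_bridge_springs(
            network,
            s,
            pn.BridgeSpec(donor=(donor, "LYS"), acceptor=(acceptor, "ARG"), bridge_k=2.0),
        )
        assert bound.n_springs == network.n_springs  # no duplicate pairs
        assert bound.count("bridge") == 6
        bridged = [sp for sp in bound.springs if sp.tag == "bridge"]
        assert all(sp.k == pytest.approx(3.0) for sp in bridged)  # 1 + 2

    def test_original_network_unmodified(self, hexamer_networks):
        unbound, _ = hexamer_networks
        assert unbound.count("bridge") == 0

    def test_nearest_rule_matches_cyclic_on_symmetric_ring(
        self, hexamer, hexamer_spec, hexamer_networks
    ):
        donor, acceptor = pn.bridge_residues(hexamer_spec)
        network, bound_cyclic = hexamer_networks
        bound_nearest = pn.add_bridge_springs(
            network,
            hexamer,
            pn.BridgeSpec(
                donor=(donor, "LYS"),
                acceptor=(acceptor, "ARG"),
                interface_rule="nearest",
            ),
        )
        pairs = lambda net: sorted(
            (s.i, s.j) for s in net.springs if s.tag == "bridge"
        )
        assert pairs(bound_nearest) == pairs(bound_cyclic)


# --- build_hessian ----------------------------------------------------------


class TestBuildHessian:
    def test_dimer_closed_form(self):
        # two bodies, one spring k: single stretch mode with eigenvalue 2k
        for k in (1.0, 2.5):
            network = pn.build_spring_network(pn.make_dimer(5.0), k=k)
            eigenvalues = np.linalg.eigvalsh(pn.build_hessian(network))
            np.testing.assert_allclose(eigenvalues[:5], 0.0, atol=1e-12)
            assert eigenvalues[5] == pytest.approx(2.0 * k)

    def test_exact_symmetry(self, hexamer_networks):
        hessian = pn.build_hessian(hexamer_networks[0])
        assert np.abs(hessian - hessian.T).max() == 0.0

    def test_translation_null_space(self, hexamer_networks):
        hessian = pn.build_hessian(hexamer_networks[0])
        scale = np.abs(hessian).max()
        for axis in range(3):
            translation = np.zeros(hessian.shape[0])
            translation[axis::3] = 1.0
            assert np.abs(hessian @ translation).max() < 1e-10 * scale

    def test_ring24_spectrum_matches_oracle(self):
        coords = ring24_coords()
        structure = pn.CGStructure(
            chain_ids=np.array(["A"] * 24),
            res_ids=np.arange(1, 25),
            res_names=np.array(["GLY"] * 24),
            coords=coords,
        )
        network = pn.build_spring_network(structure, cutoff=8.0)
        pairs = brute_force_pairs(coords, 8.0)
        assert [(s.i, s.j) for s in network.springs] == pairs
        ours = np.linalg.eigvalsh(pn.build_hessian(network))
        reference = np.linalg.eigvalsh(oracle_hessian(coords, pairs))
        np.testing.assert_allclose(ours, reference, atol=1e-8 * reference.max())

    def test_psd(self, hexamer_modes):
        unbound, _ = hexamer_modes
        assert unbound.eigenvalues.min() > -1e-8 * unbound.eigenvalues.max()


# --- compute_modes ----------------------------------------------------------


class TestComputeModes:
    def test_dimer_single_stretch_mode(self):
        network = pn.build_spring_network(pn.make_dimer(5.0))
        modes = pn.compute_modes(pn.build_hessian(network))
        assert modes.n_modes == 1  # collinear body: 5 rigid motions
        v = modes.mode_vector(1).reshape(2, 3)
        # equal and opposite displacements along the bond (x) axis
        np.testing.assert_allclose(v[0], -v[1], atol=1e-12)
        np.testing.assert_allclose(np.abs(v[0]), [1 / np.sqrt(2), 0, 0], atol=1e-12)

    def test_hexamer_mode_count(self, hexamer, hexamer_modes):
        unbound, bound = hexamer_modes
        assert unbound.rigid_count == 6
        assert bound.rigid_count == 6
        assert unbound.n_modes == 3 * hexamer.n_atoms - 6

    def test_disconnected_network_error(self):
        coords = np.array(
            [[0, 0, 0], [5, 0, 0], [100, 0, 0], [105, 0, 0]], dtype=float
        )
        structure = pn.CGStructure(
            chain_ids=np.array(["A"] * 4),
            res_ids=np.arange(1, 5),
            res_names=np.array(["GLY"] * 4),
            coords=coords,
        )
        network = pn.build_spring_network(structure, cutoff=8.0)
        with pytest.raises(DisconnectedNetworkError):
            pn.compute_modes(pn.build_hessian(network))

    def test_eigenvectors_orthonormal(self, hexamer_modes):
        unbound, _ = hexamer_modes
        v = unbound.eigenvectors
        gram = v.T @ v
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8

    def test_sign_convention_deterministic(self, hexamer_networks):
        hessian = pn.build_hessian(hexamer_networks[0])
        a = pn.compute_modes(hessian)
        b = pn.compute_modes(hessian)
        np.testing.assert_array_equal(a.eigenvectors, b.eigenvectors)
        idx = np.argmax(np.abs(a.eigenvectors), axis=0)
        assert (a.eigenvectors[idx, np.arange(a.eigenvectors.shape[1])] > 0).all()

    def test_c6_degeneracy_pattern(self, hexamer_modes):
        # C6 symmetry forces two-fold degenerate E-representation pairs
        # (2/3 of the internal modes); pairs must agree to 1e-8 relative.
        eigenvalues = hexamer_modes[0].nonrigid_eigenvalues
        paired = 0
        i = 0
        while i < len(eigenvalues) - 1:
            if (eigenvalues[i + 1] - eigenvalues[i]) / eigenvalues[i + 1] < 1e-8:
                paired += 2
                i += 2
            else:
                i += 1
        assert 0.6 <= paired / len(eigenvalues) <= 0.75

    def test_eigenvalue_monotonicity_under_bridges(self, hexamer_modes):
        unbound, bound = hexamer_modes
        assert np.all(bound.eigenvalues >= unbound.eigenvalues - 1e-10)

    def test_asymmetric_hessian_rejected(self):
        with pytest.raises(ParameterError):
            pn.compute_modes(np.arange(36.0).reshape(6, 6))


# --- mode_fraction ----------------------------------------------------------


def _mode_set_from_eigenvalues(nonrigid):
    eigenvalues = np.concatenate([np.zeros(6), np.asarray(nonrigid, dtype=float)])
    return pn.ModeSet(
        n_nodes=len(eigenvalues) // 3 or 1,
        eigenvalues=eigenvalues,
        eigenvectors=np.eye(len(eigenvalues)),
        rigid_count=6,
    )


class TestModeFraction:
    def test_equal_eigenvalues_split_evenly(self):
        modes = _mode_set_from_eigenvalues([1.0, 1.0])
        assert pn.mode_fraction(modes, 1) == pytest.approx(0.5)
        assert pn.mode_fraction(modes, 2) == pytest.approx(0.5)

    def test_inverse_weighting(self):
        modes = _mode_set_from_eigenvalues([1.0, 4.0])
        assert pn.mode_fraction(modes, 1) == pytest.approx(0.8)
        assert pn.mode_fraction(modes, 2) == pytest.approx(0.2)

    def test_fractions_sum_to_one(self, hexamer_modes):
        for weighting in ("inv", "inv_sqrt", "uniform"):
            fractions = pn.mode_fractions(hexamer_modes[0], weighting)
            assert fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rigid_or_invalid_index_rejected(self, hexamer_modes):
        with pytest.raises(ParameterError):
            pn.mode_fraction(hexamer_modes[0], 0)
        with pytest.raises(ParameterError):
            pn.mode_fraction(hexamer_modes[0], 10**6)

    def test_unknown_weighting(self, hexamer_modes):
        with pytest.raises(ParameterError):
            pn.mode_fractions(hexamer_modes[0], "bogus")
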