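import itertools

import numpy as np
import pytest
from rdkit import Chem

from cpqsar import descriptors as desc
from cpqsar.descriptors import (
    DESCRIPTOR_COLUMNS,
    MolecularDescriptorCalculator,
    compute_descriptor_block,
    count_fragment,
    edge_adjacency_eigenvalue,
    edge_spectral_moment,
    moran_autocorrelation,
    path_walk_index,
    distance_detour_ring_index,
    topological_charge_index,
)
from cpqsar.graphs import GraphSizeError, MolecularGraph
from cpqsar.records import MoleculeRecord


# --- independent brute-force oracles (kept free of the production code) ---


def brute_walks(adj: np.ndarray, start: int, k: int) -> int:
    """Count length-k walks from `start` by explicit enumeration."""
    frontier = {start: 1}
    for _ in range(k):
        nxt: dict[int, int] = {}
        for v, cnt in frontier.items():
            for w in np.flatnonzero(adj[v]):
                nxt[w] = nxt.get(w, 0) + cnt
        frontier = nxt
    return sum(frontier.values())


def brute_paths(adj: np.ndarray, start: int, k: int) -> int:
    """Count self-avoiding length-k paths from `start` by enumeration."""
    n = len(adj)
    count = 0

    def rec(v, seen, d):
        nonlocal count
        if d == k:
            count += 1
            return
        for w in range(n):
            if adj[v, w] and w not in seen:
                rec(w, seen | {w}, d + 1)

    rec(start, {start}, 0)
    return count


def brute_detour(adj: np.ndarray) -> np.ndarray:
    """Longest simple path lengths by enumerating all vertex permutations."""
    n = len(adj)
    best = np.zeros((n, n))
    for perm in itertools.permutations(range(n)):
        length = 0
        for a, b in zip(perm, perm[1:]):
            if not adj[a, b]:
                break
            length += 1
            i, j = perm[0], b
            best[i, j] = max(best[i, j], length)
            best[j, i] = best[i, j]
        # inner breaks just stop extending this permutation
    return best


class TestPathWalkIndex:
    def test_too_small_graph_is_zero(self, small_graphs):
        assert path_walk_index(small_graphs["ethane"], 5) == 0.0

    def test_hexane_matches_brute_force(self, small_graphs):
        g = small_graphs["hexane"]
        adj = g.adjacency.astype(int)
        expected = np.mean(
            [
                (brute_paths(adj, v, 5) / brute_walks(adj, v, 5)) if brute_walks(adj, v, 5) else 0.0
                for v in range(g.n_atoms)
            ]
        )
        assert path_walk_index(g, 5) == pytest.approx(expected)
        assert expected == pytest.approx(1 / 30)

    @pytest.mark.parametrize("name", ["butane", "benzene", "cyclopentane", "hexane"])
    def test_bounded_by_one(self, small_graphs, name):
        assert 0.0 <= path_walk_index(small_graphs[name], 5) <= 1.0


class TestDistanceDetourRingIndex:
    def test_acyclic_is_zero(self, small_graphs):
        assert distance_detour_ring_index(small_graphs["butane"], 6) == 0.0

    def test_wrong_ring_size_is_zero(self, small_graphs):
        assert distance_detour_ring_index(small_graphs["cyclopentane"], 6) == 0.0

    def test_benzene_from_brute_force_detour(self, small_graphs):
        g = small_graphs["benzene"]
        adj = g.adjacency.astype(int)
        delta = brute_detour(adj)
        D = g.distance
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        expected = sum(D[i, j] / delta[i, j] for i, j in pairs)
        assert distance_detour_ring_index(g, 6) == pytest.approx(expected)
        assert expected == pytest.approx(7.2)

    def test_detour_size_guard(self):
        g = MolecularGraph.from_smiles("C" * 31, detour_atom_limit=30)
        with pytest.raises(GraphSizeError):
            _ = g.detour


class TestMoranAutocorrelation:
    def test_constant_weights_give_zero(self, small_graphs):
        assert moran_autocorrelation(small_graphs["butane"], 2) == 0.0

    def test_chloropropane_hand_value(self, small_graphs):
        # Cl(2.18)-C-C-C(1.76 each): pairs at lag 2 are (Cl,C2) and (C1,C3)
        assert moran_autocorrelation(small_graphs["chloropropane"], 2) == pytest.approx(-1 / 3)

    def test_lag_beyond_diameter_is_zero(self, small_graphs):
        assert moran_autocorrelation(small_graphs["chloropropane"], 9) == 0.0

    @pytest.mark.parametrize(
        "smiles", ["CCOCN", "ClCCSCBr", "NCC(=O)O", "c1ccncc1O", "CCCCl", "OCCN"]
    )
    @pytest.mark.parametrize("lag", [1, 2, 3])
    def test_agrees_with_naive_double_loop(self, smiles, lag):
        from cpqsar.descriptors import polarizability_scheme

        g = MolecularGraph.from_smiles(smiles)
        scheme = polarizability_scheme()
        w = np.array([scheme.weight(e) for e in g.elements])
        D = g.distance
        wbar = w.mean()
        num, cnt = 0.0, 0
        for i in range(g.n_atoms):
            for j in range(i + 1, g.n_atoms):
                if D[i, j] == lag:
                    num += (w[i] - wbar) * (w[j] - wbar)
                    cnt += 1
        denom = np.sum((w - wbar) ** 2) / g.n_atoms
        expected = (num / cnt) / denom if cnt and denom else 0.0
        assert moran_autocorrelation(g, lag) == pytest.approx(expected, abs=1e-12)


class TestEdgeAdjacency:
    def test_ethane_rank10_padding(self, small_graphs):
        assert edge_adjacency_eigenvalue(small_graphs["ethane"], 10, "none") == 0.0

    def test_propane_rank1_unweighted(self, small_graphs):
        # E = [[0,1],[1,0]] has eigenvalues +/-1; rank 1 is +1
        assert edge_adjacency_eigenvalue(small_graphs["propane"], 1, "none") == pytest.approx(1.0)

    def test_spectral_moment_propane(self, small_graphs):
        g = small_graphs["propane"]
        assert edge_spectral_moment(g, 2, "none", "raw") == pytest.approx(2.0)
        assert edge_spectral_moment(g, 2, "none") == pytest.approx(np.log(3.0))

    def test_ethane_moment_zero(self, small_graphs):
        assert edge_spectral_moment(small_graphs["ethane"], 3, "none") == 0.0

    @pytest.mark.parametrize("smiles", ["CCC", "c1ccccc1", "CC(C)CC", "C1CCCC1C"])
    @pytest.mark.parametrize("weighting", ["none", "edge_degree"])
    def test_trace_power_equals_eigenvalue_power_sum(self, smiles, weighting):
        g = MolecularGraph.from_smiles(smiles)
        E = g.edge_adjacency(weighting)
        for order in (2, 5, 11):
            mu_trace = np.trace(np.linalg.matrix_power(E, order))
            mu_eig = np.sum(np.linalg.eigvalsh(E) ** order)
            assert mu_trace == pytest.approx(mu_eig, abs=1e-9)
            assert edge_spectral_moment(g, order, weighting, "raw") == pytest.approx(
                mu_trace, abs=1e-9
            )


class TestTopologicalChargeIndex:
    def test_ethane_order1_is_zero(self, small_graphs):
        assert topological_charge_index(small_graphs["ethane"], 1) == 0.0

    def test_propane_hand_values(self, small_graphs):
        g = small_graphs["propane"]
        # M = A D*: ct_12 = -0.25, ct_13 = 0, ct_23 = 0.25
        assert topological_charge_index(g, 1) == pytest.approx(0.5)
        assert topological_charge_index(g, 2) == pytest.approx(0.0)
        assert topological_charge_index(g, 1, mean=True) == pytest.approx(0.25)

    def test_single_atom_errors(self):
        with pytest.raises(ValueError):
            topological_charge_index(MolecularGraph.from_smiles("C"), 2)

    @pytest.mark.parametrize("smiles", ["CCCC", "c1ccccc1", "CC(C)C"])
    def test_nonnegative_and_mean_relation(self, smiles):
        g = MolecularGraph.from_smiles(smiles)
        for k in (1, 2, 3):
            G = topological_charge_index(g, k)
            J = topological_charge_index(g, k, mean=True)
            assert G >= 0.0
            assert J == pytest.approx(G / (g.n_atoms - 1))


class TestFragmentCounts:
    def test_ndma_nitroso(self):
        g = MolecularGraph.from_smiles("CN(C)N=O")
        assert count_fragment(g, "nRNNOx") == 1

    def test_benzene_all_zero(self, small_graphs):
        for frag in desc.FRAGMENT_NAMES:
            assert count_fragment(small_graphs["benzene"], frag) == 0

    def test_aromatic_nitroso_discriminated(self):
        g = MolecularGraph.from_smiles("O=Nc1ccccc1")
        assert count_fragment(g, "nRNNOx") == 0
        assert count_fragment(g, "N-078") >= 1

    def test_unknown_fragment_errors(self, small_graphs):
        with pytest.raises(KeyError):
            count_fragment(small_graphs["benzene"], "nope")

    def test_additive_over_disconnected_copies(self):
        # counting operates on the bare mol (no largest-fragment reduction)
        one = Chem.MolFromSmiles("CNC")
        two = Chem.MolFromSmiles("CNC.CNC")
        assert count_fragment(two, "N-067") == 2 * count_fragment(one, "N-067")


class TestDescriptorBlock:
    def test_column_names_and_order(self):
        records = [MoleculeRecord(id="e", smiles="CC")]
        block = compute_descriptor_block(records)
        assert block.column_names == DESCRIPTOR_COLUMNS
        assert block.column_names == [
            "PW5", "D/Dr06", "MATS2p", "EEig10x", "ESpm11x", "ESpm09d",
            "GGI2", "JGI6", "nRNNOx", "nPO4", "N-067", "N-078",
        ]

    def test_ethane_row_all_zero(self):
        block = compute_descriptor_block([MoleculeRecord(id="e", smiles="CC")])
        np.testing.assert_allclose(block.values[0], np.zeros(12))

    def test_fixture_block_complete(self):
        smiles = ["CCO", "c1ccccc1", "CCN", "CC(C)C", "C1CCCCC1",
                  "CN(C)N=O", "Clc1ccccc1", "CC=O", "CCCC", "O=C1C=CC(=O)C=C1"]
        records = [MoleculeRecord(id=f"f{i}", smiles=s) for i, s in enumerate(smiles)]
        block = compute_descriptor_block(records)
        assert block.shape == (10, 12)
        assert np.all(np.isfinite(block.values))

    def test_unparseable_structure_reported_with_id(self):
        records = [MoleculeRecord(id="ok", smiles="CC"),
                   MoleculeRecord(id="bad", smiles="C1CC")]
        with pytest.raises(ValueError, match="bad"):
            compute_descriptor_block(records)

    def test_sklearn_calculator_matches_function(self):
        records = [MoleculeRecord(id="a", smiles="CCO"), MoleculeRecord(id="b", smiles="CCC")]
        df = MolecularDescriptorCalculator().fit_transform(records)
        block = compute_descriptor_block(records)
        np.testing.assert_array_equal(df.to_numpy(), block.values)
        assert list(df.columns) == DESCRIPTOR_COLUMNS


class TestPermutationInvariance:
    @pytest.mark.parametrize("smiles", ["CCCCCC", "c1ccccc1C", "CC(C)CO", "O=C1C=CC(=O)C=C1"])
    def test_all_descriptors_invariant_under_relabeling(self, smiles, rng):
        base = MolecularGraph.from_smiles(smiles)
        reference = desc.compute_descriptors(base)
        mol = Chem.MolFromSmiles(smiles)
        for _ in range(3):
            perm = list(rng.permutation(mol.GetNumAtoms()))
            perm = [int(x) for x in perm]
            renum = Chem.RenumberAtoms(mol, perm)
            values = desc.compute_descriptors(MolecularGraph.from_mol(renum))
            for key in reference:
                assert values[key] == pytest.approx(reference[key], abs=1e-9), key
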