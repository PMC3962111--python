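import numpy as np
import pytest

from cpqsar.cpann import CPANNClassifier
from cpqsar.graphs import MolecularGraph
from cpqsar.records import DescriptorMatrix
from cpqsar.synthetic import SyntheticSpec, generate_gaussian_classes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_graphs():
    return {
        "ethane": MolecularGraph.from_smiles("CC"),
        "propane": MolecularGraph.from_smiles("CCC"),
        "butane": MolecularGraph.from_smiles("CCCC"),
        "hexane": MolecularGraph.from_smiles("CCCCCC"),
        "benzene": MolecularGraph.from_smiles("c1ccccc1"),
        "cyclopentane": MolecularGraph.from_smiles("C1CCCC1"),
        "chloropropane": MolecularGraph.from_smiles("CCCCl"),
    }


@pytest.fixture(scope="session")
def separable_data():
    """Well-separated two-class Gaussian clouds, normalized."""
    matrix, labels = generate_gaussian_classes(
        SyntheticSpec(n_per_class=40, p=5, separation=4.0, seed=7)
    )
    return matrix, labels


@pytest.fixture(scope="session")
def fitted_classifier(separable_data):
    matrix, labels = separable_data
    clf = CPANNClassifier(nx=7, ny=7, epochs=40, random_state=3)
    clf.fit(matrix.values, labels)
    return clf


@pytest.fixture
def random_matrix(rng):
    values = rng.normal(size=(20, 12))
    return DescriptorMatrix(
        values, [f"m{i}" for i in range(20)], [f"c{j}" for j in range(12)]
    )
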