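import numpy as np
import pytest

from molbias.molgraph import BOND_TYPES, Dataset, MolecularGraph, PropertyTable
from molbias.synthetic import GeneratorConfig, generate_population

ATOMS = ("C", "N", "O", "F")


def triangle(bond: str = "single") -> MolecularGraph:
    return MolecularGraph(id="tri", nodes=["C", "C", "C"], edges=[(0, 1, bond), (0, 2, bond), (1, 2, bond)])


def path3() -> MolecularGraph:
    return MolecularGraph(id="p3", nodes=["C", "O", "N"], edges=[(0, 1, "single"), (1, 2, "single")])


@pytest.fixture(scope="session")
def population_1000() -> Dataset:
    return generate_population(GeneratorConfig(n_molecules=1000, seed=42))


@pytest.fixture(scope="session")
def tiny_population() -> Dataset:
    return generate_population(GeneratorConfig(n_molecules=40, size_range=(3, 9), seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
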