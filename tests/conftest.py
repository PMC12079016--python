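import numpy as np
import pytest

from chargevar.moltypes import (
    Atom,
    Bond,
    ChargeEnsemble,
    ChargeSet,
    MoleculeGraph,
)

CHARGE_SUM_TOL = 1e-6


def assert_conserved(cs: ChargeSet, tol: float = CHARGE_SUM_TOL) -> None:
    """Charge conservation: the sum must equal the total formal charge."""
    assert abs(float(cs.charges.sum()) - cs.molecule.total_formal_charge) <= tol


def carbon_path(n_atoms: int, name: str = "path") -> MoleculeGraph:
    """Bare carbon path graph (valences intentionally under-saturated)."""
    return MoleculeGraph(
        atoms=[Atom("C") for _ in range(n_atoms)],
        bonds=[Bond(i, i + 1) for i in range(n_atoms - 1)],
        name=name,
    )


def random_ensemble(rng: np.random.Generator, n_sets: int, n_atoms: int) -> ChargeEnsemble:
    """Random mean-centred charge sets on a carbon path molecule."""
    mol = carbon_path(n_atoms)
    q = rng.normal(0.0, 0.3, size=(n_sets, n_atoms))
    q -= q.mean(axis=1, keepdims=True)
    return ChargeEnsemble(molecule=mol, sets=[ChargeSet(row, mol) for row in q])


@pytest.fixture
def toluene() -> MoleculeGraph:
    """Toluene with a kekulized ring: ring C0-C5, methyl C6, explicit H7-H14."""
    atoms = [Atom("C")] * 7 + [Atom("H")] * 8
    bonds = [
        Bond(0, 1, 1),
        Bond(1, 2, 2),
        Bond(2, 3, 1),
        Bond(3, 4, 2),
        Bond(4, 5, 1),
        Bond(5, 0, 2),
        Bond(0, 6, 1),  # ring-methyl bond
    ]
    bonds += [Bond(i, 6 + i, 1) for i in range(1, 6)]  # one H per ring CH
    bonds += [Bond(6, 12, 1), Bond(6, 13, 1), Bond(6, 14, 1)]  # methyl hydrogens
    return MoleculeGraph(atoms=atoms, bonds=bonds, name="toluene")


@pytest.fixture
def methane() -> MoleculeGraph:
    return MoleculeGraph(
        atoms=[Atom("C")] + [Atom("H")] * 4,
        bonds=[Bond(0, i) for i in range(1, 5)],
        name="methane",
    )


@pytest.fixture
def water() -> MoleculeGraph:
    return MoleculeGraph(
        atoms=[Atom("O"), Atom("H"), Atom("H")],
        bonds=[Bond(0, 1), Bond(0, 2)],
        name="water",
    )
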