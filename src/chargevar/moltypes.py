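"""Core chemical data model: molecular graphs, conformers, charge sets, ensembles.

Atom ordering is the single source of alignment throughout the package: every
:class:`Conformer` and :class:`ChargeSet` of a molecule stores its per-atom data
in the molecule's atom order, and no atom-mapping inference is ever attempted.
Hydrogens are explicit atoms — valence checking and hydrogen capping on
truncation both require them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "MoleculeGraph",
    "Conformer",
    "Provenance",
    "ChargeSet",
    "ChargeEnsemble",
    "AlignmentError",
    "EnsembleError",
    "validate_molecule",
    "validate_conformer",
    "CHARGE_SUM_TOL",
]

#: Tolerance on |sum(q) - total formal charge| for a valid charge set, in e.
CHARGE_SUM_TOL = 1e-6

#: Maximum total bond order (valence) per element.  Sulfur is permitted its
#: hypervalent state, so its ceiling is 6 rather than 2.
MAX_VALENCE: dict[str, int] = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 6,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

#: Plausible range for a bonded inter-atomic distance, in Angstrom.
BOND_DISTANCE_RANGE = (0.7, 2.5)


class AlignmentError(ValueError):
    """Per-atom data does not align with the molecule's atom list."""


class EnsembleError(ValueError):
    """A charge ensemble violates its structural invariants."""


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0


@dataclass(frozen=True)
class Bond:
    u: int
    v: int
    order: int = 1

    def other(self, idx: int) -> int:
        if idx == self.u:
            return self.v
        if idx == self.v:
            return self.u
        raise ValueError(f"atom {idx} is not an endpoint of bond ({self.u},{self.v})")


@dataclass
class MoleculeGraph:
    """A molecular graph with explicit hydrogens.

    Parameters
    ----------
    atoms:
        Per-atom element symbol and integer formal charge (e).
    bonds:
        Bonds as ``(u, v, order)`` with 0-based atom indices and integer
        order in {1, 2, 3}.
    name:
        Free-text identifier used in reports and file output.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = "molecule"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def total_formal_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element, formal_charge=a.formal_charge)
        for b in self.bonds:
            g.add_edge(b.u, b.v, order=b.order)
        return g

    def neighbors(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self.bonds if idx in (b.u, b.v)]

    def valence(self, idx: int) -> int:
        return sum(b.order for b in self.bonds if idx in (b.u, b.v))


@dataclass
class Conformer:
    """One 3D geometry (Angstrom) of a molecule, atom-aligned to its graph."""

    coordinates: np.ndarray
    molecule: MoleculeGraph
    id: str = "conf-0"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.molecule.n_atoms, 3):
            raise AlignmentError(
                f"conformer {self.id!r}: coordinate shape {self.coordinates.shape} "
                f"does not match {self.molecule.n_atoms} atoms"
            )


@dataclass(frozen=True)
class Provenance:
    """Where a charge set came from: method tag, conformer id, platform tag."""

    method: str = "unknown"
    conformer_id: str = ""
    platform: str = ""


@dataclass
class ChargeSet:
    """One per-atom partial-charge vector q (units e), atom-aligned.

    The defining invariant is charge conservation: the charges must sum to the
    molecule's total formal charge to within ``CHARGE_SUM_TOL``.
    """

    charges: np.ndarray
    molecule: MoleculeGraph
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.shape != (self.molecule.n_atoms,):
            raise AlignmentError(
                f"charge set has {self.charges.shape[0] if self.charges.ndim == 1 else '?'} "
                f"charges for {self.molecule.n_atoms} atoms"
            )
        excess = abs(float(self.charges.sum()) - self.molecule.total_formal_charge)
        if excess > CHARGE_SUM_TOL:
            raise ValueError(
                f"charge sum deviates from total formal charge by {excess:.3g} e "
                f"(tolerance {CHARGE_SUM_TOL:g} e)"
            )


@dataclass
class ChargeEnsemble:
    """A molecule together with >= 2 atom-aligned charge sets."""

    molecule: MoleculeGraph
    sets: list[ChargeSet]

    def __post_init__(self) -> None:
        if len(self.sets) < 2:
            raise EnsembleError(f"ensemble needs >= 2 charge sets, got {len(self.sets)}")
        for k, s in enumerate(self.sets):
            if s.molecule is not self.molecule and s.molecule.n_atoms != self.molecule.n_atoms:
                raise AlignmentError(f"charge set {k} is not aligned to the ensemble molecule")

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def charge_matrix(self) -> np.ndarray:
        """Stack charges into an (n_sets, n_atoms) array."""
        return np.vstack([s.charges for s in self.sets])


def validate_molecule(mol: MoleculeGraph) -> list[str]:
    """Check every MoleculeGraph invariant; return human-readable violations.

    An empty list means the molecule is valid.  Checks: bond indices in range
    and distinct, no duplicate bonds, bond orders in {1,2,3}, graph
    connectivity, and per-atom valence against ``MAX_VALENCE``.
    """
    violations: list[str] = []
    n = mol.n_atoms
    if n == 0:
        return ["molecule has no atoms"]

    seen: set[tuple[int, int]] = set()
    for bi, b in enumerate(mol.bonds):
        if not (0 <= b.u < n and 0 <= b.v < n):
            violations.append(f"bond {bi}: index out of range ({b.u},{b.v})")
            continue
        if b.u == b.v:
            violations.append(f"bond {bi}: self-bond at atom {b.u}")
            continue
        key = (min(b.u, b.v), max(b.u, b.v))
        if key in seen:
            violations.append(f"bond {bi}: duplicate bond ({b.u},{b.v})")
        seen.add(key)
        if b.order not in (1, 2, 3):
            violations.append(f"bond {bi}: order {b.order} not in {{1,2,3}}")

    if n > 1:
        g = mol.to_networkx()
        if not nx.is_connected(g):
            violations.append("graph is disconnected")

    for i, atom in enumerate(mol.atoms):
        cap = MAX_VALENCE.get(atom.element)
        if cap is None:
            violations.append(f"atom {i}: element {atom.element!r} has no valence rule")
            continue
        val = mol.valence(i)
        if val > cap:
            violations.append(f"atom {i} ({atom.element}): valence {val} exceeds maximum {cap}")
    return violations


def validate_conformer(conf: Conformer) -> list[str]:
    """Check that every bonded distance is chemically plausible."""
    lo, hi = BOND_DISTANCE_RANGE
    violations: list[str] = []
    for bi, b in enumerate(conf.molecule.bonds):
        r = float(np.linalg.norm(conf.coordinates[b.u] - conf.coordinates[b.v]))
        if not (lo <= r <= hi):
            violations.append(
                f"bond {bi} ({b.u},{b.v}): distance {r:.3f} A outside [{lo}, {hi}] A"
            )
    return violations
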