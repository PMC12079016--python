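"""Synthetic molecules, conformers and charge sets with controlled variability.

This module supplies ground truth for the whole analysis without invoking a
quantum-chemistry engine.  Its charge model is explicitly a stand-in, not an
AM1-BCC emulator; its contract is three-fold:

1. a *conformer-independent* base assignment derived from electronegativity
   differences across bonds (the graph-only limit, analogous to methods that
   give identical charges for every conformer);
2. a *conformer-dependent* perturbation driven by close intramolecular
   contacts — pairs of atoms that are far apart in the bond graph but close
   in space exchange charge with an exponentially decaying weight, with a
   single amplitude knob ``alpha``;
3. optional *hardware-style jitter* of scale ``eta`` emulating small
   platform-dependent numerical differences in charging runs.

All charge operations conserve total charge exactly (antisymmetric pairwise
transfers; mean-centred jitter), and all randomness flows through explicit
integer seeds — there is no global random state.

Molecule templates use a tiny grammar, ``chain(n_heavy)`` or
``chain(n_heavy, {position: element})``: a carbon chain of ``n_heavy`` atoms
with optional single heavy-atom substituents attached at 1-based chain
positions, hydrogens added to complete all valences.  Conformers are built
from idealized internal coordinates — fixed bond lengths from a table, fixed
tetrahedral angles, and uniformly random dihedrals on every heavy-heavy
(rotatable) bond.
"""

from __future__ import annotations

import ast
import math
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .moltypes import (
    Atom,
    Bond,
    ChargeEnsemble,
    ChargeSet,
    Conformer,
    MoleculeGraph,
    Provenance,
    validate_molecule,
)

__all__ = [
    "SynthParams",
    "PAULING_ELECTRONEGATIVITY",
    "BOND_LENGTHS",
    "make_molecule",
    "sample_conformers",
    "base_charges",
    "conformer_charges",
    "hardware_jitter",
    "make_benchmark_ensemble",
]

#: Pauling electronegativities for the supported elements.
PAULING_ELECTRONEGATIVITY: dict[str, float] = {
    "H": 2.20,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "F": 3.98,
    "S": 2.58,
    "Cl": 3.16,
    "Br": 2.96,
    "I": 2.66,
}

#: Equilibrium single-bond lengths in Angstrom, keyed by sorted element pair.
BOND_LENGTHS: dict[tuple[str, str], float] = {
    ("C", "C"): 1.54,
    ("C", "H"): 1.09,
    ("C", "O"): 1.43,
    ("H", "O"): 0.96,
    ("C", "N"): 1.47,
    ("H", "N"): 1.01,
    ("C", "S"): 1.82,
    ("H", "S"): 1.34,
    ("C", "F"): 1.35,
    ("C", "Cl"): 1.77,
    ("C", "Br"): 1.94,
    ("C", "I"): 2.14,
    ("N", "N"): 1.45,
    ("N", "O"): 1.40,
    ("O", "O"): 1.48,
    ("S", "S"): 2.05,
    ("H", "H"): 0.74,
}

#: Valence to fill with hydrogens when building template molecules.
FILL_VALENCE: dict[str, int] = {
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 2,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
    "H": 1,
}

TETRAHEDRAL_ANGLE = math.radians(109.4712206)


@dataclass
class SynthParams:
    """Parameters of the synthetic charge model.

    Parameters
    ----------
    kappa:
        Base-charge scale in e per electronegativity unit; each atom's base
        charge is ``kappa`` times the summed electronegativity differences to
        its bonded neighbours.
    alpha:
        Dimensionless amplitude of the conformer-dependent contact
        perturbation; 0 gives fully conformer-independent charges.
    lambda_decay:
        Decay length (Angstrom) of the contact weight ``exp(-r / lambda)``.
    eta:
        Hardware-style jitter scale in e (standard deviation before
        mean-centring); 0 disables jitter.
    seed:
        Integer seed controlling all randomness downstream.
    """

    kappa: float = 0.08
    alpha: float = 0.05
    lambda_decay: float = 1.5
    eta: float = 0.0
    seed: int = 0
    chi_table: dict[str, float] = field(default_factory=lambda: dict(PAULING_ELECTRONEGATIVITY))
    bond_length_table: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(BOND_LENGTHS)
    )

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be > 0")


_TEMPLATE_RE = re.compile(r"^\s*chain\(\s*(\d+)\s*(?:,\s*(\{.*\})\s*)?\)\s*$")


def parse_template(template: str) -> tuple[int, dict[int, str]]:
    """Parse a ``chain(n[, {pos: element}])`` template string."""
    m = _TEMPLATE_RE.match(template)
    if not m:
        raise ValueError(f"unrecognized template: {template!r}")
    n_heavy = int(m.group(1))
    if n_heavy < 1:
        raise ValueError("chain length must be >= 1")
    subs: dict[int, str] = {}
    if m.group(2):
        raw = ast.literal_eval(m.group(2))
        subs = {int(k): str(v) for k, v in raw.items()}
    for pos, el in subs.items():
        if not (1 <= pos <= n_heavy):
            raise ValueError(f"substituent position {pos} outside chain 1..{n_heavy}")
        if el not in FILL_VALENCE:
            raise ValueError(f"unsupported substituent element {el!r}")
    return n_heavy, subs


def make_molecule(template: str, params: SynthParams | None = None) -> MoleculeGraph:
    """Build a valid MoleculeGraph from a chain template, hydrogens explicit.

    Atom ordering is deterministic: chain carbons first, then substituent
    heavy atoms in position order, then hydrogens in order of the heavy atom
    they complete.
    """
    n_heavy, subs = parse_template(template)
    atoms: list[Atom] = [Atom("C") for _ in range(n_heavy)]
    bonds: list[Bond] = [Bond(i - 1, i, 1) for i in range(1, n_heavy)]

    for pos in sorted(subs):
        idx = len(atoms)
        atoms.append(Atom(subs[pos]))
        bonds.append(Bond(pos - 1, idx, 1))

    # hydrogens fill remaining valence of every heavy atom
    n_heavy_total = len(atoms)
    used = [0] * n_heavy_total
    for b in bonds:
        used[b.u] += 1
        used[b.v] += 1
    for i in range(n_heavy_total):
        deficit = FILL_VALENCE[atoms[i].element] - used[i]
        if deficit < 0:
            raise ValueError(f"template {template!r}: valence of atom {i} over-saturated")
        for _ in range(deficit):
            h = len(atoms)
            atoms.append(Atom("H"))
            bonds.append(Bond(i, h, 1))

    mol = MoleculeGraph(atoms=atoms, bonds=bonds, name=template)
    problems = validate_molecule(mol)
    if problems:
        raise ValueError(f"template {template!r} produced invalid molecule: {problems}")
    return mol


def _bond_length(table: dict[tuple[str, str], float], e1: str, e2: str) -> float:
    key = (min(e1, e2), max(e1, e2))
    try:
        return table[key]
    except KeyError:
        raise KeyError(f"no bond length tabulated for element pair {key}") from None


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float
) -> np.ndarray:
    """Natural-extension-reference-frame placement of an atom at distance r
    from c, angle theta (new-c-b), dihedral phi (new-c-b-a)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(phi), r * math.sin(theta) * math.sin(phi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _spanning_parents(mol: MoleculeGraph) -> tuple[list[int], list[int]]:
    """BFS order and parent index (-1 for the root) over the bond graph."""
    g = mol.to_networkx()
    order: list[int] = []
    parent = [-1] * mol.n_atoms
    seen = {0}
    queue = [0]
    while queue:
        node = queue.pop(0)
        order.append(node)
        for nb in sorted(g.neighbors(node)):
            if nb not in seen:
                seen.add(nb)
                parent[nb] = node
                queue.append(nb)
    return order, parent


def sample_conformers(
    mol: MoleculeGraph, n: int, seed: int, params: SynthParams | None = None
) -> list[Conformer]:
    """Generate ``n`` idealized-geometry conformers of a template molecule.

    Geometries use exact tabulated bond lengths, tetrahedral angles, and
    uniformly random torsions on every bond between two heavy atoms;
    substituent and hydrogen branches are staggered at 120 degree offsets
    around each torsion axis.  Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("need at least one conformer")
    params = params or SynthParams()
    rng = np.random.default_rng(seed)
    order, parent = _spanning_parents(mol)
    children: list[list[int]] = [[] for _ in range(mol.n_atoms)]
    for node in order:
        p = parent[node]
        if p >= 0:
            children[p].append(node)

    heavy = [a.element != "H" for a in mol.atoms]
    # torsion axis for children of p is the bond parent[p]-p; rotatable iff
    # both endpoints are heavy
    rotatable = [
        parent[p] >= 0 and heavy[p] and heavy[parent[p]] and len(children[p]) > 0
        for p in range(mol.n_atoms)
    ]

    d1 = np.array([-1.0, 1.0, 0.0])  # virtual parent of the root (off the +x axis)
    d2 = np.array([-1.0, -1.0, 0.0])  # virtual grandparent of the root

    confs: list[Conformer] = []
    for ci in range(n):
        torsion = {
            p: (rng.uniform(0.0, 2.0 * math.pi) if rotatable[p] else math.pi)
            for p in range(mol.n_atoms)
        }
        coords = np.zeros((mol.n_atoms, 3))
        for node in order:
            p = parent[node]
            if p < 0:
                continue  # root stays at the origin
            r = _bond_length(
                params.bond_length_table, mol.atoms[p].element, mol.atoms[node].element
            )
            g = parent[p]
            sib = children[p].index(node)
            if g < 0:
                # children of the root: first along +x, the rest placed
                # tetrahedrally around the root-to-first-child axis
                if sib == 0:
                    coords[node] = coords[p] + np.array([r, 0.0, 0.0])
                else:
                    first = children[p][0]
                    phi = (sib - 1) * 2.0 * math.pi / 3.0
                    coords[node] = _place_atom(
                        d2, coords[first], coords[p], r, TETRAHEDRAL_ANGLE, phi
                    )
            else:
                a = coords[parent[g]] if parent[g] >= 0 else d1
                phi = torsion[p] + sib * 2.0 * math.pi / 3.0
                coords[node] = _place_atom(a, coords[g], coords[p], r, TETRAHEDRAL_ANGLE, phi)
        confs.append(Conformer(coordinates=coords, molecule=mol, id=f"conf-{ci}"))
    return confs


def base_charges(mol: MoleculeGraph, params: SynthParams | None = None) -> ChargeSet:
    """Conformer-independent base charges from bond electronegativity flow.

    ``q0(i) = formal_charge(i) + kappa * sum_j (chi(j) - chi(i))`` over bonded
    neighbours j.  The electronegativity term is antisymmetric per bond, so
    the total charge equals the total formal charge exactly.
    """
    params = params or SynthParams()
    chi = params.chi_table
    for a in mol.atoms:
        if a.element not in chi:
            raise KeyError(f"element {a.element!r} missing from chi_table")
    q = np.array([float(a.formal_charge) for a in mol.atoms])
    for b in mol.bonds:
        t = params.kappa * (chi[mol.atoms[b.v].element] - chi[mol.atoms[b.u].element])
        q[b.u] += t
        q[b.v] -= t
    return ChargeSet(charges=q, molecule=mol, provenance=Provenance(method="synthetic-base"))


def _eligible_pairs(mol: MoleculeGraph) -> list[tuple[int, int]]:
    """Atom pairs at topological distance >= 3 (beyond 1-2 and 1-3)."""
    g = mol.to_networkx()
    dist = dict(nx.all_pairs_shortest_path_length(g))
    return [
        (i, j)
        for i in range(mol.n_atoms)
        for j in range(i + 1, mol.n_atoms)
        if dist[i].get(j, 10**9) >= 3
    ]


def conformer_charges(
    mol: MoleculeGraph, conf: Conformer, params: SynthParams | None = None
) -> ChargeSet:
    """Geometry-dependent charges: base charges plus contact perturbation.

    Every atom pair beyond the 1-2/1-3 topological exclusion exchanges charge
    ``alpha * (q0(j) - q0(i)) * exp(-r_ij / lambda_decay)``; transfers are
    antisymmetric so total charge is conserved exactly.  Close contacts
    between atoms of unlike base charge therefore perturb charges the most —
    mimicking the strong-intramolecular-interaction mechanism by which some
    conformers yield outlier charge sets.
    """
    params = params or SynthParams()
    q0 = base_charges(mol, params).charges
    q = q0.copy()
    if params.alpha > 0:
        for i, j in _eligible_pairs(mol):
            r = float(np.linalg.norm(conf.coordinates[i] - conf.coordinates[j]))
            t = params.alpha * (q0[j] - q0[i]) * math.exp(-r / params.lambda_decay)
            q[i] += t
            q[j] -= t
    return ChargeSet(
        charges=q,
        molecule=mol,
        provenance=Provenance(method="synthetic-conformer", conformer_id=conf.id),
    )


def hardware_jitter(q: ChargeSet, eta: float, seed: int) -> ChargeSet:
    """Add mean-centred Gaussian noise of scale eta to a charge set.

    Emulates platform-dependent numerical differences between charging runs.
    The noise mean is subtracted so the charge sum is conserved exactly;
    eta = 0 returns charges identical to the input.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    prov = Provenance(
        method=q.provenance.method,
        conformer_id=q.provenance.conformer_id,
        platform=f"jitter-eta{eta:g}-seed{seed}",
    )
    if eta == 0:
        return ChargeSet(charges=q.charges.copy(), molecule=q.molecule, provenance=prov)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, eta, size=q.charges.shape[0])
    noise -= noise.mean()
    return ChargeSet(charges=q.charges + noise, molecule=q.molecule, provenance=prov)


def make_benchmark_ensemble(
    template: str, n_conformers: int, params: SynthParams | None = None
) -> tuple[ChargeEnsemble, list[Conformer]]:
    """Molecule -> conformers -> one charge set per conformer.

    The standard study design: a molecule is charged once per conformer and
    the resulting charge sets are collected into an ensemble for variability
    analysis.  Jitter (if ``params.eta > 0``) is applied per conformer with a
    seed derived from ``(params.seed, conformer index)``.
    """
    params = params or SynthParams()
    mol = make_molecule(template, params)
    confs = sample_conformers(mol, n_conformers, params.seed, params)
    sets: list[ChargeSet] = []
    for k, conf in enumerate(confs):
        cs = conformer_charges(mol, conf, params)
        if params.eta > 0:
            jitter_seed = int(np.random.SeedSequence([params.seed, k]).generate_state(1)[0] % (2**31))
            cs = hardware_jitter(cs, params.eta, jitter_seed)
        cs.provenance = Provenance(
            method=f"synthetic-alpha{params.alpha:g}-eta{params.eta:g}",
            conformer_id=conf.id,
            platform=cs.provenance.platform or f"seed{params.seed}",
        )
        sets.append(cs)
    return ChargeEnsemble(molecule=mol, sets=sets), confs
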