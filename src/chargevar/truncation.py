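"""Molecule truncation: cut an acyclic single bond, keep one fragment, cap with H.

Charge assignment cost grows steeply with atom count, so large flexible
molecules are routinely reduced before charging by removing a peripheral
functional group across a single bond and completing the opened valence with
a hydrogen.  Only single, acyclic bonds are cuttable; the cap is always a
hydrogen.  Retained atoms keep their original relative order, with the new
hydrogen appended last, so downstream per-atom data for the retained
fragment can be compared index-wise after remapping.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .moltypes import Atom, Bond, Conformer, MoleculeGraph, validate_molecule
from .synthetic_data import BOND_LENGTHS, _bond_length

__all__ = ["truncate_at_bond", "TruncationError"]


class TruncationError(ValueError):
    """The requested cut violates a truncation precondition."""


def truncate_at_bond(
    mol: MoleculeGraph,
    bond: tuple[int, int],
    keep: int,
    conf: Conformer | None = None,
) -> tuple[MoleculeGraph, Conformer | None, list[int]]:
    """Cut ``bond``, keep the fragment containing ``keep``, cap with hydrogen.

    Parameters
    ----------
    mol:
        Molecule to truncate.
    bond:
        The (u, v) atom-index pair of the bond to cut; must exist, be a
        single bond, and lie outside every cycle.
    keep:
        Which endpoint's fragment survives; must be ``u`` or ``v``.
    conf:
        Optional geometry to carry over.  The capping hydrogen is placed
        along the former bond vector at the tabulated X-H bond length.

    Returns
    -------
    (truncated molecule, carried conformer or None, old->kept atom indices)
        The last element lists the retained original atom indices in their
        new order (the capping hydrogen is the final atom and has no
        original index).
    """
    u, v = bond
    the_bond = None
    for b in mol.bonds:
        if {b.u, b.v} == {u, v}:
            the_bond = b
            break
    if the_bond is None:
        raise TruncationError(f"no bond between atoms {u} and {v}")
    if the_bond.order != 1:
        raise TruncationError(f"bond ({u},{v}) has order {the_bond.order}; only single bonds are cuttable")
    if keep not in (u, v):
        raise TruncationError(f"keep={keep} is not an endpoint of bond ({u},{v})")

    g_cut = mol.to_networkx()
    g_cut.remove_edge(u, v)
    if nx.has_path(g_cut, u, v):  # endpoints still connected => the bond was in a ring
        raise TruncationError(f"bond ({u},{v}) lies in a ring and cannot be cut")

    kept = sorted(nx.node_connected_component(g_cut, keep))
    discard_end = v if keep == u else u
    remap = {old: new for new, old in enumerate(kept)}

    atoms = [mol.atoms[i] for i in kept]
    bonds = [
        Bond(remap[b.u], remap[b.v], b.order)
        for b in mol.bonds
        if b.u in remap and b.v in remap
    ]
    h_idx = len(atoms)
    atoms.append(Atom("H"))
    bonds.append(Bond(remap[keep], h_idx, 1))

    out = MoleculeGraph(atoms=atoms, bonds=bonds, name=f"{mol.name}|cut({u},{v})keep{keep}")
    problems = validate_molecule(out)
    if problems:
        raise TruncationError(f"truncation produced an invalid molecule: {problems}")

    new_conf = None
    if conf is not None:
        coords = np.vstack([conf.coordinates[kept]])
        direction = conf.coordinates[discard_end] - conf.coordinates[keep]
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise TruncationError("cut bond has zero length in the supplied conformer")
        r = _bond_length(BOND_LENGTHS, mol.atoms[keep].element, "H")
        h_pos = conf.coordinates[keep] + direction / norm * r
        coords = np.vstack([coords, h_pos])
        new_conf = Conformer(coordinates=coords, molecule=out, id=f"{conf.id}|truncated")
    return out, new_conf, kept
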