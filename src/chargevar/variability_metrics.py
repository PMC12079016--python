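"""Charge-variability metrics over ensembles of partial-charge sets.

Two headline metrics quantify how much geometry-dependent charging varies for
one molecule:

* **maximal partial charge difference** — the largest per-atom range
  (max - min) of charge across all sets in the ensemble, i.e. the largest
  value of ``max_u |q1(u) - q2(u)|`` over any pair of sets;
* **maximal dq_bond difference** — for each bond (u, v) the bond charge
  difference ``dq_bond = q(u) - q(v)`` is a proxy for bond polarity; this
  metric is the largest per-bond range of dq_bond across the ensemble.

Both are computed as per-element max - min over the stacked charge matrix,
which is mathematically identical to the maximum over all set pairs (the
pairwise forms are kept as test oracles).  The sign convention of dq_bond
(u minus v, in bond storage order) is observationally irrelevant: every
reported quantity is an absolute range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moltypes import AlignmentError, ChargeEnsemble, ChargeSet, MoleculeGraph

__all__ = [
    "BondDeltaSet",
    "VariabilityReport",
    "pairwise_max_atom_diff",
    "per_atom_range",
    "max_charge_range",
    "bond_delta_q",
    "per_bond_range",
    "pairwise_max_bond_diff",
    "max_bond_delta_range",
    "variability_report",
    "compare_matched_sets",
]


@dataclass
class BondDeltaSet:
    """Per-bond charge differences q(u) - q(v), ordered as the bond list."""

    deltas: np.ndarray
    source_id: str = ""


@dataclass
class VariabilityReport:
    """Full per-atom / per-bond variability summary for one ensemble."""

    per_atom_range: np.ndarray
    per_bond_range: np.ndarray
    max_atom_range: float
    max_bond_range: float
    argmax_atom: int
    argmax_bond: int
    n_sets: int
    molecule_name: str = ""


def _check_aligned(q1: ChargeSet, q2: ChargeSet) -> None:
    if q1.charges.shape != q2.charges.shape:
        raise AlignmentError(
            f"charge sets have different lengths: {q1.charges.shape[0]} vs {q2.charges.shape[0]}"
        )


def pairwise_max_atom_diff(q1: ChargeSet, q2: ChargeSet) -> float:
    """Largest absolute per-atom charge difference between two sets (e).

    Symmetric in its arguments and zero iff the sets are identical.
    """
    _check_aligned(q1, q2)
    return float(np.max(np.abs(q1.charges - q2.charges)))


def per_atom_range(ens: ChargeEnsemble) -> np.ndarray:
    """Per-atom charge range max_k q_k(u) - min_k q_k(u) across all sets (e)."""
    q = ens.charge_matrix()
    return q.max(axis=0) - q.min(axis=0)


def max_charge_range(ens: ChargeEnsemble) -> float:
    """Maximal partial charge difference: the largest per-atom range (e)."""
    return float(per_atom_range(ens).max())


def bond_delta_q(q: ChargeSet, mol: MoleculeGraph) -> BondDeltaSet:
    """Bond charge differences q(u) - q(v) for every bond, in storage order."""
    if q.charges.shape[0] != mol.n_atoms:
        raise AlignmentError(
            f"charge set length {q.charges.shape[0]} does not match {mol.n_atoms} atoms"
        )
    u = np.fromiter((b.u for b in mol.bonds), dtype=int, count=mol.n_bonds)
    v = np.fromiter((b.v for b in mol.bonds), dtype=int, count=mol.n_bonds)
    return BondDeltaSet(deltas=q.charges[u] - q.charges[v], source_id=q.provenance.conformer_id)


def _bond_delta_matrix(ens: ChargeEnsemble) -> np.ndarray:
    mol = ens.molecule
    u = np.fromiter((b.u for b in mol.bonds), dtype=int, count=mol.n_bonds)
    v = np.fromiter((b.v for b in mol.bonds), dtype=int, count=mol.n_bonds)
    q = ens.charge_matrix()
    return q[:, u] - q[:, v]


def per_bond_range(ens: ChargeEnsemble) -> np.ndarray:
    """Per-bond range (max - min) of dq_bond across all sets (e)."""
    d = _bond_delta_matrix(ens)
    return d.max(axis=0) - d.min(axis=0)


def pairwise_max_bond_diff(q1: ChargeSet, q2: ChargeSet, mol: MoleculeGraph) -> float:
    """Largest absolute difference in dq_bond between two sets, over bonds (e).

    Bounded above by ``2 * pairwise_max_atom_diff(q1, q2)`` (triangle
    inequality on the two endpoint differences).
    """
    _check_aligned(q1, q2)
    d1 = bond_delta_q(q1, mol).deltas
    d2 = bond_delta_q(q2, mol).deltas
    if d1.size == 0:
        return 0.0
    return float(np.max(np.abs(d1 - d2)))


def max_bond_delta_range(ens: ChargeEnsemble) -> float:
    """Maximal dq_bond difference: the largest per-bond range (e)."""
    r = per_bond_range(ens)
    return float(r.max()) if r.size else 0.0


def variability_report(ens: ChargeEnsemble) -> VariabilityReport:
    """Compute the full variability summary for an ensemble."""
    atom_r = per_atom_range(ens)
    bond_r = per_bond_range(ens)
    return VariabilityReport(
        per_atom_range=atom_r,
        per_bond_range=bond_r,
        max_atom_range=float(atom_r.max()),
        max_bond_range=float(bond_r.max()) if bond_r.size else 0.0,
        argmax_atom=int(atom_r.argmax()),
        argmax_bond=int(bond_r.argmax()) if bond_r.size else -1,
        n_sets=ens.n_sets,
        molecule_name=ens.molecule.name,
    )


def compare_matched_sets(ensA: ChargeEnsemble, ensB: ChargeEnsemble) -> tuple[np.ndarray, float]:
    """Matched-pair comparison of two ensembles of the same conformers.

    Used for the cross-platform study: the same conformers charged in two
    environments give two ensembles whose k-th sets derive from the same
    conformer.  Returns the per-pair maximal atom charge difference and the
    overall maximum.
    """
    if ensA.n_sets != ensB.n_sets:
        raise AlignmentError(
            f"matched comparison needs equal set counts, got {ensA.n_sets} vs {ensB.n_sets}"
        )
    for k, (a, b) in enumerate(zip(ensA.sets, ensB.sets)):
        if a.provenance.conformer_id != b.provenance.conformer_id:
            raise AlignmentError(
                f"set {k}: conformer ids differ "
                f"({a.provenance.conformer_id!r} vs {b.provenance.conformer_id!r})"
            )
    per_pair = np.array(
        [pairwise_max_atom_diff(a, b) for a, b in zip(ensA.sets, ensB.sets)], dtype=float
    )
    return per_pair, float(per_pair.max())
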