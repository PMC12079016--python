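"""File formats: SDF with per-atom charges, ensemble JSON, metric/selection CSV.

SDF records carry charges in the ``PARTIAL_CHARGES`` data field
(whitespace-separated, atom order, 6 decimal places); on read the
``atom.dprop.PartialCharge`` per-atom-line dialect is accepted as well.
Because fixed-precision printing can leave a tiny residue on the charge sum,
the writer balances the rounded values by one unit in the last place on as
few atoms as necessary so every written record still satisfies the
charge-conservation invariant on re-read.

All atom indices in JSON and CSV are 0-based; the SDF bond block uses the
format's native 1-based indices (converted internally).  All writers are
deterministic; all readers reject rather than repair malformed input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D

from .moltypes import (
    Atom,
    Bond,
    ChargeEnsemble,
    ChargeSet,
    Conformer,
    MoleculeGraph,
    Provenance,
)
from .variability_metrics import VariabilityReport

__all__ = [
    "SCHEMA_VERSION",
    "SdfRecord",
    "read_sdf",
    "write_sdf",
    "write_ensemble_json",
    "read_ensemble_json",
    "write_metrics_csv",
    "write_selection_csv",
]

SCHEMA_VERSION = 1

#: An SDF record: molecule, geometry, and (optionally) its charge set.
SdfRecord = tuple[MoleculeGraph, Conformer, ChargeSet | None]

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _to_rdkit(mol: MoleculeGraph, conf: Conformer) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in mol.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.formal_charge)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    for b in mol.bonds:
        rw.AddBond(b.u, b.v, _BOND_TYPES[b.order])
    rdconf = Chem.Conformer(mol.n_atoms)
    for i, (x, y, z) in enumerate(conf.coordinates):
        rdconf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m = rw.GetMol()
    m.AddConformer(rdconf)
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
    m.SetProp("_Name", mol.name)
    return m


def _balanced_rounded(q: ChargeSet) -> list[float]:
    """Round charges to 6 dp and balance the residual one ulp at a time."""
    vals = [round(float(c), 6) for c in q.charges]
    target = float(q.molecule.total_formal_charge)
    residual = target - sum(vals)
    step = 1e-6 if residual > 0 else -1e-6
    n_steps = int(round(abs(residual) / 1e-6))
    # spread the correction over the largest-|q| atoms, one ulp each
    order = sorted(range(len(vals)), key=lambda i: (-abs(vals[i]), i))
    for k in range(min(n_steps, len(vals))):
        vals[order[k]] = round(vals[order[k]] + step, 6)
    return vals


def write_sdf(records: Iterable[SdfRecord], path: str | Path) -> None:
    """Write V2000 SDF records with charges in the PARTIAL_CHARGES field.

    Deterministic: identical input produces byte-identical files.
    """
    path = Path(path)
    chunks: list[str] = []
    for mol, conf, charges in records:
        m = _to_rdkit(mol, conf)
        block = Chem.MolToMolBlock(m, kekulize=False)
        props = ""
        if charges is not None:
            txt = " ".join(f"{v:.6f}" for v in _balanced_rounded(charges))
            props += f">  <PARTIAL_CHARGES>\n{txt}\n\n"
            if charges.provenance.conformer_id:
                props += f">  <CONFORMER_ID>\n{charges.provenance.conformer_id}\n\n"
        chunks.append(block + props + "$$$$\n")
    path.write_text("".join(chunks))


def _parse_charges(rd: Chem.Mol, n_atoms: int) -> np.ndarray | None:
    if rd.HasProp("PARTIAL_CHARGES"):
        vals = [float(t) for t in rd.GetProp("PARTIAL_CHARGES").split()]
    elif rd.HasProp("atom.dprop.PartialCharge"):
        vals = [float(t) for t in rd.GetProp("atom.dprop.PartialCharge").split()]
    else:
        return None
    if len(vals) != n_atoms:
        raise ValueError(
            f"record has {len(vals)} partial charges for {n_atoms} atoms"
        )
    return np.array(vals)


def read_sdf(path: str | Path) -> list[SdfRecord]:
    """Read V2000 SDF records; charges are optional per record."""
    if Path(path).read_text().strip() == "":
        return []  # a valid empty file holds zero records
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: list[SdfRecord] = []
    for ri, rd in enumerate(supplier):
        if rd is None:
            raise ValueError(f"malformed SDF record at index {ri}")
        atoms = [Atom(a.GetSymbol(), a.GetFormalCharge()) for a in rd.GetAtoms()]
        bonds = [
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
            for b in rd.GetBonds()
        ]
        name = rd.GetProp("_Name") if rd.HasProp("_Name") else f"record-{ri}"
        mol = MoleculeGraph(atoms=atoms, bonds=bonds, name=name)
        coords = rd.GetConformer().GetPositions()
        conf_id = rd.GetProp("CONFORMER_ID") if rd.HasProp("CONFORMER_ID") else f"record-{ri}"
        conf = Conformer(coordinates=np.asarray(coords), molecule=mol, id=conf_id)
        qvals = _parse_charges(rd, mol.n_atoms)
        charges = (
            ChargeSet(
                charges=qvals,
                molecule=mol,
                provenance=Provenance(method="sdf", conformer_id=conf_id),
            )
            if qvals is not None
            else None
        )
        out.append((mol, conf, charges))
    return out


# ---------------------------------------------------------------------------
# ensemble JSON archive


def write_ensemble_json(
    path: str | Path,
    ensemble: ChargeEnsemble,
    conformers: list[Conformer] | None = None,
) -> None:
    """Serialize an ensemble (and its conformers) to a versioned JSON archive."""
    mol = ensemble.molecule
    doc = {
        "schema_version": SCHEMA_VERSION,
        "molecule": {
            "name": mol.name,
            "atoms": [[a.element, a.formal_charge] for a in mol.atoms],
            "bonds": [[b.u, b.v, b.order] for b in mol.bonds],
        },
        "conformers": [
            {"id": c.id, "coordinates": c.coordinates.tolist()} for c in (conformers or [])
        ],
        "charge_sets": [
            {
                "provenance": {
                    "method": s.provenance.method,
                    "conformer_id": s.provenance.conformer_id,
                    "platform": s.provenance.platform,
                },
                "charges": s.charges.tolist(),
            }
            for s in ensemble.sets
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_ensemble_json(path: str | Path) -> tuple[ChargeEnsemble, list[Conformer]]:
    """Read a JSON archive; rejects unknown schema versions and broken references."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported ensemble archive schema version: {version!r}")
    mb = doc["molecule"]
    mol = MoleculeGraph(
        atoms=[Atom(el, int(fc)) for el, fc in mb["atoms"]],
        bonds=[Bond(int(u), int(v), int(o)) for u, v, o in mb["bonds"]],
        name=mb["name"],
    )
    conformers = [
        Conformer(coordinates=np.array(cb["coordinates"]), molecule=mol, id=cb["id"])
        for cb in doc["conformers"]
    ]
    known_ids = {c.id for c in conformers}
    sets = []
    for sb in doc["charge_sets"]:
        prov = sb["provenance"]
        cid = prov.get("conformer_id", "")
        if conformers and cid and cid not in known_ids:
            raise ValueError(f"charge set references unknown conformer id {cid!r}")
        sets.append(
            ChargeSet(
                charges=np.array(sb["charges"]),
                molecule=mol,
                provenance=Provenance(
                    method=prov.get("method", ""),
                    conformer_id=cid,
                    platform=prov.get("platform", ""),
                ),
            )
        )
    return ChargeEnsemble(molecule=mol, sets=sets), conformers


# ---------------------------------------------------------------------------
# CSV reports

METRICS_COLUMNS = [
    "molecule",
    "n_sets",
    "max_partial_charge_diff_e",
    "max_dqbond_diff_e",
    "argmax_atom",
    "argmax_bond",
]


def write_metrics_csv(reports: Iterable[VariabilityReport], path: str | Path) -> None:
    """Write one metrics row per molecule (sorted by molecule name)."""
    rows = [
        {
            "molecule": r.molecule_name,
            "n_sets": r.n_sets,
            "max_partial_charge_diff_e": r.max_atom_range,
            "max_dqbond_diff_e": r.max_bond_range,
            "argmax_atom": r.argmax_atom,
            "argmax_bond": r.argmax_bond,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS).sort_values("molecule")
    df.to_csv(path, index=False)


def write_selection_csv(rows: list[dict], path: str | Path) -> None:
    """Write selection rows (id, value, stratum or rank) as-is, in order."""
    pd.DataFrame(rows).to_csv(path, index=False)
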