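"""Electrostatically least-interacting conformer filtering and charge averaging.

Multi-conformer charging reduces conformer dependence by (1) scoring each
conformer's internal electrostatic repulsion with all partial charges made
positive — conformers with strong internal contacts score high and are the
ones whose charges deviate most; (2) keeping the lowest-scoring top fraction
(default 2%) of conformers; (3) picking a diverse subset (default 10) from
that pool; and (4) averaging the selected conformers' charge sets atom-wise.

The proprietary reference implementation does not document its diversity
criterion or its exact electrostatic form; the documented stand-ins here are
heavy-atom-inclusive Kabsch RMSD with greedy max-min selection, and a bare
``sum |q_i||q_j| / r_ij`` over pairs beyond the 1-2/1-3 topological
exclusion.  Both are deterministic and order-independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .moltypes import AlignmentError, ChargeSet, Conformer, Provenance

__all__ = [
    "ElfConfig",
    "intramolecular_repulsion_score",
    "kabsch_rmsd",
    "greedy_diverse_subset",
    "elf_select",
    "elf_consensus_charges",
]


@dataclass
class ElfConfig:
    """Settings for electrostatically-least-interacting conformer selection.

    ``top_fraction`` is the proportion of lowest-scoring conformers retained
    as the candidate pool (default 2%); ``n_select`` how many diverse
    conformers are averaged (default 10); ``min_conformers`` the recommended
    minimum input count (default 500) below which a warning — not an error —
    is emitted, so that small-scale runs remain possible; ``distance_floor``
    caps the 1/r singularity for pathological geometries.
    """

    top_fraction: float = 0.02
    n_select: int = 10
    min_conformers: int = 500
    exclude_topology: tuple[int, ...] = (1, 2)  # graph distances to skip (1-2, 1-3 pairs)
    distance_floor: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.distance_floor <= 0:
            raise ValueError("distance_floor must be > 0")


def _scored_pairs(conf: Conformer, cfg: ElfConfig) -> list[tuple[int, int]]:
    g = conf.molecule.to_networkx()
    dist = dict(nx.all_pairs_shortest_path_length(g))
    skip = set(cfg.exclude_topology)
    n = conf.molecule.n_atoms
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if dist[i].get(j, 10**9) not in skip
    ]


def intramolecular_repulsion_score(
    conf: Conformer, q: ChargeSet, cfg: ElfConfig | None = None
) -> float:
    """Internal electrostatic repulsion with all charges made positive (e^2/A).

    ``sum over eligible pairs of |q_i| |q_j| / max(r_ij, distance_floor)``,
    where eligible pairs are those beyond the configured topological
    exclusion.  Lower scores mean fewer or weaker close contacts — the
    conformers a consensus charge should be built from.
    """
    cfg = cfg or ElfConfig()
    if q.charges.shape[0] != conf.molecule.n_atoms:
        raise AlignmentError("charge set not aligned to conformer's molecule")
    aq = np.abs(q.charges)
    score = 0.0
    for i, j in _scored_pairs(conf, cfg):
        r = float(np.linalg.norm(conf.coordinates[i] - conf.coordinates[j]))
        score += aq[i] * aq[j] / max(r, cfg.distance_floor)
    return score


def kabsch_rmsd(confA: Conformer, confB: Conformer) -> float:
    """Minimal RMSD (Angstrom) over rigid superposition with proper rotations.

    Both geometries are centred and the optimal proper rotation is found by
    the Kabsch/SVD procedure (with the determinant correction that forbids
    reflections); symmetric in its arguments and zero for congruent
    geometries, including degenerate collinear and two-point cases.
    """
    if confA.coordinates.shape != confB.coordinates.shape:
        raise AlignmentError("conformers have different atom counts")
    a = confA.coordinates - confA.coordinates.mean(axis=0)
    b = confB.coordinates - confB.coordinates.mean(axis=0)
    n = a.shape[0]
    u, s, vt = np.linalg.svd(b.T @ a)
    sign = np.sign(np.linalg.det(u @ vt))
    trace = s[0] + s[1] + sign * s[2]
    msd = max(0.0, (np.sum(a * a) + np.sum(b * b) - 2.0 * trace) / n)
    return math.sqrt(msd)


def greedy_diverse_subset(confs: list[Conformer], k: int, seed_index: int) -> list[int]:
    """Greedy max-min diverse selection of k conformer indices.

    Starting from ``seed_index``, repeatedly add the conformer whose minimum
    Kabsch RMSD to the already-chosen set is largest; ties break to the
    lowest index.  Deterministic.
    """
    n = len(confs)
    if k > n:
        raise ValueError(f"cannot select {k} of {n} conformers")
    if not (0 <= seed_index < n):
        raise ValueError("seed_index out of range")
    chosen = [seed_index]
    # distance of every candidate to the nearest chosen conformer
    min_d = np.array([kabsch_rmsd(confs[i], confs[seed_index]) for i in range(n)])
    min_d[seed_index] = -np.inf
    while len(chosen) < k:
        nxt = int(np.argmax(min_d))  # argmax takes the first (lowest) index on ties
        chosen.append(nxt)
        new_d = np.array([kabsch_rmsd(confs[i], confs[nxt]) for i in range(n)])
        min_d = np.minimum(min_d, new_d)
        min_d[nxt] = -np.inf
    return chosen


def elf_select(
    confs: list[Conformer], sets: list[ChargeSet], cfg: ElfConfig | None = None
) -> list[int]:
    """Indices of the diverse low-interaction conformers to average.

    The pool is the ``ceil(top_fraction * count)`` lowest-scoring conformers
    (enlarged to ``n_select`` if smaller), seeded at the lowest-scoring pool
    member; scoring ties break to the lowest index.
    """
    cfg = cfg or ElfConfig()
    if len(confs) != len(sets):
        raise AlignmentError("need exactly one charge set per conformer")
    n = len(confs)
    if n < cfg.n_select:
        raise ValueError(f"need >= {cfg.n_select} conformers, got {n}")
    if n < cfg.min_conformers:
        warnings.warn(
            f"{n} conformers is below the recommended minimum of {cfg.min_conformers}; "
            "selection proceeds but the pool may be unrepresentative",
            stacklevel=2,
        )
    scores = np.array(
        [intramolecular_repulsion_score(c, q, cfg) for c, q in zip(confs, sets)]
    )
    pool_size = max(math.ceil(cfg.top_fraction * n), cfg.n_select)
    order = np.argsort(scores, kind="stable")  # stable sort -> lowest index wins ties
    pool = sorted(int(i) for i in order[:pool_size])
    pool_confs = [confs[i] for i in pool]
    seed_local = pool.index(int(order[0]))
    picked_local = greedy_diverse_subset(pool_confs, cfg.n_select, seed_local)
    return [pool[i] for i in picked_local]


def elf_consensus_charges(
    confs: list[Conformer], sets: list[ChargeSet], cfg: ElfConfig | None = None
) -> ChargeSet:
    """Atom-wise mean of the selected conformers' charge sets.

    The consensus conserves total charge exactly (the mean of vectors with a
    common sum has that sum); provenance records the selected conformer ids.
    """
    cfg = cfg or ElfConfig()
    picked = elf_select(confs, sets, cfg)
    q = np.mean([sets[i].charges for i in picked], axis=0)
    mol = sets[picked[0]].molecule
    # re-centre the numerical residue of the mean onto exact conservation
    q = q + (mol.total_formal_charge - q.sum()) / q.shape[0]
    ids = ",".join(confs[i].id for i in picked)
    return ChargeSet(
        charges=q,
        molecule=mol,
        provenance=Provenance(method="elf-consensus", conformer_id=ids),
    )
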