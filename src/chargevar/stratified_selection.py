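"""Molecule selection: sigma-window stratification and ranked picking.

Two selection procedures feed downstream simulation studies:

* **stratify** bins molecules by a variability metric into three windows of
  the metric's distribution — "good" (low variability, ``[mean - 1.8 sd,
  mean - 1.0 sd]``), "average" (``[mean - 0.4 sd, mean + 0.4 sd]``) and
  "bad" (high variability, ``[mean + 1.0 sd, mean + 1.8 sd]``) — and picks a
  fixed number per window;
* **rank_and_pick** orders molecules by their maximal bond-polarity range
  descending and greedily accepts candidates that are not too similar to
  those already accepted, replacing a manual similarity screen with a
  deterministic Tanimoto-on-labeled-paths rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .moltypes import MoleculeGraph
from .variability_metrics import VariabilityReport

__all__ = [
    "StratumWindows",
    "StratifiedSelection",
    "DegenerateDistributionError",
    "stratify",
    "similarity",
    "rank_and_pick",
]


class DegenerateDistributionError(ValueError):
    """The metric distribution has zero spread; windows are undefined."""


@dataclass(frozen=True)
class StratumWindows:
    """Closed selection windows derived from a sample mean and sd (both e)."""

    mean: float
    sd: float

    @property
    def good(self) -> tuple[float, float]:
        return (self.mean - 1.8 * self.sd, self.mean - 1.0 * self.sd)

    @property
    def average(self) -> tuple[float, float]:
        return (self.mean - 0.4 * self.sd, self.mean + 0.4 * self.sd)

    @property
    def bad(self) -> tuple[float, float]:
        return (self.mean + 1.0 * self.sd, self.mean + 1.8 * self.sd)

    def window(self, stratum: str) -> tuple[float, float]:
        return {"good": self.good, "average": self.average, "bad": self.bad}[stratum]


@dataclass
class StratifiedSelection:
    windows: StratumWindows
    strata: dict[str, list[str]]  # stratum -> selected molecule ids
    values: dict[str, float] = field(default_factory=dict)  # id -> metric value


STRATA = ("good", "average", "bad")


def stratify(values: dict[str, float], n_per_stratum: int = 5) -> StratifiedSelection:
    """Select up to ``n_per_stratum`` molecules per variability stratum.

    The sample mean and standard deviation (n-1 denominator) of the supplied
    metric values define the three closed windows.  Within each window the
    ``n_per_stratum`` values closest to the window midpoint are selected (ties
    break to the lexicographically lower molecule id); a value lying in two
    windows belongs to the more extreme stratum.  Strata are under-filled if
    candidates are scarce.  Zero spread raises
    :class:`DegenerateDistributionError`.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    if len(values) < 3:
        raise ValueError("need at least 3 molecules to stratify")
    arr = np.array(list(values.values()), dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0 or np.ptp(arr) == 0.0:
        raise DegenerateDistributionError(
            "all metric values are identical; stratification windows are degenerate"
        )
    win = StratumWindows(mean=mean, sd=sd)

    # extreme strata claim boundary values first, so "good"/"bad" beat "average"
    def stratum_of(v: float) -> str | None:
        for s in ("good", "bad", "average"):
            lo, hi = win.window(s)
            if lo <= v <= hi:
                return s
        return None

    members: dict[str, list[tuple[str, float]]] = {s: [] for s in STRATA}
    for mid in sorted(values):
        s = stratum_of(values[mid])
        if s is not None:
            members[s].append((mid, values[mid]))

    strata: dict[str, list[str]] = {}
    for s in STRATA:
        lo, hi = win.window(s)
        centre = (lo + hi) / 2.0
        ranked = sorted(members[s], key=lambda t: (abs(t[1] - centre), t[0]))
        strata[s] = [mid for mid, _ in ranked[:n_per_stratum]]
    return StratifiedSelection(windows=win, strata=strata, values=dict(values))


def _labeled_paths(mol: MoleculeGraph, max_len: int = 4) -> set[str]:
    """Element-labeled simple paths of 1..max_len bonds, canonical direction."""
    g = mol.to_networkx()
    paths: set[str] = set()

    def extend(path: list[int]) -> None:
        if len(path) > 1:
            labels = [mol.atoms[i].element for i in path]
            paths.add(min("-".join(labels), "-".join(reversed(labels))))
        if len(path) - 1 == max_len:
            return
        for nb in g.neighbors(path[-1]):
            if nb not in path:
                extend(path + [nb])

    for start in range(mol.n_atoms):
        extend([start])
    return paths


def similarity(molA: MoleculeGraph, molB: MoleculeGraph) -> float:
    """Tanimoto coefficient over element-labeled simple-path sets.

    Paths of one to four bonds are enumerated, labeled by their element
    sequences, and canonicalized by direction; the similarity is
    ``|A & B| / |A | B|``.  Symmetric, in [0, 1], and 1 for molecules with
    identical path sets (in particular, isomorphic labeled graphs).
    """
    pa = _labeled_paths(molA)
    pb = _labeled_paths(molB)
    union = pa | pb
    if not union:
        return 1.0 if molA.n_atoms and molB.n_atoms else 0.0
    return len(pa & pb) / len(union)


def rank_and_pick(
    reports: dict[str, VariabilityReport],
    k: int,
    pool: int,
    mols: dict[str, MoleculeGraph],
    tau: float = 0.6,
) -> list[str]:
    """Pick up to ``k`` high-variability molecules, avoiding near-duplicates.

    Molecules are sorted by maximal bond-polarity range descending (ties
    break to the lower id), restricted to the top ``pool``, then accepted
    greedily whenever their similarity to every already-accepted molecule is
    below ``tau``.  Fully deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (k <= pool <= len(reports)):
        raise ValueError(f"need k <= pool <= {len(reports)}, got k={k}, pool={pool}")
    ranked = sorted(reports, key=lambda mid: (-reports[mid].max_bond_range, mid))[:pool]
    accepted: list[str] = []
    for mid in ranked:
        if len(accepted) == k:
            break
        if all(similarity(mols[mid], mols[a]) < tau for a in accepted):
            accepted.append(mid)
    return accepted
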