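# Methods

## Problem

Geometry-dependent partial-charge assignment (AM1-BCC and relatives) gives a
different per-atom charge vector — a *partial charge set* — for every input
conformer, and small numerical differences between platforms add further
variation. Because fixed-charge force fields feed these charges directly into
Coulombic terms, the variability propagates into computed observables such as
hydration free energies. `chargevar` implements the analysis side of this
problem: quantifying charge variability over an ensemble of charge sets,
constructing a consensus charge from electrostatically least-interacting
conformers, selecting molecules by variability stratum or rank, and truncating
molecules before expensive charging. A synthetic charge generator supplies
ensembles with known, tunable variability so the whole pipeline can be
validated without a quantum-chemistry engine.

## Variability metrics

For a molecule with atom set A, bond set B, and charge sets q_1 … q_K
(all atom-aligned by construction; no atom-mapping inference is ever done):

* **Maximal partial charge difference**
  `max_u [ max_k q_k(u) − min_k q_k(u) ]` — the largest per-atom range.
  It equals the maximum over all set pairs (k, l) of
  `max_u |q_k(u) − q_l(u)|`; the package computes the O(K·|A|) range form and
  keeps the exhaustive pairwise form as a test oracle.
* **Maximal Δq_bond difference** — per bond (u, v), the bond polarity proxy
  is `Δq_bond = q(u) − q(v)`; the metric is the largest per-bond range of
  Δq_bond across sets. We read the pairwise form of the bond metric as
  `|(q1(u) − q1(v)) − (q2(u) − q2(v))|`: the difference *of the bond deltas*
  between two charge sets. (Without the inner grouping the expression would
  not vanish for identical sets, contradicting the definition of the metric
  as a range across sets.) The sign convention (u minus v, in bond storage
  order) is irrelevant to every reported number, which is always an absolute
  range; this is covered by tests.

A triangle inequality links the two:
`max Δq_bond range ≤ 2 × max charge range`, with equality attained by
anti-correlated endpoint shifts on a single bond.

The matched-pair comparison (`compare_matched_sets`) handles the
cross-platform design: the same conformers charged in two environments give
two ensembles whose k-th sets share a conformer id; the per-pair maximal atom
difference and its overall maximum are the reported quantities.

## Consensus charging (ELF-style)

Conformers are scored by internal electrostatic repulsion *with all charges
made positive*: `Σ |q_i||q_j| / max(r_ij, r_floor)` over atom pairs beyond the
1-2/1-3 topological exclusion (those distances are fixed by covalent geometry
and carry no conformational signal). The lowest-scoring `top_fraction`
(default 2%) of conformers — enlarged to `n_select` if smaller — form the
pool; a greedy max-min selection under Kabsch RMSD, seeded at the
lowest-scoring conformer with ties broken by index, picks `n_select`
(default 10) diverse conformers; their charge sets are averaged atom-wise.
The reference implementation of this idea is proprietary and does not
document its diversity criterion, exclusion rules, or dielectric treatment;
the choices above are this package's own deterministic stand-ins and are
documented as such. `min_conformers` defaults to 500, the recommended input
size for this family of methods, but emits a warning rather than an error
below it so that smaller studies remain possible; this package's own studies
and tests run with 30–150 conformers per batch.

Kabsch RMSD is computed directly by SVD with the determinant correction that
forbids reflections, which remains exact for degenerate (planar, collinear,
two-point) geometries.

## Synthetic charge model

The generator is a stand-in with three contractual properties, not an
emulator of any quantum-chemical method:

1. **Base charges** (conformer-independent limit):
   `q0(i) = formal_charge(i) + κ Σ_j (χ(j) − χ(i))` over bonded neighbours,
   with Pauling electronegativities χ and κ = 0.08 e per electronegativity
   unit. Antisymmetry per bond conserves total charge exactly. This is the
   analogue of graph-based charging methods, which produce identical charges
   for every conformer.
2. **Contact perturbation**: every pair beyond the 1-2/1-3 exclusion
   exchanges `α (q0(j) − q0(i)) exp(−r_ij / λ)` with α = 0.05 (dimensionless)
   and λ = 1.5 Å by default. Close contacts between atoms of unlike base
   charge — the intramolecular-interaction geometry that makes real
   conformers yield outlier charges — perturb the most. Transfers are
   antisymmetric, so conservation is exact; the perturbation is linear in α,
   so metrics recover α monotonically on a shared-seed grid.
3. **Hardware jitter**: mean-centred Gaussian noise of scale η per atom
   (default 0), emulating platform-dependent numerics.

At the defaults (α = 0.05, 50 conformers) the generated maximal charge
differences fall around 0.01–0.06 e across the study templates — the same
order as published single-conformer AM1-BCC variability for drug-like
molecules — but no quantitative agreement with any real charge engine is
claimed or tested.

Molecules come from a `chain(n, {position: element})` template grammar
(carbon chains with single heavy substituents, hydrogens completing all
valences). Conformers are built from idealized internal coordinates —
tabulated bond lengths (exact by construction), tetrahedral angles, and
uniformly random torsions on heavy-heavy bonds, placed by the
natural-extension-reference-frame recurrence. Rings, realistic angles, and
energy minimization are deliberately out of scope: only relative non-bonded
contact distances matter downstream. All randomness flows through explicit
integer seeds.

**What passing tests do and do not show.** The synthetic ensembles have, by
construction, exactly the statistical structure the analysis assumes
(contact-driven variability, exact conservation, a single amplitude knob).
Passing tests therefore validate the *analysis machinery* — metrics,
consensus, selection, truncation, I/O — not the behaviour of any real charge
engine on real molecules, where variability additionally reflects geometry
optimization, wavefunction convergence and conformer-generation details.

## Selection procedures

* **Stratification**: sample mean x̄ and standard deviation σ (n−1
  denominator) of the per-molecule metric define closed windows
  good `[x̄−1.8σ, x̄−1.0σ]`, average `[x̄−0.4σ, x̄+0.4σ]`,
  bad `[x̄+1.0σ, x̄+1.8σ]`. Within a window the n values closest to the
  window midpoint are taken (ties to the lower id); a value on two windows
  goes to the more extreme stratum; zero spread raises an explicit error
  rather than silently assigning everything to "average".
* **Ranked picking**: sort by maximal Δq_bond difference descending, restrict
  to a top pool, then greedily accept candidates whose similarity to all
  accepted molecules is below τ (default 0.6). Similarity is a Tanimoto
  coefficient over element-labeled simple paths of 1–4 bonds
  (direction-canonicalized) — a deterministic replacement for a manual
  "avoid similar molecules" judgment.

## Truncation

Only single, acyclic bonds are cuttable; the retained fragment keeps its
atom order and gains one capping hydrogen (never a methyl), appended last.
When a geometry is carried, the hydrogen is placed along the former bond
vector at the tabulated X–H length; by default coordinates are regenerated
from the truncated graph instead, since truncation normally precedes
conformer generation.

## File formats and numerical choices

* SDF V2000 via RDKit; charges in the `PARTIAL_CHARGES` data field at six
  decimals, with the `atom.dprop.PartialCharge` dialect accepted on read.
  Fixed-precision printing can leave a sum residue above the 1e-6 e
  conservation tolerance, so the writer balances the rounded values by one
  unit in the last place over the largest-|q| atoms; round trips are
  therefore exact to 2e-6 e per atom.
* A versioned JSON archive holds molecule + conformers + charge sets
  losslessly (full float precision); readers reject unknown schema versions
  and broken conformer references.
* Charge conservation: `|Σq − total formal charge| ≤ 1e-6 e` for every
  charge set, 1e-9 e for consensus and jitter outputs (mean-centring and
  residue re-centring make these exact to rounding).
* The ELF score caps 1/r at `distance_floor` = 0.5 Å to bound pathological
  geometries.
* Ties everywhere (scores, diversity, ranking, stratification) break to the
  lowest index or lexicographically lowest id, making every procedure a pure
  function of its inputs and seed.

## Problem sizes

The default study configuration in `scripts/acceptance.py` uses 12 chain
templates, 50 conformers per molecule for single-conformer ensembles, 20
batches of 60 conformers per molecule for the consensus-dispersion
comparison, a 500-sample Gaussian for stratification, and 200 random
ensembles up to 50 sets × 60 atoms for the metric/oracle cross-check. These
sizes were chosen as the smallest at which every qualitative effect is
unambiguous and stable across seeds.

## Known limitations

* The synthetic charge model is linear in α and has no geometry
  optimization; it cannot produce the multi-modal outliers real engines show.
* The conformer generator covers acyclic, singly-substituted chains only.
* The ELF scoring function is a documented stand-in for an undocumented
  proprietary criterion; selections will differ from the reference tool.
* No free-energy calculation of any kind is included, and no correlation
  between the variability metrics and downstream observables is asserted.
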