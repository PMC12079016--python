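# chargevar

Conformer-dependent atomic partial-charge variability: metrics, consensus
charging, molecule selection and truncation.

Geometry-dependent charge methods (AM1-BCC and relatives) assign a different
per-atom charge vector to every input conformer of the same molecule, and
platform-dependent numerics add further variation. These differences
propagate directly into force-field electrostatics and hence into computed
observables such as hydration free energies. `chargevar` is a toolkit for
the analysis side of this problem, aimed at force-field and free-energy
practitioners who need to quantify, reduce, or screen for charge
variability before running simulations.

## What it computes

For a molecule with atoms A, bonds B and charge sets q_1 … q_K (one per
conformer, atom-aligned):

* **Maximal partial charge difference** — the largest per-atom range
  `max_{u∈A} [max_k q_k(u) − min_k q_k(u)]`, equivalently the maximum over
  set pairs of `max_u |q_i(u) − q_j(u)|`.
* **Maximal Δq_bond difference** — with bond polarity proxy
  `Δq_bond = q(u) − q(v)` per bond (u,v) ∈ B, the largest per-bond range of
  Δq_bond across the K sets. Always ≤ 2× the atom metric.
* **ELF-style consensus charges** — score conformers by internal
  electrostatic repulsion with all charges made positive, keep the top 2%
  least-interacting, pick 10 diverse ones by greedy max-min Kabsch RMSD, and
  average their charge sets.
* **Selection** — stratify molecules into good/average/bad variability
  windows (`[x̄−1.8σ, x̄−1σ]`, `[x̄−0.4σ, x̄+0.4σ]`, `[x̄+1σ, x̄+1.8σ]`), or
  rank by Δq_bond variability with a path-Tanimoto similarity filter.
* **Truncation** — cut an acyclic single bond, keep one fragment, cap the
  open valence with hydrogen.
* **Matched-pair comparison** — per-conformer maximal charge difference
  between two charging environments (e.g. with and without emulated
  hardware jitter).

A synthetic generator (`chargevar.synthetic_data`) produces molecules,
torsion-sampled conformers, and charge sets with a conformer-independent
electronegativity-based base term, a contact-driven perturbation of
amplitude α, and optional hardware-style jitter η — so every stage can be
exercised and validated without a quantum-chemistry engine. See
`docs/methods.md` for the model and its limits.

## Worked example

```python
import warnings
from chargevar import (
    SynthParams, make_benchmark_ensemble, variability_report, elf_consensus_charges,
)

# hexane-like chain with an O at position 2 and an N at position 5,
# charged once per conformer for 50 torsion-sampled conformers
ens, confs = make_benchmark_ensemble(
    "chain(6, {2: 'O', 5: 'N'})", 50, SynthParams(alpha=0.05, seed=7)
)
r = variability_report(ens)
print(f"molecule: {r.molecule_name}  ({ens.molecule.n_atoms} atoms, {r.n_sets} charge sets)")
print(f"max partial charge difference: {r.max_atom_range:.4f} e (atom {r.argmax_atom})")
print(f"max dq_bond difference:        {r.max_bond_range:.4f} e (bond {r.argmax_bond})")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # 50 conformers is below the recommended 500
    cons = elf_consensus_charges(confs, ens.sets)
print(f"consensus charge sum: {cons.charges.sum():+.2e} e")
```

prints

```
molecule: chain(6, {2: 'O', 5: 'N'})  (23 atoms, 50 charge sets)
max partial charge difference: 0.0237 e (atom 7)
max dq_bond difference:        0.0370 e (bond 19)
consensus charge sum: -6.25e-17 e
```

Across the 50 conformers, some atom's charge spans a 0.0237 e range and some
bond's polarity spans a 0.0370 e range — variability that would feed
directly into a force field's electrostatics. The consensus charge set
conserves total charge to rounding.

The same operations are available from the shell:

```bash
chargevar generate --template "chain(6, {2: 'O', 5: 'N'})" --n-conformers 50 \
    --alpha 0.05 --seed 7 --out ens.sdf
chargevar metrics --in ens.sdf --out metrics.csv
chargevar elf --in ens.sdf --out consensus.sdf
chargevar run --config study.json --out study_out/
```

## Layout

| Module | Contents |
| --- | --- |
| `chargevar.moltypes` | molecular graph, conformer, charge set, ensemble + validation |
| `chargevar.variability_metrics` | atom/bond variability metrics, matched-pair comparison |
| `chargevar.elf_consensus` | repulsion scoring, Kabsch RMSD, diverse selection, consensus |
| `chargevar.synthetic_data` | template molecules, torsion conformers, synthetic charges |
| `chargevar.stratified_selection` | σ-window stratification, path-Tanimoto ranking |
| `chargevar.truncation` | acyclic bond cutting with hydrogen capping |
| `chargevar.io_formats` | SDF with charge fields, ensemble JSON, CSV reports |
| `chargevar.pipeline_driver` | end-to-end study orchestration with manifests |
| `chargevar.cli` | `chargevar` command-line interface |
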