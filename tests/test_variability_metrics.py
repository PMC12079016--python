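"""Variability metrics, checked against brute-force pairwise oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chargevar.moltypes import Atom, Bond, ChargeEnsemble, ChargeSet, MoleculeGraph
from chargevar.variability_metrics import (
    bond_delta_q,
    compare_matched_sets,
    max_bond_delta_range,
    max_charge_range,
    pairwise_max_atom_diff,
    pairwise_max_bond_diff,
    per_atom_range,
    variability_report,
)

from conftest import carbon_path, random_ensemble


def brute_force_max_atom_range(ens: ChargeEnsemble) -> float:
    """Oracle: exhaustive max over all set pairs of the pairwise atom metric."""
    return max(
        pairwise_max_atom_diff(a, b) for a, b in itertools.combinations(ens.sets, 2)
    )


def brute_force_max_bond_range(ens: ChargeEnsemble) -> float:
    """Oracle: exhaustive max over all set pairs of the pairwise bond metric."""
    return max(
        pairwise_max_bond_diff(a, b, ens.molecule)
        for a, b in itertools.combinations(ens.sets, 2)
    )


def _two_atom_sets(q1_vals, q2_vals):
    mol = carbon_path(len(q1_vals))
    return ChargeSet(np.array(q1_vals), mol), ChargeSet(np.array(q2_vals), mol), mol


class TestPairwiseAtomDiff:
    def test_identical_sets_give_zero(self):
        q1, q2, _ = _two_atom_sets([0.3, -0.3], [0.3, -0.3])
        assert pairwise_max_atom_diff(q1, q2) == 0.0

    def test_hand_evaluated_two_atoms(self):
        q1, q2, _ = _two_atom_sets([0.40, -0.40], [0.30, -0.30])
        assert pairwise_max_atom_diff(q1, q2) == pytest.approx(0.10)

    def test_hand_evaluated_three_atoms(self):
        q1, q2, _ = _two_atom_sets([0.2, -0.1, -0.1], [0.2, -0.3, 0.1])
        assert pairwise_max_atom_diff(q1, q2) == pytest.approx(0.20)

    def test_symmetry(self):
        q1, q2, _ = _two_atom_sets([0.2, -0.1, -0.1], [0.2, -0.3, 0.1])
        assert pairwise_max_atom_diff(q1, q2) == pairwise_max_atom_diff(q2, q1)


class TestPerAtomRange:
    def test_identical_sets_all_zero(self):
        mol = carbon_path(4)
        sets = [ChargeSet(np.array([0.1, -0.2, 0.3, -0.2]), mol) for _ in range(5)]
        assert np.all(per_atom_range(ChargeEnsemble(molecule=mol, sets=sets)) == 0)

    def test_range_is_max_minus_min(self):
        mol = carbon_path(2)
        vals = [0.05, 0.10, 0.15]
        sets = [ChargeSet(np.array([v, -v]), mol) for v in vals]
        r = per_atom_range(ChargeEnsemble(molecule=mol, sets=sets))
        assert r[0] == pytest.approx(0.10)

    def test_duplicate_set_invariance(self):
        rng = np.random.default_rng(0)
        ens = random_ensemble(rng, 5, 8)
        dup = ChargeEnsemble(molecule=ens.molecule, sets=ens.sets + [ens.sets[0]])
        assert np.array_equal(per_atom_range(ens), per_atom_range(dup))


class TestBondDeltaQ:
    def test_uniform_charges_give_zeros(self):
        mol = carbon_path(5)
        d = bond_delta_q(ChargeSet(np.zeros(5), mol), mol)
        assert np.all(d.deltas == 0)

    def test_single_bond_hand_case(self):
        # bond (0,1) with q(0)=0.3, q(1)=-0.1 -> dq_bond = +0.4
        mol = carbon_path(3)
        d = bond_delta_q(ChargeSet(np.array([0.3, -0.1, -0.2]), mol), mol)
        assert d.deltas[0] == pytest.approx(0.4)

    def test_path_graph_telescopes(self):
        mol = carbon_path(6)
        rng = np.random.default_rng(1)
        q = rng.normal(0, 0.2, 6)
        q -= q.mean()
        d = bond_delta_q(ChargeSet(q, mol), mol)
        assert d.deltas.sum() == pytest.approx(q[0] - q[-1])


class TestPairwiseBondDiff:
    def test_identical_sets_give_zero(self):
        q1, q2, mol = _two_atom_sets([0.3, -0.3], [0.3, -0.3])
        assert pairwise_max_bond_diff(q1, q2, mol) == 0.0

    def test_hand_case_saturates_two_times_atom_bound(self):
        # one bond, anti-correlated endpoint shifts: dq1=0.60, dq2=0.20,
        # |dq1-dq2| = 0.40 = 2 * max atom diff (bound saturation)
        mol = MoleculeGraph(atoms=[Atom("C"), Atom("C")], bonds=[Bond(0, 1)], name="pair")
        qa = ChargeSet(np.array([0.30, -0.30]), mol)
        qb = ChargeSet(np.array([0.10, -0.10]), mol)
        assert pairwise_max_bond_diff(qa, qb, mol) == pytest.approx(0.40)
        assert pairwise_max_bond_diff(qa, qb, mol) == pytest.approx(
            2 * pairwise_max_atom_diff(qa, qb)
        )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_brute_force_over_bonds(self, seed):
        rng = np.random.default_rng(seed)
        ens = random_ensemble(rng, 2, 10)
        q1, q2 = ens.sets
        expected = max(
            abs((q1.charges[b.u] - q1.charges[b.v]) - (q2.charges[b.u] - q2.charges[b.v]))
            for b in ens.molecule.bonds
        )
        assert pairwise_max_bond_diff(q1, q2, ens.molecule) == pytest.approx(expected)


class TestEnsembleMaxima:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_equivalence_with_pairwise_oracles(self, seed):
        rng = np.random.default_rng(seed)
        ens = random_ensemble(rng, rng.integers(2, 11), rng.integers(2, 21))
        assert max_charge_range(ens) == pytest.approx(brute_force_max_atom_range(ens), abs=1e-12)
        assert max_bond_delta_range(ens) == pytest.approx(brute_force_max_bond_range(ens), abs=1e-12)

    def test_two_set_ensemble_degenerates_to_pairwise(self):
        rng = np.random.default_rng(5)
        ens = random_ensemble(rng, 2, 12)
        assert max_bond_delta_range(ens) == pytest.approx(
            pairwise_max_bond_diff(ens.sets[0], ens.sets[1], ens.molecule)
        )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_triangle_bound_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ens = random_ensemble(rng, 6, 10)
        assert max_bond_delta_range(ens) <= 2 * max_charge_range(ens) + 1e-12
        perm = list(rng.permutation(len(ens.sets)))
        shuffled = ChargeEnsemble(molecule=ens.molecule, sets=[ens.sets[i] for i in perm])
        assert max_charge_range(shuffled) == max_charge_range(ens)
        assert max_bond_delta_range(shuffled) == max_bond_delta_range(ens)

    def test_metrics_non_decreasing_under_added_set(self):
        rng = np.random.default_rng(9)
        ens = random_ensemble(rng, 5, 10)
        extra = ChargeSet(
            np.r_[0.5, np.full(9, -0.5 / 9)], ens.molecule
        )
        grown = ChargeEnsemble(molecule=ens.molecule, sets=ens.sets + [extra])
        assert max_charge_range(grown) >= max_charge_range(ens)
        assert max_bond_delta_range(grown) >= max_bond_delta_range(ens)


class TestVariabilityReport:
    def test_fields_agree_with_individual_metrics(self):
        rng = np.random.default_rng(3)
        ens = random_ensemble(rng, 8, 15)
        r = variability_report(ens)
        assert r.max_atom_range == pytest.approx(max_charge_range(ens))
        assert r.max_bond_range == pytest.approx(max_bond_delta_range(ens))
        assert r.max_atom_range == pytest.approx(r.per_atom_range.max())
        assert r.per_atom_range[r.argmax_atom] == r.max_atom_range
        assert r.per_bond_range[r.argmax_bond] == r.max_bond_range
        assert r.n_sets == 8
        assert np.all(r.per_atom_range >= 0) and np.all(r.per_bond_range >= 0)

    def test_duplicate_sets_report_zeros(self):
        mol = carbon_path(4)
        base = np.array([0.1, -0.2, 0.3, -0.2])
        ens = ChargeEnsemble(molecule=mol, sets=[ChargeSet(base.copy(), mol) for _ in range(3)])
        r = variability_report(ens)
        assert r.max_atom_range == 0 and r.max_bond_range == 0 and r.n_sets == 3


class TestCompareMatchedSets:
    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(4)
        ens = random_ensemble(rng, 5, 8)
        per_pair, overall = compare_matched_sets(ens, ens)
        assert np.all(per_pair == 0) and overall == 0

    def test_conformer_id_mismatch_raises(self):
        from chargevar.moltypes import Provenance

        mol = carbon_path(3)
        a = ChargeSet(np.array([0.1, -0.2, 0.1]), mol, Provenance(conformer_id="c0"))
        b = ChargeSet(np.array([0.1, -0.2, 0.1]), mol, Provenance(conformer_id="c1"))
        ensA = ChargeEnsemble(molecule=mol, sets=[a, a])
        ensB = ChargeEnsemble(molecule=mol, sets=[b, b])
        with pytest.raises(ValueError, match="conformer ids"):
            compare_matched_sets(ensA, ensB)
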