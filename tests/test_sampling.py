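"""Budget allocation, constraints, conformer generation, flips, pruning,
and rigid-body perturbation."""

import numpy as np
import pytest

from mcligand._geometry import coordinate_rmsd
from mcligand.errors import SamplingError
from mcligand.ligand import TopologyFeatures, assign_bond_orders, detect_topology
from mcligand.sampling import (ConformerSet, ConstraintSet, allocate_budget,
                               build_constraints, flip_sampling,
                               generate_conformers, pairwise_rmsd_matrix,
                               perturb, prune_redundant, verify_constraints)

from conftest import TOY_SMILES, make_ligand


def features(n_heavy, side=(), long_=(), terminals=(0, 1)):
    return TopologyFeatures(
        terminal_atoms=frozenset(terminals),
        side_chains=tuple(frozenset(s) for s in side),
        long_chains=tuple(frozenset(s) for s in long_),
        core_atoms=frozenset(), is_macrocycle=False, n_heavy=n_heavy)


class TestBudget:
    @pytest.mark.parametrize("n_heavy,total", [(24, 5000), (25, 7000),
                                               (10, 5000), (40, 7000)])
    def test_default_totals_at_size_boundary(self, n_heavy, total):
        plan = allocate_budget(features(n_heavy))
        assert plan.total_budget == total

    def test_three_strategy_split_with_round_robin_remainder(self):
        plan = allocate_budget(features(24))
        counts = [c for _, c, _ in plan.strategies]
        assert counts == [1667, 1667, 1666]
        assert sum(counts) == 5000

    def test_branching_strategy_requires_side_chains(self):
        names = [n for n, _, _ in allocate_budget(features(24)).strategies]
        assert names == ["unconstrained", "fixed_terminal", "blob"]
        names = [n for n, _, _ in
                 allocate_budget(features(24, side=[(4, 5, 6, 7)])).strategies]
        assert "branching" in names

    def test_user_count_overrides(self):
        assert allocate_budget(features(30), user_count=100).total_budget == 100
        with pytest.raises(ValueError):
            allocate_budget(features(30), user_count=0)


class TestConstraints:
    def test_blob_sphere_of_linear_three_atom_ligand(self):
        lig = make_ligand("CCO", seed=1)
        lig.coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        feats = features(3)
        cs = build_constraints("blob", lig, feats)
        center, radius = cs.bounding_sphere
        np.testing.assert_allclose(center, [1.0, 0, 0], atol=1e-12)
        assert radius == pytest.approx(1.0)

    def test_fixed_terminal_pins_every_terminal_pair(self):
        lig = make_ligand("CCO", seed=1)
        lig.coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        cs = build_constraints("fixed_terminal", lig, features(3, terminals=(0, 2)))
        assert cs.pair_distance_pins == ((0, 2, 2.0),)

    def test_branching_fixes_the_core(self, toy_ligand, toy_bonded):
        feats = detect_topology(toy_bonded)
        cs = build_constraints("branching", toy_ligand, feats)
        side = set().union(*feats.side_chains)
        assert cs.fixed_atoms == frozenset(set(range(12)) - side)

    def test_inapplicable_strategy_rejected(self, toy_ligand):
        with pytest.raises(SamplingError):
            build_constraints("long_chain", toy_ligand, features(12))


class TestGeneration:
    def test_two_atom_ligand_keeps_bond_length(self):
        lig = make_ligand("CC", seed=4)
        bonded = assign_bond_orders(lig, "CC")
        out = generate_conformers(bonded, ConstraintSet(), 10, seed=7)
        assert len(out) == 10
        lengths = np.linalg.norm(out.coords[:, 0] - out.coords[:, 1], axis=1)
        assert np.all(np.abs(lengths - 1.54) < 0.15 * 1.54 + 0.05)

    def test_fully_pinned_reproduces_input(self, toy_bonded):
        cs = ConstraintSet(fixed_atoms=frozenset(range(12)))
        out = generate_conformers(toy_bonded, cs, 5, seed=1)
        for k in range(len(out)):
            dev = np.linalg.norm(out.coords[k] - toy_bonded.ligand.coords, axis=1)
            assert dev.max() <= 0.01

    def test_chain_torsions_cluster_at_staggered_modes(self):
        lig = make_ligand("CCCC", seed=9)
        bonded = assign_bond_orders(lig, "CCCC")
        out = generate_conformers(bonded, ConstraintSet(), 300, seed=3)
        torsions = []
        for k in range(len(out)):
            p = out.coords[k]
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            x = np.dot(n1, n2)
            y = np.dot(np.cross(n1, b2 / np.linalg.norm(b2)), n2)
            torsions.append(np.degrees(np.arctan2(y, x)))
        torsions = np.abs(np.asarray(torsions))
        near_mode = (np.abs(torsions - 60) < 30) | (np.abs(torsions - 180) < 30)
        assert near_mode.mean() > 0.8

    def test_deterministic_for_fixed_seed_and_worker_independent(self, toy_bonded):
        a = generate_conformers(toy_bonded, ConstraintSet(), 60, seed=5)
        b = generate_conformers(toy_bonded, ConstraintSet(), 60, seed=5)
        c = generate_conformers(toy_bonded, ConstraintSet(), 60, seed=5, workers=3)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.coords, c.coords)

    def test_emitted_conformers_pass_independent_verifier(self, toy_ligand, toy_bonded):
        feats = detect_topology(toy_bonded)
        for strategy in ("unconstrained", "fixed_terminal", "blob", "branching"):
            cs = build_constraints(strategy, toy_ligand, feats)
            out = generate_conformers(toy_bonded, cs, 25, seed=11, source=strategy)
            assert verify_constraints(out.coords, toy_bonded, cs).all(), strategy


class TestFlip:
    def test_first_three_members_are_axis_flips_preserving_internal_geometry(
            self, toy_bonded):
        out = flip_sampling(toy_bonded)
        base = toy_bonded.ligand.coords
        dm = lambda x: np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        for k in range(3):
            np.testing.assert_allclose(dm(out.coords[k]), dm(base), atol=1e-8)
        assert len(out) == 3 + 3 * 10

    def test_x_flip_negates_y_and_z_about_centroid(self):
        # asymmetric zig-zag with realistic ~1.5 Å bonds
        coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                           [2.3, 1.2, 0.4], [3.5, 1.5, -0.45]])
        lig = make_ligand("CCCC", seed=2)
        lig.coords = coords
        bonded = assign_bond_orders(lig, "CCCC")
        out = flip_sampling(bonded)
        center = coords.mean(axis=0)
        expected = coords.copy()
        expected[:, 1:] = 2 * center[1:] - coords[:, 1:]
        np.testing.assert_allclose(out.coords[0], expected, atol=1e-10)


class TestPrune:
    def _set(self, members):
        lig = make_ligand("CCCC", seed=2)
        bonded = assign_bond_orders(lig, "CCCC")
        return ConformerSet(topology=bonded, coords=np.asarray(members),
                            sources=["s"] * len(members))

    def test_identical_pair_collapses_to_one(self):
        base = make_ligand("CCCC", seed=2).coords
        out = prune_redundant(self._set([base, base.copy()]), seed=0)
        assert len(out) == 1

    def test_pair_beyond_threshold_survives(self):
        base = make_ligand("CCCC", seed=2).coords
        out = prune_redundant(self._set([base, base + [0.3, 0, 0]]), seed=0)
        assert len(out) == 2

    def test_three_clusters_leave_three_survivors(self):
        rng = np.random.default_rng(4)
        base = make_ligand("CCCC", seed=2).coords
        members = []
        for shift in ([0, 0, 0], [5, 0, 0], [0, 5, 0]):
            center = base + np.asarray(shift, dtype=float)
            for _ in range(3):
                members.append(center + rng.normal(0, 0.01, base.shape))
        members.append(base + np.array([0, 0, 5.0]))   # a singleton cluster
        out = prune_redundant(self._set(members), seed=9)
        assert len(out) == 4
        rmat = pairwise_rmsd_matrix(out.coords)
        iu = np.triu_indices(len(out), 1)
        assert rmat[iu].min() >= 0.2

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        base = make_ligand("CCCC", seed=2).coords
        members = [base + rng.normal(0, 0.2, base.shape) for _ in range(12)]
        once = prune_redundant(self._set(members), seed=1)
        twice = prune_redundant(once, seed=2)
        assert len(once) == len(twice)
        np.testing.assert_array_equal(once.coords, twice.coords)


class TestPerturb:
    def _single(self):
        lig = make_ligand("CCCC", seed=2)
        bonded = assign_bond_orders(lig, "CCCC")
        return ConformerSet(topology=bonded, coords=lig.coords[None],
                            sources=["s"])

    def test_one_member_becomes_twenty_five(self):
        out = perturb(self._single())
        assert len(out) == 1 + 18 + 6

    def test_translation_members_sit_at_exactly_0p3_angstrom(self):
        src = self._single()
        out = perturb(src)
        trans = out.coords[19:]
        for k in range(6):
            assert coordinate_rmsd(trans[k], src.coords[0]) == pytest.approx(0.3)

    def test_rotation_members_keep_centroid_and_internal_geometry(self):
        src = self._single()
        out = perturb(src)
        base_centroid = src.coords[0].mean(axis=0)
        dm = lambda x: np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        for k in range(1, 19):
            np.testing.assert_allclose(out.coords[k].mean(axis=0),
                                       base_centroid, atol=1e-9)
            np.testing.assert_allclose(dm(out.coords[k]), dm(src.coords[0]),
                                       atol=1e-9)
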