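"""Network-builder tests: chain composition, packing, template
cross-linking, relaxation and protonation handling."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelmesh import topology as topo
from gelmesh.geometry import min_image_distance
from gelmesh.system import merge_systems
from gelmesh.topology import (ACIDIC, BASIC, InvalidCompositionError,
                              PackingInfeasibleError, TemplateMissingError,
                              build_bis, build_chain, conversion,
                              find_reactive_pairs, henderson_hasselbalch_fraction,
                              match_reaction_template, pack_system,
                              prune_unreacted_bis, relax, run_crosslinking)
from conftest import make_pair_system

# united-atom formula masses used for the hand-computed packing oracle
M_NIPAM = 113.16
M_AAC_PROTONATED = 72.063
M_BIS = 154.169


class TestHendersonHasselbalch:
    @pytest.mark.parametrize("ph, pka, expected, places", [
        (2.75, 4.75, 0.99, 2),   # acidic medium: carboxyls essentially protonated
        (7.4, 4.75, 99.8, 1),    # weakly basic medium: essentially deprotonated
        (4.75, 4.75, 50.0, 10),  # symmetry point
    ])
    def test_deprotonated_percent(self, ph, pka, expected, places):
        assert round(henderson_hasselbalch_fraction(ph, pka), places) == expected

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0, 14), st.floats(0, 14))
    def test_bounded_and_monotone_in_ph(self, ph, pka):
        f = henderson_hasselbalch_fraction(ph, pka)
        assert 0.0 <= f <= 100.0
        assert henderson_hasselbalch_fraction(ph + 0.5, pka) >= f


class TestBuildChain:
    @pytest.mark.parametrize("aac_count, expected_pct", [(0, 0), (1, 5), (3, 15), (4, 20)])
    def test_census_matches_composition(self, aac_count, expected_pct):
        chain = build_chain(20, aac_count, ACIDIC, seed=3)
        labels = Counter(str(chain.residue_labels[chain.resids == m][0]) for m in range(20))
        assert labels["AAC"] == aac_count
        assert labels["NIPAM"] == 20 - aac_count
        assert aac_count / 20 * 100 == expected_pct

    def test_pure_nipam_has_no_aac(self):
        chain = build_chain(20, 0, ACIDIC, seed=0)
        assert not np.any(chain.residue_labels == "AAC")

    def test_every_monomer_contributes_one_reactive_site(self):
        chain = build_chain(12, 2, ACIDIC, seed=1)
        assert int(chain.reactive_site.sum()) == 12
        assert np.all(chain.names[chain.reactive_site] == "CB")

    def test_invalid_composition_raises(self):
        with pytest.raises(InvalidCompositionError):
            build_chain(20, 21, ACIDIC, seed=0)

    def test_protonation_flags_follow_model(self):
        acidic = build_chain(10, 3, ACIDIC, seed=5)
        basic = build_chain(10, 3, BASIC, seed=5)
        oh_a = acidic.protonated[acidic.names == "OH"]
        oh_b = basic.protonated[basic.names == "OH"]
        assert oh_a.all() and not oh_b.any()
        # geometry/topology identical: only flags (and the O-H mass) differ
        assert np.array_equal(acidic.bonds, basic.bonds)
        assert np.allclose(acidic.positions, basic.positions)


class TestPackSystem:
    def test_box_edge_matches_mass_density_closed_form(self):
        chains = [build_chain(20, 0, ACIDIC, seed=s) for s in range(4)]
        packed = pack_system(chains, 50, density=0.8, tolerance=1.0, seed=2)
        total_mass = 4 * 20 * M_NIPAM + 50 * M_BIS
        edge = (total_mass / 0.8 * 1e24 / 6.02214076e23) ** (1 / 3)
        assert packed.box == pytest.approx([edge] * 3, rel=1e-4)

    def test_tolerance_respected_between_molecules(self, small_packed):
        s = small_packed
        for i in range(s.n_atoms):
            for j in range(i + 1, s.n_atoms):
                if s.mol_ids[i] != s.mol_ids[j]:
                    assert min_image_distance(s.positions[i], s.positions[j], s.box) >= 2.0 - 1e-9

    def test_single_atom_molecule_packs(self):
        from gelmesh.system import MolecularSystem

        atom = MolecularSystem.from_lists(
            [{"element": "C", "position": (0, 0, 0), "mass": 12.011}], [], (10, 10, 10))
        packed = pack_system([atom], 0, density=0.1, tolerance=0.0, seed=0)
        assert packed.n_atoms == 1

    def test_infeasible_packing_raises(self):
        chains = [build_chain(10, 0, ACIDIC, seed=s) for s in range(4)]
        with pytest.raises(PackingInfeasibleError):
            pack_system(chains, 20, density=0.8, tolerance=25.0, seed=0,
                        max_attempts=500)


class TestFindReactivePairs:
    def test_pair_inside_cutoff_found(self, pair_within_cutoff):
        pairs = find_reactive_pairs(pair_within_cutoff, 3.5)
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(3.4)

    def test_pair_beyond_cutoff_empty(self, pair_beyond_cutoff):
        assert find_reactive_pairs(pair_beyond_cutoff, 3.5) == []

    def test_intramolecular_pair_excluded(self):
        same_mol = make_pair_system(3.4, same_molecule=True)
        assert find_reactive_pairs(same_mol, 3.5) == []

    def test_sorted_by_ascending_distance(self, small_packed):
        pairs = find_reactive_pairs(small_packed, 8.0)
        dists = [p[2] for p in pairs]
        assert dists == sorted(dists)


class TestTemplateMatching:
    def test_conformant_pair_matches(self, pair_within_cutoff):
        (i, j, _), = find_reactive_pairs(pair_within_cutoff, 3.5)
        assert match_reaction_template(pair_within_cutoff, (i, j))

    def test_changed_connectivity_rejected(self, pair_within_cutoff):
        s = pair_within_cutoff.copy()
        (i, j, _), = find_reactive_pairs(s, 3.5)
        # graft an extra carbon onto one endpoint: neighborhood no longer
        # matches the pre-reaction template
        from gelmesh.system import normalize_bonds

        extra = s.n_atoms
        s = merge_systems([s, _lone_carbon()], s.box)
        s.bonds = normalize_bonds(np.vstack([s.bonds, [[i, extra]]]))
        assert not match_reaction_template(s, (i, j))

    def test_bis_bis_pair_forbidden(self):
        bis = [build_bis(seed=k) for k in range(2)]
        b0, b1 = bis[0].copy(), bis[1].copy()
        b1.positions = b1.positions + 3.0
        merged = merge_systems([b0, b1], (40, 40, 40))
        pairs = find_reactive_pairs(merged, 10.0)
        assert pairs  # sites are in range ...
        assert not any(match_reaction_template(merged, p[:2]) for p in pairs)

    def test_unknown_residue_raises_template_missing(self):
        from gelmesh.system import MolecularSystem

        weird = MolecularSystem.from_lists(
            [{"element": "C", "position": (0, 0, 0), "residue_label": "IBU",
              "reactive_site": True, "mol_id": 0},
             {"element": "C", "position": (2, 0, 0), "residue_label": "IBU",
              "reactive_site": True, "mol_id": 1}], [], (20, 20, 20))
        with pytest.raises(TemplateMissingError):
            match_reaction_template(weird, (0, 1))


def _lone_carbon():
    from gelmesh.system import MolecularSystem

    return MolecularSystem.from_lists(
        [{"element": "C", "position": (12.0, 10.0, 10.0), "mol_id": 0}], [], (30, 30, 30))


class TestCrosslinking:
    def test_two_site_fixture_forms_one_bond(self, pair_within_cutoff):
        linked, report = run_crosslinking(pair_within_cutoff, relax_steps=0)
        new = len(linked.bonds) - len(pair_within_cutoff.bonds)
        assert new == 1
        assert report.cycles[0][2] == 1
        # both sites of the only candidate pair reacted: conversion 2/2
        assert report.final_conversion == pytest.approx(
            linked.reacted.sum() / linked.reactive_site.sum())

    def test_conversion_monotone_and_bounded(self, small_packed):
        _, report = run_crosslinking(small_packed, relax_steps=10, seed=4)
        convs = [c[3] for c in report.cycles]
        assert all(b >= a for a, b in zip(convs, convs[1:]))
        assert 0.0 <= report.final_conversion <= 1.0
        assert len(report.cycles) <= 12

    def test_deterministic_under_fixed_seed(self, small_packed):
        a, ra = run_crosslinking(small_packed, relax_steps=5, seed=9)
        b, rb = run_crosslinking(small_packed, relax_steps=5, seed=9)
        assert np.array_equal(a.bonds, b.bonds)
        assert ra.cycles == rb.cycles

    def test_no_reactive_proximity_means_zero_conversion(self):
        s = make_pair_system(20.0, box=60.0)
        _, report = run_crosslinking(s, relax_steps=0)
        assert report.final_conversion == 0.0
        assert report.ladder_exhausted

    def test_bonds_only_between_template_matched_distance_pairs(self, small_packed):
        before = {tuple(b) for b in small_packed.bonds.tolist()}
        linked, report = run_crosslinking(small_packed, relax_steps=0, seed=1)
        formed = [b for b in linked.bonds.tolist() if tuple(b) not in before]
        max_cutoff = max(c[0] for c in report.cycles)
        for i, j in formed:
            assert small_packed.mol_ids[i] != small_packed.mol_ids[j]
            assert linked.reacted[i] and linked.reacted[j]
            # with relax_steps=0 the geometry is frozen: every formed bond
            # must respect the distance criterion of some cycle
            d = min_image_distance(small_packed.positions[i],
                                   small_packed.positions[j], small_packed.box)
            assert d <= max_cutoff + 1e-9

    def test_descending_ladder_rejected(self, pair_within_cutoff):
        with pytest.raises(ValueError):
            run_crosslinking(pair_within_cutoff, cutoffs=(5.0, 3.5))


class TestRelax:
    def test_zero_steps_is_identity(self, pair_within_cutoff):
        out = relax(pair_within_cutoff, 0)
        assert np.array_equal(out.positions, pair_within_cutoff.positions)

    def test_stretched_bond_contracts(self):
        from gelmesh.system import MolecularSystem

        s = MolecularSystem.from_lists(
            [{"element": "C", "position": (10, 10, 10)},
             {"element": "C", "position": (13.06, 10, 10)}],  # 2x the 1.53 rest length
            [(0, 1)], (30, 30, 30))
        out = relax(s, 50)
        d0 = 3.06
        d1 = np.linalg.norm(out.positions[1] - out.positions[0])
        assert d1 < d0
        assert d1 >= 1.53 - 1e-6

    def test_overlapping_nonbonded_pair_separates(self):
        from gelmesh.system import MolecularSystem

        s = MolecularSystem.from_lists(
            [{"element": "C", "position": (10, 10, 10)},
             {"element": "C", "position": (10.5, 10, 10)}], [], (30, 30, 30))
        out = relax(s, 50)
        assert np.linalg.norm(out.positions[1] - out.positions[0]) > 0.5

    def test_topology_unchanged(self, small_packed):
        out = relax(small_packed, 15)
        assert np.array_equal(out.bonds, small_packed.bonds)


class TestPruning:
    def test_counting_oracle(self, small_packed):
        linked, _ = run_crosslinking(small_packed, relax_steps=0, seed=2)
        bis_mols = [m for m in np.unique(linked.mol_ids)
                    if np.all(linked.residue_labels[linked.mol_ids == m] == "BIS")]
        reacted_bis = [m for m in bis_mols
                       if np.any(linked.reacted[linked.mol_ids == m])]
        pruned = prune_unreacted_bis(linked)
        removed_atoms = linked.n_atoms - pruned.n_atoms
        assert removed_atoms == (len(bis_mols) - len(reacted_bis)) * 11

    def test_composition_conserved_apart_from_pruned_bis(self, small_packed):
        linked, _ = run_crosslinking(small_packed, relax_steps=0, seed=2)
        pruned = prune_unreacted_bis(linked)
        before = Counter(linked.residue_labels.tolist())
        after = Counter(pruned.residue_labels.tolist())
        assert after["NIPAM"] == before["NIPAM"]
        assert after["AAC"] == before["AAC"]
        assert after["BIS"] <= before["BIS"]

    def test_no_bis_is_identity(self):
        chain = build_chain(5, 1, ACIDIC, seed=0)
        pruned = prune_unreacted_bis(chain)
        assert pruned.n_atoms == chain.n_atoms

    def test_all_reacted_bis_kept(self, bis_molecule):
        b = bis_molecule.copy()
        b.reacted[b.names == "C2"] = True
        assert prune_unreacted_bis(b).n_atoms == b.n_atoms
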