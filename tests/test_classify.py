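import itertools

import numpy as np
import pytest

from triplescan import fixtures as fx
from triplescan.classify import (PairGeometry, TripleCodeRegistry,
                                 classify_triple, cis_or_trans, dominant_edge,
                                 family_string)
from triplescan.geometry import random_rotation
from triplescan.hbond import find_base_hbonds, triple_hbond_filter


class TestDominantEdge:
    def test_guanine_n1_n2_toward_cytosine_is_wc(self, gc_pair):
        bonds = find_base_hbonds(gc_pair[0], gc_pair[1])
        assert dominant_edge(gc_pair[0], gc_pair[1], bonds) == "WC"
        assert dominant_edge(gc_pair[1], gc_pair[0], bonds) == "WC"

    def test_adenine_n7_n6_is_hoogsteen(self, uau_model):
        # the second uridine binds the adenine N7/N6 face
        a, u = uau_model[0], uau_model[2]
        bonds = find_base_hbonds(a, u)
        assert dominant_edge(a, u, bonds) == "H"
        assert dominant_edge(u, a, bonds) == "WC"

    def test_sugar_edge_by_geometric_side(self, gcg_model):
        # second G binds the first G's N3/N2 sugar face
        g1, g3 = gcg_model[0], gcg_model[2]
        bonds = find_base_hbonds(g1, g3)
        assert dominant_edge(g1, g3, bonds) == "S"

    def test_no_bonds_is_an_error(self, gc_pair):
        with pytest.raises(ValueError):
            dominant_edge(gc_pair[0], gc_pair[1], [])


class TestCisTrans:
    def test_canonical_wc_pair_is_cis(self, gc_pair):
        assert cis_or_trans(gc_pair[0], gc_pair[1]) == "Cis"

    def test_reverse_wc_pair_is_trans(self):
        from triplescan.fixtures import PairingDirective, PlacementSpec

        model = fx.compose_triple(PlacementSpec(
            ["A", "U"], {1: PairingDirective(0, "WC", "WC", "trans")}))
        assert cis_or_trans(model[0], model[1]) == "Trans"

    def test_symmetric_and_pose_invariant(self, gc_pair, rng):
        assert cis_or_trans(gc_pair[1], gc_pair[0]) == "Cis"
        moved = fx.transform(gc_pair, random_rotation(rng),
                             rng.uniform(-30, 30, 3))
        assert cis_or_trans(moved[0], moved[1]) == "Cis"

    def test_works_without_c1_prime(self, gc_pair):
        from triplescan.structure_io import Nucleotide

        stripped = [
            Nucleotide(n.res_id, n.base_type,
                       {k: v for k, v in n.atoms.items() if k != "C1'"})
            for n in gc_pair
        ]
        assert cis_or_trans(stripped[0], stripped[1]) == "Cis"


class TestFamilyString:
    def _pg(self, orientation, e1, e2):
        return PairGeometry(("A", 1, ""), ("A", 2, ""), e1, e2, orientation)

    def test_cis_before_trans(self):
        pairs = [self._pg("Trans", "H", "WC"), self._pg("Cis", "WC", "WC")]
        assert family_string(pairs) == "Cis WC / WC – Trans H / WC"

    def test_edges_alphabetical_within_pair(self):
        assert self._pg("Cis", "WC", "S").label() == "Cis S / WC"
        assert self._pg("Cis", "S", "H").label() == "Cis H / S"

    def test_common_agc_family(self):
        pairs = [self._pg("Cis", "WC", "WC"), self._pg("Cis", "S", "WC")]
        assert family_string(pairs) == "Cis S / WC – Cis WC / WC"

    def test_single_pair_degenerate(self):
        assert family_string([self._pg("Trans", "WC", "H")]) == "Trans H / WC"


class TestClassifyTriple:
    def test_uau_family_and_wc_flag(self, uau_model):
        _, _, bonds = triple_hbond_filter(uau_model)
        record = classify_triple(uau_model, bonds)
        assert record.family == "Cis H / WC – Cis WC / WC"
        assert record.contains_wc_pair
        assert record.composition == "AUU"

    def test_family_invariant_under_residue_order(self, uau_model):
        _, _, bonds = triple_hbond_filter(uau_model)
        reference = classify_triple(uau_model, bonds)
        for perm in itertools.permutations(uau_model):
            record = classify_triple(list(perm), bonds)
            assert record.family == reference.family
            assert record.contains_wc_pair == reference.contains_wc_pair

    def test_wc_flag_requires_cis_wc_wc(self, acc_model):
        _, _, bonds = triple_hbond_filter(acc_model, protonation_search=True)
        record = classify_triple(acc_model, bonds)
        # both A·C pairs are trans here: no (cis) Watson-Crick pair
        assert not record.contains_wc_pair


class TestCodeRegistry:
    def test_first_topology_gets_suffix_one(self, gcg_model):
        registry = TripleCodeRegistry()
        _, _, bonds = triple_hbond_filter(gcg_model)
        record = classify_triple(gcg_model, bonds, registry)
        assert record.code == "CGG1"

    def test_distinct_topologies_increment(self, uau_model):
        registry = TripleCodeRegistry()
        _, _, bonds = triple_hbond_filter(uau_model)
        first = classify_triple(uau_model, bonds, registry)
        assert first.code == "AUU1"
        # drop one bond: a different topology of the same composition
        second = classify_triple(uau_model, bonds[:-1], registry)
        assert second.code == "AUU2"

    def test_identical_topology_reuses_code(self, uau_model, rng):
        registry = TripleCodeRegistry()
        _, _, bonds = triple_hbond_filter(uau_model)
        first = classify_triple(uau_model, bonds, registry)
        moved = fx.transform(uau_model, random_rotation(rng),
                             rng.uniform(-30, 30, 3))
        renumbered = [
            type(n)(res_id=("B", 100 + i, ""), base_type=n.base_type,
                    atoms=n.atoms)
            for i, n in enumerate(moved)
        ]
        _, _, bonds2 = triple_hbond_filter(renumbered)
        again = classify_triple(renumbered, bonds2, registry)
        assert again.code == first.code

    def test_registry_persists_across_runs(self, uau_model, gcg_model):
        registry = TripleCodeRegistry()
        _, _, b1 = triple_hbond_filter(uau_model)
        _, _, b2 = triple_hbond_filter(gcg_model)
        code_uau = classify_triple(uau_model, b1, registry).code
        code_gcg = classify_triple(gcg_model, b2, registry).code
        reloaded = TripleCodeRegistry.from_json(registry.to_json())
        assert classify_triple(uau_model, b1, reloaded).code == code_uau
        assert classify_triple(gcg_model, b2, reloaded).code == code_gcg
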