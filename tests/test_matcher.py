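import numpy as np
import pytest
from brute_oracle import brute_force_hits

from triplescan import fixtures as fx
from triplescan.geometry import random_rotation
from triplescan.matcher import (MatchHit, StructureGraph, canonicalize_hits,
                                edge_compatible, search_structure,
                                ullmann_search)
from triplescan.patterns import ToleranceSpec, pattern_from_occurrence

TOL_01 = ToleranceSpec("absolute", 0.1)
TOL_17 = ToleranceSpec("absolute", 1.7)
TOL_60 = ToleranceSpec("percent", 60)


class TestEdgeCompatible:
    @pytest.mark.parametrize("d_pattern,d_structure,tol,expected", [
        (100, 10.0, TOL_17, True),    # 10 Å vs 10 Å within 1.7 Å
        (100, 11.7, TOL_17, True),    # boundary inclusive
        (100, 11.8, TOL_17, False),
        (100, 16.0, TOL_60, True),    # fuzzy regime: 60% of 10 Å
        (100, 16.1, TOL_60, False),
        (100, 12.0, ToleranceSpec("absolute", 0.0), False),
        (0, 0.0, ToleranceSpec("absolute", 0.0), True),
    ])
    def test_examples(self, d_pattern, d_structure, tol, expected):
        assert edge_compatible(d_pattern, d_structure, tol) is expected

    def test_percent_applies_to_pattern_distance(self):
        # 50% of the 4 Å pattern distance is 2 Å, irrespective of the
        # (larger) structure distance
        tol = ToleranceSpec("percent", 50)
        assert edge_compatible(40, 6.0, tol)
        assert not edge_compatible(40, 6.1, tol)


class TestUllmannSearch:
    def test_self_recovery(self, uau_model):
        pattern = pattern_from_occurrence(uau_model, "uau")
        hits = search_structure(pattern, uau_model, TOL_01)
        assert len(hits) == 1
        assert hits[0].residues == tuple(sorted(n.res_id for n in uau_model))
        # encoding rounds to 0.05 Å, so deviations stay within 0.1 Å
        assert hits[0].max_abs_deviation <= 0.1

    def test_finds_all_planted_copies(self, uau_model):
        pattern = pattern_from_occurrence(uau_model, "uau")
        field = fx.make_field([fx.uau_triple()] * 3, 27, seed=7)
        hits = search_structure(pattern, field, TOL_01)
        assert len(hits) == 3

    def test_empty_structure(self, uau_model):
        pattern = pattern_from_occurrence(uau_model, "uau")
        graph = StructureGraph.from_nucleotides([])
        assert ullmann_search(pattern, graph, TOL_17) == []

    def test_convention_mismatch_rejected(self, uau_model):
        pattern = pattern_from_occurrence(uau_model, "uau")
        pattern.convention = "other-recipe-v9"
        graph = StructureGraph.from_nucleotides(uau_model)
        with pytest.raises(ValueError, match="convention"):
            ullmann_search(pattern, graph, TOL_17)

    def test_rigid_motion_invariance(self, uau_model, rng):
        pattern = pattern_from_occurrence(uau_model, "uau")
        field = fx.make_field([fx.uau_triple()] * 2, 20, seed=13)
        ref = search_structure(pattern, field, TOL_17)
        moved = fx.transform(field, random_rotation(rng),
                             rng.uniform(-40, 40, 3))
        hits = search_structure(pattern, moved, TOL_17)
        assert [h.residues for h in hits] == [h.residues for h in ref]
        for a, b in zip(hits, ref):
            assert a.max_abs_deviation == pytest.approx(
                b.max_abs_deviation, abs=1e-6)

    def test_sequence_order_independence(self, uau_model):
        """Hits do not depend on residue numbering along the chain."""
        pattern = pattern_from_occurrence(uau_model, "uau")
        field = fx.make_field([fx.uau_triple()], 12, seed=3)
        hits = search_structure(pattern, field, TOL_01)
        reversed_field = [
            type(n)(res_id=("A", len(field) - i, ""), base_type=n.base_type,
                    atoms=n.atoms)
            for i, n in enumerate(field)
        ]
        hits_rev = search_structure(pattern, reversed_field, TOL_01)
        assert len(hits) == len(hits_rev) == 1

    def test_wildcard_slot_matches_any_base(self, uau_model):
        pattern = pattern_from_occurrence(uau_model, "uau")
        concrete = {h.residues
                    for h in search_structure(pattern, uau_model, TOL_01)}
        pattern.slots = ("N", "N", "N")
        wild = {h.residues
                for h in search_structure(pattern, uau_model, TOL_01)}
        assert concrete <= wild

    def test_tolerance_monotonicity(self, uau_model):
        pattern = pattern_from_occurrence(uau_model, "uau")
        field = fx.perturb(fx.make_field([fx.uau_triple()] * 2, 20, seed=23),
                           sigma=0.15, seed=5)
        sets = []
        for tol in (ToleranceSpec("absolute", 0.0), TOL_01, TOL_17, TOL_60):
            sets.append({h.residues
                         for h in search_structure(pattern, field, tol)})
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestCanonicalization:
    def test_symmetric_slots_collapse(self, uau_model):
        # under a tolerance loose enough to blur the two U environments the
        # raw search yields both assignments of one residue set;
        # canonicalization keeps the better one
        pattern = pattern_from_occurrence(uau_model, "uau")
        graph = StructureGraph.from_nucleotides(uau_model)
        raw = ullmann_search(pattern, graph, ToleranceSpec("percent", 500))
        assert len(raw) == 2
        assert len({h.residues for h in raw}) == 1
        assert raw[0].assignment != raw[1].assignment
        assert len(canonicalize_hits(raw)) == 1

    def test_disjoint_hits_kept(self):
        h1 = MatchHit({0: ("A", 1, ""), 1: ("A", 2, ""), 2: ("A", 3, "")}, 0.1)
        h2 = MatchHit({0: ("A", 4, ""), 1: ("A", 5, ""), 2: ("A", 6, "")}, 0.2)
        assert len(canonicalize_hits([h1, h2])) == 2

    def test_keeps_smallest_deviation(self):
        res = {0: ("A", 1, ""), 1: ("A", 2, ""), 2: ("A", 3, "")}
        h1 = MatchHit(dict(res), 0.5)
        h2 = MatchHit(dict(res), 0.2)
        out = canonicalize_hits([h1, h2])
        assert len(out) == 1 and out[0].max_abs_deviation == 0.2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [101, 102, 103])
    @pytest.mark.parametrize("tol", [TOL_01, TOL_17, TOL_60],
                             ids=["0.1A", "1.7A", "60%"])
    def test_matches_brute_force(self, seed, tol, uau_model, gcg_model):
        rng = np.random.default_rng(seed)
        n_decoys = int(rng.integers(24, 40))
        field = fx.make_field(
            [fx.uau_triple(), fx.gcg_triple()], n_decoys, seed=seed)
        for model, name in ((uau_model, "uau"), (gcg_model, "gcg")):
            pattern = pattern_from_occurrence(model, name)
            expected = brute_force_hits(pattern, field, tol)
            got = {h.residues: h.max_abs_deviation
                   for h in search_structure(pattern, field, tol)}
            assert set(got) == set(expected)
            for key in got:
                assert got[key] == pytest.approx(expected[key], abs=1e-9)

    def test_refinement_never_removes_valid_hits(self, uau_model):
        """Completeness: every brute-force hit survives Ullmann refinement."""
        pattern = pattern_from_occurrence(uau_model, "uau")
        field = fx.perturb(
            fx.make_field([fx.uau_triple()] * 3, 30, seed=77),
            sigma=0.2, seed=8)
        expected = brute_force_hits(pattern, field, TOL_60)
        got = {h.residues for h in search_structure(pattern, field, TOL_60)}
        assert set(expected) <= got
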