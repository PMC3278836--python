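import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplescan import fixtures as fx
from triplescan.geometry import random_rotation
from triplescan.patterns import (PatternMatrix, ToleranceSpec, all_block_keys,
                                 encode_distance, load_library,
                                 pattern_from_occurrence, read_pattern,
                                 starter_library, write_pattern)


class TestEncodeDistance:
    @pytest.mark.parametrize("d,expected", [
        (10.0, 100),   # a 10 Å separation is marked 100 in the SS column
        (0.0, 0),
        (1.74, 17),    # round half away from zero on tenths
        (1.75, 18),
        (2.85, 29),
    ])
    def test_examples(self, d, expected):
        assert encode_distance(d) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            encode_distance(-0.1)

    @given(st.floats(min_value=0.0, max_value=500.0),
           st.floats(min_value=0.0, max_value=500.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_exact_on_tenths(self, a, b):
        lo, hi = sorted((a, b))
        assert encode_distance(lo) <= encode_distance(hi)
        tenth = round(lo, 1)
        assert encode_distance(tenth) == pytest.approx(round(tenth * 10))


class TestPatternFromOccurrence:
    def test_canonical_under_all_input_orders(self, uau_model):
        reference = pattern_from_occurrence(uau_model, "p")
        for perm in itertools.permutations(uau_model):
            p = pattern_from_occurrence(list(perm), "p")
            assert p.slots == reference.slots
            assert p.blocks == reference.blocks

    def test_rigid_motion_invariance(self, gcg_model, rng):
        reference = pattern_from_occurrence(gcg_model, "p")
        moved = fx.transform(gcg_model, random_rotation(rng),
                             rng.uniform(-30, 30, 3))
        assert pattern_from_occurrence(moved, "p").blocks == reference.blocks

    def test_duplicate_residues_rejected(self, uau_model):
        with pytest.raises(ValueError, match="duplicate"):
            pattern_from_occurrence([uau_model[0]] * 2 + [uau_model[1]], "p")

    def test_ss_entry_is_measured_sx_sx_distance(self, gcg_model):
        from triplescan.pseudoatoms import compute_pseudoatoms

        p = pattern_from_occurrence(gcg_model, "p")
        ordered = sorted(gcg_model, key=lambda n: (n.base_type, n.res_id))
        ps = [compute_pseudoatoms(n) for n in ordered]
        d = float(np.linalg.norm(ps[0].nodes["Sx"] - ps[2].nodes["Sx"]))
        assert p.blocks[((0, "X"), (2, "X"))][0] == encode_distance(d)

    def test_intra_block_consistent_with_midpoint_constraint(self, uau_model):
        p = pattern_from_occurrence(uau_model, "p")
        for slot in range(3):
            # midpoints coincide by construction; well under the 1 Å bound
            assert p.estimated_intra_midpoint_separation(slot) < 0.5


class TestPatternFiles:
    def test_round_trip(self, tmp_path, uau_model):
        p = pattern_from_occurrence(uau_model, "uau test")
        path = tmp_path / "p.pat"
        write_pattern(p, path)
        q = read_pattern(path)
        assert (q.name, q.slots, q.convention, q.chirality, q.blocks) == (
            p.name, p.slots, p.convention, p.chirality, p.blocks)

    def test_swapped_unit_order_respects_mirror_rule(self, tmp_path, uau_model):
        p = pattern_from_occurrence(uau_model, "p")
        path = tmp_path / "p.pat"
        write_pattern(p, path)
        lines = path.read_text().splitlines()
        out = []
        for line in lines:
            tokens = line.split()
            if tokens and tokens[0].startswith("B") and len(tokens) == 6:
                ss, se, es, ee = (t.split("=")[1] for t in tokens[2:])
                out.append(f"{tokens[1]} {tokens[0]} "
                           f"SS={ss} SE={es} ES={se} EE={ee}")
            else:
                out.append(line)
        path.write_text("\n".join(out) + "\n")
        assert read_pattern(path).blocks == p.blocks

    @pytest.mark.parametrize("mutation,message", [
        (lambda s: s.replace("SS=", "SS=x"), "bad entry"),
        (lambda s: s.replace("CONVENTION glyN-centroid-L2.0-v1\n", ""),
         "missing CONVENTION"),
        (lambda s: s.replace("SLOTS A U U", "SLOTS A U"), "SLOTS"),
        (lambda s: s.replace("B1X B1Y", "B1X B1X", 1), "self-pair"),
    ])
    def test_malformed_files_rejected(self, tmp_path, uau_model,
                                      mutation, message):
        p = pattern_from_occurrence(uau_model, "p")
        path = tmp_path / "p.pat"
        write_pattern(p, path)
        path.write_text(mutation(path.read_text()))
        with pytest.raises(ValueError, match=message):
            read_pattern(path)

    def test_library_round_trip_and_sorting(self, tmp_path):
        specs = [fx.uau_triple(), fx.gcg_triple(), fx.wc_gc_pair()]
        originals = []
        for i, spec in enumerate(specs[:2]):
            model = fx.compose_triple(spec)
            p = pattern_from_occurrence(model, f"pat-{i}")
            write_pattern(p, tmp_path / f"zz-{1-i}.pat")
            originals.append(p)
        loaded = load_library(tmp_path)
        assert [p.name for p in loaded] == ["pat-1", "pat-0"]  # file-name order
        assert {p.name: p.blocks for p in loaded} == {
            p.name: p.blocks for p in originals}

    def test_library_duplicate_names_rejected(self, tmp_path, uau_model):
        p = pattern_from_occurrence(uau_model, "same")
        write_pattern(p, tmp_path / "a.pat")
        write_pattern(p, tmp_path / "b.pat")
        with pytest.raises(ValueError, match="duplicate pattern names"):
            load_library(tmp_path)

    def test_empty_directory(self, tmp_path):
        assert load_library(tmp_path) == []

    def test_starter_library_ships_valid_patterns(self):
        lib = starter_library()
        assert len(lib) >= 4
        assert all(isinstance(p, PatternMatrix) for p in lib)
        assert len(all_block_keys()) == 15


class TestToleranceSpec:
    @pytest.mark.parametrize("text,mode,value", [
        ("1.7A", "absolute", 1.7),
        ("60%", "percent", 60.0),
        ("0.1a", "absolute", 0.1),
        ("2.5", "absolute", 2.5),
    ])
    def test_parse(self, text, mode, value):
        tol = ToleranceSpec.parse(text)
        assert (tol.mode, tol.value) == (mode, value)

    def test_invalid(self):
        with pytest.raises(ValueError):
            ToleranceSpec("absolute", -1.0)
        with pytest.raises(ValueError):
            ToleranceSpec("nonsense", 1.0)
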