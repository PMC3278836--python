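"""Exhaustive reference matcher used as an independent oracle.

Enumerates every ordered assignment of three distinct residues to the
three pattern slots and checks all node-pair distance blocks directly
from coordinates — no candidate pruning, no refinement, no spatial
index. Feasible up to ~50 nucleotides."""

import itertools

import numpy as np

from triplescan.matcher import StructureGraph
from triplescan.patterns import all_block_keys

_AXIS_NODES = {"X": (0, 1), "Y": (2, 3)}


def brute_force_hits(pattern, nucleotides, tol):
    """Canonical hit dict: sorted residue-id triple -> best worst-case
    deviation (Å) over all slot assignments of that residue set."""
    graph = StructureGraph.from_nucleotides(nucleotides)
    nodes = graph.node_array()
    n = len(nucleotides)
    keys = all_block_keys()
    found = {}
    for combo in itertools.permutations(range(n), 3):
        if any(pattern.slots[k] not in ("N", nucleotides[combo[k]].base_type)
               for k in range(3)):
            continue
        worst, ok = 0.0, True
        for (i, ax_i), (j, ax_j) in keys:
            entries = pattern.block((i, ax_i), (j, ax_j))
            si, ei = _AXIS_NODES[ax_i]
            sj, ej = _AXIS_NODES[ax_j]
            ri, rj = combo[i], combo[j]
            for enc, (a, b) in zip(entries,
                                   ((si, sj), (si, ej), (ei, sj), (ei, ej))):
                d = float(np.linalg.norm(nodes[ri][a] - nodes[rj][b]))
                ref = enc / 10.0
                limit = (tol.value if tol.mode == "absolute"
                         else tol.value / 100.0 * ref)
                if abs(d - ref) > limit:
                    ok = False
                    break
                worst = max(worst, abs(d - ref))
            if not ok:
                break
        if ok:
            key = tuple(sorted(nucleotides[k].res_id for k in combo))
            if key not in found or worst < found[key]:
                found[key] = worst
    return found
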