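"""Ullmann subgraph-isomorphism search of pattern matrices against a
structure's pseudo-atom distance graph.

The pattern is a complete graph on six vector units (three bases times
two vectors); the structure contributes two units per nucleotide. Because
a slot's X and Y units must land on the same nucleotide, the search runs
at nucleotide granularity: slot-to-nucleotide candidates are pruned by
base type, intra-base block compatibility and a spatial index, then
refined Ullmann-style (a candidate survives only while every other slot
retains a compatible partner for it) before depth-first enumeration.
Matching depends only on distances, so hits are independent of sequence
order and residue numbering; a post-match chirality check flags
mirror-image embeddings, which distance matrices alone cannot exclude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .patterns import AXES, PatternMatrix, ToleranceSpec
from .pseudoatoms import PseudoatomSet, chirality_sign, compute_pseudoatoms
from .structure_io import Nucleotide, ResId


@dataclass
class StructureGraph:
    """Pseudo-atom view of a structure, ready to be searched."""

    nucleotides: list[Nucleotide]
    psets: list[PseudoatomSet]
    convention: str

    @classmethod
    def from_nucleotides(cls, nucleotides: list[Nucleotide]) -> "StructureGraph":
        psets = [compute_pseudoatoms(n) for n in nucleotides]
        convention = psets[0].convention if psets else ""
        return cls(nucleotides=list(nucleotides), psets=psets,
                   convention=convention)

    def __len__(self):
        return len(self.nucleotides)

    def node_array(self) -> np.ndarray:
        """(n, 4, 3) array of node coordinates in Sx, Ex, Sy, Ey order."""
        return np.array([
            [ps.nodes["Sx"], ps.nodes["Ex"], ps.nodes["Sy"], ps.nodes["Ey"]]
            for ps in self.psets
        ]).reshape(len(self.psets), 4, 3)

    def centroids(self) -> np.ndarray:
        return np.array([ps.mid_x for ps in self.psets])


@dataclass
class MatchHit:
    assignment: dict[int, ResId]  # pattern slot -> residue id
    max_abs_deviation: float      # Å, worst node-pair distance deviation
    mirror_flag: bool = False

    @property
    def residues(self) -> tuple[ResId, ...]:
        return tuple(sorted(self.assignment.values()))


def edge_compatible(d_pattern: int, d_structure: float,
                    tol: ToleranceSpec) -> bool:
    """Is a structure distance within tolerance of an encoded pattern
    distance? Absolute tolerances are in Å; percent tolerances apply to
    the pattern distance (the pattern is the reference object)."""
    ref = d_pattern / 10.0
    dev = abs(d_structure - ref)
    if tol.mode == "absolute":
        return dev <= tol.value
    return dev <= (tol.value / 100.0) * ref


# node index within a unit-axis: S=0, E=1 offsets into the (4,3) node array
_AXIS_NODES = {"X": (0, 1), "Y": (2, 3)}


def _pair_block_ok(pattern: PatternMatrix, slot_i: int, slot_j: int,
                   nodes_r: np.ndarray, nodes_s: np.ndarray,
                   tol: ToleranceSpec) -> tuple[bool, float]:
    """Check all four inter-base axis blocks between two candidate
    nucleotides; returns (ok, worst deviation in Å)."""
    worst = 0.0
    for ax_i in AXES:
        si, ei = _AXIS_NODES[ax_i]
        for ax_j in AXES:
            sj, ej = _AXIS_NODES[ax_j]
            entries = pattern.block((slot_i, ax_i), (slot_j, ax_j))
            for d_enc, (a, b) in zip(entries,
                                     ((si, sj), (si, ej), (ei, sj), (ei, ej))):
                d = float(np.linalg.norm(nodes_r[a] - nodes_s[b]))
                if not edge_compatible(d_enc, d, tol):
                    return False, worst
                worst = max(worst, abs(d - d_enc / 10.0))
    return True, worst


def _intra_block_ok(pattern: PatternMatrix, slot: int,
                    nodes_r: np.ndarray, tol: ToleranceSpec) -> tuple[bool, float]:
    entries = pattern.block((slot, "X"), (slot, "Y"))
    worst = 0.0
    for d_enc, (a, b) in zip(entries, ((0, 2), (0, 3), (1, 2), (1, 3))):
        d = float(np.linalg.norm(nodes_r[a] - nodes_r[b]))
        if not edge_compatible(d_enc, d, tol):
            return False, worst
        worst = max(worst, abs(d - d_enc / 10.0))
    return True, worst


def ullmann_search(pattern: PatternMatrix, graph: StructureGraph,
                   tol: ToleranceSpec) -> list[MatchHit]:
    """Find every assignment of the pattern's three slots to distinct
    nucleotides whose node-pair distances all satisfy the tolerance.

    Raw hits include symmetric duplicates when slots share a base type;
    use :func:`canonicalize_hits` to collapse them."""
    if graph.convention and pattern.convention != graph.convention:
        raise ValueError(
            f"pattern convention {pattern.convention!r} does not match "
            f"structure convention {graph.convention!r}")
    n = len(graph)
    if n < 3:
        return []
    nodes = graph.node_array()

    # stage 0: per-slot candidate lists (base type + intra-base block)
    candidates: list[np.ndarray] = []
    intra_dev = np.zeros((3, n))
    for slot in range(3):
        mask = np.zeros(n, dtype=bool)
        for r, nuc in enumerate(graph.nucleotides):
            if pattern.slots[slot] not in ("N", nuc.base_type):
                continue
            ok, dev = _intra_block_ok(pattern, slot, nodes[r], tol)
            if ok:
                mask[r] = True
                intra_dev[slot, r] = dev
        candidates.append(mask)

    # stage 1: spatial pruning — any two matched nucleotides must lie
    # within the largest pattern distance plus the tolerance ceiling
    # node-to-midpoint slack: every node lies within ~2.25 Å of its base
    # midpoint, so centroids of compatible bases are within ceiling + 4.5
    radius = tol.ceiling(pattern.max_distance()) + 4.5
    tree = cKDTree(graph.centroids())
    neighbor_sets = [set(tree.query_ball_point(graph.centroids()[r], radius))
                     for r in range(n)]

    # pairwise compatibility tables for each ordered slot pair
    pair_ok: dict[tuple[int, int], dict[tuple[int, int], float]] = {}
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            table: dict[tuple[int, int], float] = {}
            for r in np.nonzero(candidates[i])[0]:
                for s in neighbor_sets[r]:
                    if s == r or not candidates[j][s]:
                        continue
                    if (j, i) in pair_ok:  # symmetric: reuse the transpose
                        if (s, r) in pair_ok[(j, i)]:
                            table[(r, s)] = pair_ok[(j, i)][(s, r)]
                        continue
                    ok, dev = _pair_block_ok(pattern, i, j,
                                             nodes[r], nodes[s], tol)
                    if ok:
                        table[(r, s)] = dev
            pair_ok[(i, j)] = table

    # stage 2: Ullmann refinement — drop candidate (i, r) if some other
    # slot j has no surviving candidate s compatible with r
    changed = True
    while changed:
        changed = False
        for i in range(3):
            for r in np.nonzero(candidates[i])[0]:
                for j in range(3):
                    if j == i:
                        continue
                    if not any((r, s) in pair_ok[(i, j)] and candidates[j][s]
                               for s in neighbor_sets[r]):
                        candidates[i][r] = False
                        changed = True
                        break

    # stage 3: depth-first enumeration over the refined candidates
    hits: list[MatchHit] = []
    for r0 in np.nonzero(candidates[0])[0]:
        for r1 in np.nonzero(candidates[1])[0]:
            if r1 == r0 or (r0, r1) not in pair_ok[(0, 1)]:
                continue
            for r2 in np.nonzero(candidates[2])[0]:
                if r2 in (r0, r1):
                    continue
                if (r0, r2) not in pair_ok[(0, 2)]:
                    continue
                if (r1, r2) not in pair_ok[(1, 2)]:
                    continue
                devs = (
                    intra_dev[0, r0], intra_dev[1, r1], intra_dev[2, r2],
                    pair_ok[(0, 1)][(r0, r1)],
                    pair_ok[(0, 2)][(r0, r2)],
                    pair_ok[(1, 2)][(r1, r2)],
                )
                assigned = [graph.nucleotides[r] for r in (r0, r1, r2)]
                mirror = (pattern.chirality != 0
                          and chirality_sign(assigned) != 0
                          and chirality_sign(assigned) != pattern.chirality)
                hits.append(MatchHit(
                    assignment={0: assigned[0].res_id, 1: assigned[1].res_id,
                                2: assigned[2].res_id},
                    max_abs_deviation=float(max(devs)),
                    mirror_flag=mirror,
                ))
    hits.sort(key=lambda h: h.residues)
    return hits


def canonicalize_hits(hits: list[MatchHit]) -> list[MatchHit]:
    """Collapse hits on the same residue set (symmetric slot assignments)
    to the one with the smallest worst-case deviation; deterministic
    output order by sorted residue ids."""
    best: dict[tuple[ResId, ...], MatchHit] = {}
    for hit in hits:
        key = hit.residues
        cur = best.get(key)
        if cur is None or hit.max_abs_deviation < cur.max_abs_deviation:
            best[key] = hit
    return [best[k] for k in sorted(best)]


def search_structure(pattern: PatternMatrix, nucleotides: list[Nucleotide],
                     tol: ToleranceSpec) -> list[MatchHit]:
    """Convenience wrapper: build the graph, search, canonicalize."""
    graph = StructureGraph.from_nucleotides(nucleotides)
    return canonicalize_hits(ullmann_search(pattern, graph, tol))
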