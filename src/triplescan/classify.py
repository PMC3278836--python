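"""Leontis-Westhof classification of base-triple geometry.

Each hydrogen-bonded pair in a triple is described by the interacting
edge of each base — Watson-Crick (WC), Hoogsteen (H) or Sugar (S) — and
by the cis/trans orientation of the two glycosidic bonds. Pyrimidines'
C-H edge is labelled Hoogsteen for uniformity. The per-pair labels are
assembled into a canonical geometric-family string by arranging cis
interactions before trans and the edges of each pair alphabetically, so
that equivalent geometries always produce the same name. Triples further
receive a composition code (sorted base letters plus a registry suffix,
e.g. "AGU1") that is stable across structures for a given bond topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EDGE_ATOMS, GLYCOSIDIC_N
from .geometry import dihedral
from .hbond import HydrogenBond
from .pseudoatoms import ring_centroid
from .structure_io import Nucleotide, ResId

EDGE_ORDER = ("H", "S", "WC")  # alphabetical
_EDGE_PRIORITY = {"WC": 0, "H": 1, "S": 2}  # tie-break: WC > H > S


@dataclass(frozen=True)
class PairGeometry:
    res_a: ResId
    res_b: ResId
    edge_a: str
    edge_b: str
    orientation: str  # "Cis" | "Trans"

    def label(self) -> str:
        """Canonical pair label: orientation then the two edges in
        alphabetical order, e.g. 'Cis WC / WC' or 'Trans H / WC'."""
        e1, e2 = sorted((self.edge_a, self.edge_b))
        return f"{self.orientation} {e1} / {e2}"

    @property
    def is_wc_pair(self) -> bool:
        return (self.orientation == "Cis"
                and self.edge_a == "WC" and self.edge_b == "WC")


@dataclass
class TripleRecord:
    nucleotides: list[Nucleotide]
    hbonds: list[HydrogenBond]
    pair_geometries: list[PairGeometry] = field(default_factory=list)
    family: str = ""
    code: str = ""
    matched_patterns: list[str] = field(default_factory=list)

    @property
    def residues(self) -> tuple[ResId, ...]:
        return tuple(sorted(n.res_id for n in self.nucleotides))

    @property
    def composition(self) -> str:
        return "".join(sorted(n.base_type for n in self.nucleotides))

    @property
    def contains_wc_pair(self) -> bool:
        return any(pg.is_wc_pair for pg in self.pair_geometries)


def _edge_direction(nuc: Nucleotide, edge: str) -> np.ndarray:
    atoms = [a for a in EDGE_ATOMS[nuc.base_type][edge] if a in nuc.atoms]
    centroid = ring_centroid(nuc)
    return np.mean([nuc.coord(a) for a in atoms], axis=0) - centroid


def dominant_edge(base: Nucleotide, partner: Nucleotide,
                  hbonds: list[HydrogenBond]) -> str:
    """Edge of ``base`` facing ``partner``, by majority over the base's
    bonding atoms.

    Atoms exclusive to one edge vote directly. Atoms shared between two
    edges (amino groups, carbonyls at edge corners) side with whichever
    of their edges received an exclusive vote; failing that, the edge
    whose atoms point most directly at the partner wins. Final ties break
    WC > H > S."""
    my_atoms = []
    for hb in hbonds:
        if hb.donor[0] == base.res_id:
            my_atoms.append(hb.donor[1])
        if hb.acceptor[0] == base.res_id:
            my_atoms.append(hb.acceptor[1])
    if not my_atoms:
        raise ValueError(f"no hydrogen bonds from {base!r} to classify")

    tables = EDGE_ATOMS[base.base_type]
    votes = {"WC": 0.0, "H": 0.0, "S": 0.0}
    ambiguous = []
    for atom in my_atoms:
        edges = [e for e in ("WC", "H", "S") if atom in tables[e]]
        if len(edges) == 1:
            votes[edges[0]] += 1.0
        elif edges:
            ambiguous.append(edges)
    for edges in ambiguous:
        backed = [e for e in edges if votes[e] > 0]
        if len(backed) == 1:
            votes[backed[0]] += 1.0
            continue
        # geometric side: which candidate edge faces the partner base
        toward = ring_centroid(partner) - ring_centroid(base)
        cosines = {
            e: float(np.dot(_edge_direction(base, e), toward))
            for e in edges
        }
        votes[max(cosines, key=lambda e: (cosines[e], -_EDGE_PRIORITY[e]))] += 1.0
    best = max(votes.values())
    winners = [e for e, v in votes.items() if v == best]
    winners.sort(key=lambda e: _EDGE_PRIORITY[e])
    return winners[0]


def cis_or_trans(a: Nucleotide, b: Nucleotide) -> str:
    """Glycosidic-bond orientation of a pair: the C1'-N-N-C1' dihedral
    (N = glycosidic nitrogen); magnitudes up to and including 90° are
    Cis, beyond is Trans."""
    na, nb = GLYCOSIDIC_N[a.base_type], GLYCOSIDIC_N[b.base_type]
    try:
        c1a, c1b = a.coord("C1'"), b.coord("C1'")
    except KeyError:
        # C1' can be absent in stripped files: proxy the glycosidic bond
        # by the centroid->N direction (points the same way from the ring)
        c1a = a.coord(na) + (a.coord(na) - ring_centroid(a))
        c1b = b.coord(nb) + (b.coord(nb) - ring_centroid(b))
    d = dihedral(c1a, a.coord(na), b.coord(nb), c1b)
    return "Cis" if abs(d) <= 90.0 else "Trans"


def classify_pairs(nucs: list[Nucleotide],
                   hbonds: list[HydrogenBond]) -> list[PairGeometry]:
    """PairGeometry for every hydrogen-bonded pair within the triple."""
    by_id = {n.res_id: n for n in nucs}
    pairs: dict[tuple[ResId, ResId], list[HydrogenBond]] = {}
    for hb in hbonds:
        key = tuple(sorted((hb.donor[0], hb.acceptor[0])))
        pairs.setdefault(key, []).append(hb)
    out = []
    for (ra, rb), bonds in sorted(pairs.items()):
        a, b = by_id[ra], by_id[rb]
        out.append(PairGeometry(
            res_a=ra, res_b=rb,
            edge_a=dominant_edge(a, b, bonds),
            edge_b=dominant_edge(b, a, bonds),
            orientation=cis_or_trans(a, b),
        ))
    return out


def family_string(pair_geometries: list[PairGeometry]) -> str:
    """Canonical geometric-family name: pair labels sorted cis before
    trans, then alphabetically, joined with ' – '."""
    labels = [pg.label() for pg in pair_geometries]
    labels.sort(key=lambda s: (0 if s.startswith("Cis") else 1, s))
    return " – ".join(labels)


class TripleCodeRegistry:
    """Assigns stable composition codes like 'AGU1': letters are the
    sorted base composition, the suffix indexes the distinct (family,
    bond-topology) combinations seen for that composition. The same
    topology always maps to the same code within a registry."""

    def __init__(self):
        self._by_composition: dict[str, list[tuple[str, frozenset]]] = {}

    def to_json(self) -> str:
        """Serialize so codes stay stable across runs and structures."""
        import json

        payload = {
            comp: [[family, sorted(map(list, topo))] for family, topo in seen]
            for comp, seen in self._by_composition.items()
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TripleCodeRegistry":
        import json

        reg = cls()
        for comp, seen in json.loads(text).items():
            reg._by_composition[comp] = [
                (family, frozenset(tuple(entry) for entry in topo))
                for family, topo in seen
            ]
        return reg

    @staticmethod
    def topology_key(t: TripleRecord) -> frozenset:
        """Base-level donor/acceptor atom topology, residue-id free."""
        by_id = {n.res_id: n.base_type for n in t.nucleotides}
        return frozenset(
            (by_id[hb.donor[0]], hb.donor[1], by_id[hb.acceptor[0]],
             hb.acceptor[1], hb.protonated)
            for hb in t.hbonds
        )

    def assign(self, t: TripleRecord) -> str:
        comp = t.composition
        key = (t.family, self.topology_key(t))
        known = self._by_composition.setdefault(comp, [])
        for idx, existing in enumerate(known, start=1):
            if existing == key:
                return f"{comp}{idx}"
        known.append(key)
        return f"{comp}{len(known)}"


def classify_triple(nucs: list[Nucleotide], hbonds: list[HydrogenBond],
                    registry: TripleCodeRegistry | None = None) -> TripleRecord:
    """Full classification of an admitted triple."""
    record = TripleRecord(nucleotides=list(nucs), hbonds=list(hbonds))
    record.pair_geometries = classify_pairs(record.nucleotides, record.hbonds)
    record.family = family_string(record.pair_geometries)
    if registry is not None:
        record.code = registry.assign(record)
    return record
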