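"""Three-base query pattern matrices.

A pattern encodes a hypothetical or observed base triple as the set of
distances between the pseudo-atom nodes of its three bases. Distances are
stored as integers in tenths of an ångström (a 10 Å separation is stored
as 100). Every unordered pair of vector units gets a block of four
entries — SS, SE, ES, EE — for the four start/end node combinations; the
intra-base X/Y block participates like any other and carries the
requirement that both vectors sit on the same base.

File dialect (plain text)::

    NAME      wc-gcg
    CONVENTION glyN-centroid-L2.0-v1
    SLOTS     C G G
    CHIRALITY 0
    B1X B1Y SS=28 SE=28 ES=28 EE=28
    B1X B2X SS=100 SE=89 ES=57 EE=61
    ...

Unit labels are ``B<slot><axis>`` with slots 1-3 and axes X/Y; 15 block
lines cover all unit pairs. ``SLOTS`` may use the wildcard ``N``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DEFAULT_CONVENTION
from .pseudoatoms import PseudoatomSet, chirality_sign, compute_pseudoatoms

VALID_SLOT_TYPES = ("A", "C", "G", "U", "N")
AXES = ("X", "Y")

#: A unit is one pseudo-atom vector: (slot index 0-2, axis).
Unit = tuple[int, str]
#: Block key: canonically ordered unit pair.
BlockKey = tuple[Unit, Unit]


@dataclass(frozen=True)
class ToleranceSpec:
    """Distance tolerance: absolute (Å) or percent of the pattern distance.

    Percentages of 60 and above give the 'fuzzy' regime used for
    discovery searches."""

    mode: str  # "absolute" | "percent"
    value: float

    def __post_init__(self):
        if self.mode not in ("absolute", "percent"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")
        if self.value < 0:
            raise ValueError("tolerance value must be >= 0")

    @classmethod
    def parse(cls, text: str) -> "ToleranceSpec":
        """Parse CLI notation: '1.7A' (absolute Å) or '60%' (percent)."""
        text = text.strip()
        if text.endswith("%"):
            return cls("percent", float(text[:-1]))
        if text.upper().endswith("A"):
            return cls("absolute", float(text[:-1]))
        return cls("absolute", float(text))

    def ceiling(self, d_pattern_angstrom: float) -> float:
        """Largest structure distance compatible with a pattern distance."""
        if self.mode == "absolute":
            return d_pattern_angstrom + self.value
        return d_pattern_angstrom * (1.0 + self.value / 100.0)

    def __str__(self):
        return (f"{self.value:g}%" if self.mode == "percent"
                else f"{self.value:g}A")


def encode_distance(d: float) -> int:
    """Distance in Å -> integer tenths of Å, rounded half away from zero."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return int(math.floor(d * 10.0 + 0.5))


def canonical_block_key(u: Unit, v: Unit) -> tuple[BlockKey, bool]:
    """Canonical ordering for a unit pair; True if the pair was swapped
    (SE and ES entries must then be exchanged)."""
    if (u[0], u[1]) <= (v[0], v[1]):
        return (u, v), False
    return (v, u), True


def all_block_keys() -> list[BlockKey]:
    units = [(s, a) for s in range(3) for a in AXES]
    return [(units[i], units[j])
            for i in range(len(units)) for j in range(i + 1, len(units))]


@dataclass
class PatternMatrix:
    name: str
    slots: tuple[str, str, str]
    blocks: dict[BlockKey, tuple[int, int, int, int]]
    convention: str = DEFAULT_CONVENTION
    chirality: int = 0  # +1/-1 handedness of the source occurrence, 0 unknown
    source: tuple[str, ...] = field(default=())  # informational residue ids

    def __post_init__(self):
        self.slots = tuple(self.slots)
        if len(self.slots) != 3 or any(s not in VALID_SLOT_TYPES for s in self.slots):
            raise ValueError(f"slots must be 3 of {VALID_SLOT_TYPES}, got {self.slots}")
        expected = set(all_block_keys())
        if set(self.blocks) != expected:
            raise ValueError(
                f"pattern {self.name!r}: expected {len(expected)} blocks, "
                f"got {len(self.blocks)}")
        for key, entries in self.blocks.items():
            if len(entries) != 4 or any(e < 0 for e in entries):
                raise ValueError(f"pattern {self.name!r}: bad block {key}: {entries}")

    def block(self, u: Unit, v: Unit) -> tuple[int, int, int, int]:
        """Block for an arbitrary unit order; SE/ES swapped as needed."""
        key, swapped = canonical_block_key(u, v)
        ss, se, es, ee = self.blocks[key]
        return (ss, es, se, ee) if swapped else (ss, se, es, ee)

    def max_distance(self) -> float:
        """Largest encoded node-pair distance, Å (spatial-pruning radius)."""
        return max(max(e) for e in self.blocks.values()) / 10.0

    def estimated_intra_midpoint_separation(self, slot: int) -> float:
        """Midpoint separation (Å) of a slot's X/Y vectors implied by its
        intra block, using nominal vector lengths for the slot base type.

        For points {S1,E1} and {S2,E2} the identity
        ``4*|m1-m2|^2 = (SS^2+SE^2+ES^2+EE^2) - |S1-E1|^2 - |S2-E2|^2``
        recovers the midpoint separation from the stored distances."""
        from .idealized import nominal_vector_lengths

        base = self.slots[slot]
        if base == "N":  # wildcard: use the largest nominal length (lenient)
            lx = max(nominal_vector_lengths(b)[0] for b in "ACGU")
            ly = nominal_vector_lengths("A")[1]
        else:
            lx, ly = nominal_vector_lengths(base)
        entries = self.blocks[((slot, "X"), (slot, "Y"))]
        sq = sum((e / 10.0) ** 2 for e in entries) - lx**2 - ly**2
        return math.sqrt(max(sq, 0.0) / 4.0)


def pattern_from_occurrence(nucs, name: str = "occurrence",
                            convention: str = DEFAULT_CONVENTION) -> PatternMatrix:
    """Build a pattern by measuring pseudo-atom distances from an actual
    occurrence of three nucleotides.

    Slots are put in canonical order — base type alphabetical, then
    residue id — so the six possible input orders all yield the same
    pattern."""
    nucs = list(nucs)
    if len(nucs) != 3:
        raise ValueError("a pattern is built from exactly 3 nucleotides")
    if len({n.res_id for n in nucs}) != 3:
        raise ValueError("duplicate residue ids in occurrence")
    nucs.sort(key=lambda n: (n.base_type, n.res_id))
    psets = [compute_pseudoatoms(n) for n in nucs]
    blocks = measure_blocks(psets)
    return PatternMatrix(
        name=name,
        slots=tuple(n.base_type for n in nucs),
        blocks=blocks,
        convention=convention,
        chirality=chirality_sign(nucs),
        source=tuple(f"{c}:{num}{ic}" for (c, num, ic) in (n.res_id for n in nucs)),
    )


def measure_blocks(psets: list[PseudoatomSet]) -> dict[BlockKey, tuple[int, int, int, int]]:
    """Encode all 15 unit-pair distance blocks from three pseudoatom sets."""
    blocks = {}
    for (i, ax_i), (j, ax_j) in all_block_keys():
        si = psets[i].nodes[f"S{ax_i.lower()}"]
        ei = psets[i].nodes[f"E{ax_i.lower()}"]
        sj = psets[j].nodes[f"S{ax_j.lower()}"]
        ej = psets[j].nodes[f"E{ax_j.lower()}"]
        blocks[((i, ax_i), (j, ax_j))] = (
            encode_distance(float(np.linalg.norm(si - sj))),
            encode_distance(float(np.linalg.norm(si - ej))),
            encode_distance(float(np.linalg.norm(ei - sj))),
            encode_distance(float(np.linalg.norm(ei - ej))),
        )
    return blocks


_UNIT_RE = re.compile(r"^B([123])([XY])$")
_ENTRY_RE = re.compile(r"^(SS|SE|ES|EE)=(-?\d+)$")


def _parse_unit(token: str, lineno: int, path) -> Unit:
    m = _UNIT_RE.match(token)
    if not m:
        raise ValueError(f"{path}:{lineno}: bad unit label {token!r}")
    return int(m.group(1)) - 1, m.group(2)


def write_pattern(p: PatternMatrix, path) -> None:
    lines = [
        f"NAME {p.name}",
        f"CONVENTION {p.convention}",
        f"SLOTS {' '.join(p.slots)}",
        f"CHIRALITY {p.chirality:+d}" if p.chirality else "CHIRALITY 0",
    ]
    if p.source:
        lines.append(f"SOURCE {' '.join(p.source)}")
    for (u, v) in all_block_keys():
        ss, se, es, ee = p.blocks[(u, v)]
        lines.append(
            f"B{u[0]+1}{u[1]} B{v[0]+1}{v[1]} "
            f"SS={ss} SE={se} ES={es} EE={ee}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pattern(path) -> PatternMatrix:
    """Parse a pattern file; malformed input raises with the line number."""
    name = convention = None
    slots = None
    chirality = 0
    source: tuple[str, ...] = ()
    blocks: dict[BlockKey, tuple[int, int, int, int]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        head = tokens[0].upper()
        if head == "NAME":
            name = " ".join(tokens[1:])
        elif head == "CONVENTION":
            if len(tokens) != 2:
                raise ValueError(f"{path}:{lineno}: CONVENTION needs one token")
            convention = tokens[1]
        elif head == "SLOTS":
            if len(tokens) != 4:
                raise ValueError(f"{path}:{lineno}: SLOTS needs 3 base types")
            slots = tuple(t.upper() for t in tokens[1:])
        elif head == "CHIRALITY":
            chirality = int(tokens[1])
        elif head == "SOURCE":
            source = tuple(tokens[1:])
        elif head == "END":
            break
        else:
            if len(tokens) != 6:
                raise ValueError(f"{path}:{lineno}: expected 'Bij Bkl SS=.. SE=.. ES=.. EE=..'")
            u = _parse_unit(tokens[0], lineno, path)
            v = _parse_unit(tokens[1], lineno, path)
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-pair {tokens[0]}")
            entries = {}
            for tok in tokens[2:]:
                m = _ENTRY_RE.match(tok)
                if not m:
                    raise ValueError(f"{path}:{lineno}: bad entry {tok!r}")
                val = int(m.group(2))
                if val < 0:
                    raise ValueError(f"{path}:{lineno}: negative distance {tok!r}")
                entries[m.group(1)] = val
            if set(entries) != {"SS", "SE", "ES", "EE"}:
                raise ValueError(f"{path}:{lineno}: need SS, SE, ES and EE")
            key, swapped = canonical_block_key(u, v)
            vals = (entries["SS"], entries["SE"], entries["ES"], entries["EE"])
            if swapped:  # ES of (i,j) is SE of (j,i)
                vals = (vals[0], vals[2], vals[1], vals[3])
            if key in blocks and blocks[key] != vals:
                raise ValueError(f"{path}:{lineno}: conflicting duplicate block {key}")
            blocks[key] = vals
    if name is None:
        raise ValueError(f"{path}: missing NAME header")
    if convention is None:
        raise ValueError(f"{path}: missing CONVENTION header")
    if slots is None:
        raise ValueError(f"{path}: missing SLOTS header")
    return PatternMatrix(name=name, slots=slots, blocks=blocks,
                         convention=convention, chirality=chirality,
                         source=source)


def starter_library_dir() -> Path:
    """Directory of the small pattern library shipped with the package
    (patterns measured from the synthetic fixture triples)."""
    return Path(__file__).parent / "data" / "patterns"


def starter_library() -> list["PatternMatrix"]:
    return load_library(starter_library_dir())


def load_library(directory) -> list[PatternMatrix]:
    """Load every ``*.pat`` file in a directory, name-sorted; duplicate
    pattern names are an error."""
    directory = Path(directory)
    patterns = []
    for path in sorted(directory.glob("*.pat")):
        try:
            patterns.append(read_pattern(path))
        except ValueError:
            raise
        except OSError as exc:
            raise IOError(f"cannot read pattern file {path}: {exc}") from exc
    names = [p.name for p in patterns]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate pattern names in {directory}: {sorted(dupes)}")
    return patterns
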