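"""Read PDB coordinate files and extract admissible RNA nucleotides.

Only base heavy atoms matter downstream: the search engine works on a
reduced pseudo-atom representation and the hydrogen-bond filter considers
base–base contacts only. Nucleotides missing any ring heavy atom are
dropped (with a warning) because neither the pseudoatom recipe nor the
donor/acceptor chemistry is well defined for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .config import BASE_TYPES, DEFAULT_MODIFIED_ALIASES, RING_ATOMS

logger = logging.getLogger(__name__)

#: (chain id, residue number, insertion code)
ResId = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0,1]")


@dataclass
class Nucleotide:
    res_id: ResId
    base_type: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    def __post_init__(self):
        if self.base_type not in BASE_TYPES:
            raise ValueError(f"unknown base type {self.base_type!r}")

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].coords

    def has_ring_atoms(self) -> bool:
        return all(a in self.atoms for a in RING_ATOMS[self.base_type])

    def __repr__(self):  # compact: ('A', 7, '') G
        ch, num, ic = self.res_id
        return f"<Nucleotide {self.base_type} {ch}{num}{ic}>"


@dataclass
class StructureMeta:
    pdb_id: str
    resolution: float | None = None
    method: str = ""

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties broken by alphabetical altloc."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def read_structure(
    path: str,
    modified_aliases: dict[str, str] | None = None,
) -> tuple[list[Nucleotide], StructureMeta]:
    """Parse a PDB file into RNA nucleotides plus structure metadata.

    First model only; altlocs resolved to the highest-occupancy copy;
    residues named A/C/G/U (or mapped through ``modified_aliases``) are
    retained, everything else is dropped. Nucleotides missing a required
    ring heavy atom are dropped with a logged warning. A structure with no
    RNA yields an empty list, not an error.
    """
    aliases = DEFAULT_MODIFIED_ALIASES if modified_aliases is None else modified_aliases
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    meta = StructureMeta(
        pdb_id=(st.name or "XXXX").lower()[:4],
        resolution=resolution,
        method=(st.info["_exptl.method"] if "_exptl.method" in st.info else ""),
    )
    nucleotides: list[Nucleotide] = []
    if len(st) == 0:
        return nucleotides, meta
    model = st[0]
    for chain in model:
        for residue in chain:
            resname = residue.name.strip().upper()
            if resname in BASE_TYPES:
                base_type = resname
            elif resname in aliases:
                base_type = aliases[resname]
            else:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = {}
            for name, copies in by_name.items():
                a = _pick_altloc(copies)
                atoms[name] = AtomRecord(
                    name=name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    altloc=a.altloc,
                    occupancy=min(max(a.occ, 0.0), 1.0),
                )
            res_id: ResId = (chain.name, residue.seqid.num, residue.seqid.icode.strip())
            nuc = Nucleotide(res_id=res_id, base_type=base_type, atoms=atoms)
            if not nuc.has_ring_atoms():
                missing = [a for a in RING_ATOMS[base_type] if a not in atoms]
                logger.warning(
                    "dropping %s %s%s%s: missing ring atoms %s",
                    base_type, *res_id, ",".join(missing),
                )
                continue
            nucleotides.append(nuc)
    nucleotides.sort(key=lambda n: (n.res_id[0], n.res_id[1], n.res_id[2]))
    return nucleotides, meta


def passes_resolution(
    meta: StructureMeta,
    cutoff: float = 3.0,
    admit_missing: bool = False,
) -> bool:
    """Resolution admission filter: True iff resolution is present and
    at or better than ``cutoff`` (structures without a stated resolution
    are rejected unless ``admit_missing``)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if meta.resolution is None:
        return admit_missing
    return meta.resolution <= cutoff
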