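"""Reduced pseudo-atom representation of nucleobases.

Each base becomes two directed vectors (four labelled nodes):

* vector X runs from the glycosidic nitrogen ``Sx`` (N9 for purines, N1
  for pyrimidines) through the ring centroid to ``Ex = 2*centroid - Sx``,
  so it encodes the glycosidic orientation of the base;
* vector Y spans the base plane perpendicular to X: an in-plane anchor
  direction (N7-N3 for purines, C4-C2 for pyrimidines) is projected onto
  the base plane, orthogonalized against X, and ``Sy``/``Ey`` are placed
  at -L/+L along it from the centroid (L = 2.0 Å).

Both vector midpoints coincide at the ring centroid by construction, so
the 1 Å intra-base midpoint constraint used by the matcher holds with
margin. The recipe is identified by a convention tag; pattern libraries
record the tag and the matcher refuses to mix conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONVENTION, GLYCOSIDIC_N, PURINES, RING_ATOMS
from .geometry import fit_plane_normal, unit
from .structure_io import Nucleotide, ResId

#: Half-length of the Y vector, Å.
Y_HALF_LENGTH = 2.0

NODE_NAMES = ("Sx", "Ex", "Sy", "Ey")

#: In-plane anchor atoms defining the raw Y direction, per base class.
_Y_ANCHOR = {True: ("N7", "N3"), False: ("C4", "C2")}  # keyed by is_purine


@dataclass
class PseudoatomSet:
    res_id: ResId
    base_type: str
    nodes: dict[str, np.ndarray]
    convention: str = DEFAULT_CONVENTION

    @property
    def mid_x(self) -> np.ndarray:
        return 0.5 * (self.nodes["Sx"] + self.nodes["Ex"])

    @property
    def mid_y(self) -> np.ndarray:
        return 0.5 * (self.nodes["Sy"] + self.nodes["Ey"])

    def midpoint_separation(self) -> float:
        return float(np.linalg.norm(self.mid_x - self.mid_y))


def ring_centroid(nuc: Nucleotide) -> np.ndarray:
    """Arithmetic mean of the ring heavy atoms (9 for purines, 6 for
    pyrimidines)."""
    names = RING_ATOMS[nuc.base_type]
    missing = [n for n in names if n not in nuc.atoms]
    if missing:
        raise ValueError(f"{nuc!r}: missing ring atoms {missing}")
    return np.mean([nuc.coord(n) for n in names], axis=0)


def compute_pseudoatoms(nuc: Nucleotide) -> PseudoatomSet:
    """Compute the four pseudo-atom nodes of one base (see module docs)."""
    centroid = ring_centroid(nuc)
    is_purine = nuc.base_type in PURINES
    sx = nuc.coord(GLYCOSIDIC_N[nuc.base_type]).copy()
    ex = 2.0 * centroid - sx

    a_from, a_to = _Y_ANCHOR[is_purine]
    anchor = nuc.coord(a_from) - nuc.coord(a_to)
    if np.linalg.norm(anchor) < 0.1:
        raise ValueError(f"{nuc!r}: degenerate Y anchor direction")

    ring = np.array([nuc.coord(n) for n in RING_ATOMS[nuc.base_type]])
    normal = fit_plane_normal(ring)
    in_plane = anchor - np.dot(anchor, normal) * normal
    x_dir = unit(ex - sx)
    y_raw = in_plane - np.dot(in_plane, x_dir) * x_dir
    if np.linalg.norm(y_raw) < 1e-6:
        raise ValueError(f"{nuc!r}: Y anchor parallel to X vector")
    y_dir = unit(y_raw)

    nodes = {
        "Sx": sx,
        "Ex": ex,
        "Sy": centroid - Y_HALF_LENGTH * y_dir,
        "Ey": centroid + Y_HALF_LENGTH * y_dir,
    }
    return PseudoatomSet(res_id=nuc.res_id, base_type=nuc.base_type, nodes=nodes)


def base_normal(nuc: Nucleotide) -> np.ndarray:
    """Signed base-plane normal with a consistent per-base orientation
    (right-handed around the glycosidic nitrogen); flips under reflection."""
    if nuc.base_type in PURINES:
        o, p, q = nuc.coord("N9"), nuc.coord("C4"), nuc.coord("C8")
    else:
        o, p, q = nuc.coord("N1"), nuc.coord("C2"), nuc.coord("C6")
    return unit(np.cross(p - o, q - o))


def chirality_sign(nucs, threshold: float = 0.1) -> int:
    """Handedness of a base triple: sign of the scalar triple product of
    the three base normals in the given order. Near-coplanar triples give
    a near-zero product, which is reported as 0 (indeterminate)."""
    n1, n2, n3 = (base_normal(n) for n in nucs)
    v = float(np.dot(n1, np.cross(n2, n3)))
    if abs(v) < threshold:
        return 0
    return 1 if v > 0 else -1


def write_pseudoatom_pdb(psets: list[PseudoatomSet], path: str) -> None:
    """Debug writer: emit pseudoatoms as HETATM pseudo-residues (PSD) so a
    reduced representation can be inspected in a molecular viewer."""
    with open(path, "w") as fh:
        serial = 1
        for i, ps in enumerate(psets, start=1):
            for node in NODE_NAMES:
                x, y, z = ps.nodes[node]
                fh.write(
                    f"HETATM{serial:5d} {node:<4s}PSD A{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {'X':>2s}\n"
                )
                serial += 1
        fh.write("END\n")
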