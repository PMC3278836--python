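"""Geometric hydrogen-bond detection between bases and the triple
admission filter (at least two base-base hydrogen bonds per base).

Crystal structures rarely include hydrogens, so polar hydrogens are
placed at idealized sp2 positions (1.0 Å N-H; amino groups get two
in-plane hydrogens at ±120° from the N-C bond, ring N-H points along the
external bisector of the ring neighbors). A bond requires, at HBPLUS-like
default thresholds: donor-acceptor distance ≤ 3.9 Å, hydrogen-acceptor
distance ≤ 2.5 Å, donor-H-acceptor angle ≥ 90°, and donor/H-acceptor-
antecedent angles ≥ 90°. Only base atoms count: ribose and phosphate
contacts never contribute to the per-base criterion.

Protonated bases (adenine N1, cytosine N3) gain a ring N-H donor; the
triple filter can optionally search protonated variants and accepts one
only where it contributes an otherwise-absent bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (ACCEPTORS, BONDED_NEIGHBORS, DONORS, HBondCriteria,
                     PROTONATED_DONORS)
from .geometry import angle_deg, fit_plane_normal, unit
from .structure_io import Nucleotide, ResId

NH_LENGTH = 1.0  # Å

#: Protonation flags: set of (base-type-specific) donor atoms to protonate.
ProtonationFlags = frozenset[str]


@dataclass(frozen=True)
class HydrogenBond:
    donor: tuple[ResId, str]
    acceptor: tuple[ResId, str]
    d_da: float
    d_ha: float | None          # None in heavy-atom mode
    angle_dha: float | None
    protonated: bool = False

    def involves(self, res_id: ResId) -> bool:
        return self.donor[0] == res_id or self.acceptor[0] == res_id


def h_positions_from_coords(base_type: str, coords, donor: str,
                            protonated: bool = False) -> list[np.ndarray]:
    """Idealized sp2 hydrogen positions for one donor atom, computed from
    a plain name->coordinate mapping (shared with the fixture composer)."""
    from .config import RING_ATOMS

    donors = dict(DONORS[base_type])
    donors.update(PROTONATED_DONORS.get(base_type, {}) if protonated else {})
    if donor not in donors:
        raise ValueError(f"{donor} is not a donor atom of {base_type}")
    n_h = donors[donor]
    ring = np.array([coords[n] for n in RING_ATOMS[base_type]])
    normal = fit_plane_normal(ring)
    d = np.asarray(coords[donor])
    neighbors = [np.asarray(coords[a])
                 for a in BONDED_NEIGHBORS[base_type][donor] if a in coords]
    if len(neighbors) >= 2:
        # ring N-H: external bisector of the two ring neighbors
        bisector = unit(unit(d - neighbors[0]) + unit(d - neighbors[1]))
        bisector = unit(bisector - np.dot(bisector, normal) * normal)
        return [d + NH_LENGTH * bisector]
    # amino group: two in-plane H at ±120° from the N-C bond
    axis = unit(d - neighbors[0])
    axis = unit(axis - np.dot(axis, normal) * normal)
    perp = unit(np.cross(normal, axis))
    hs = []
    for sign in (+1.0, -1.0):
        direction = unit(np.cos(np.radians(60.0)) * axis
                         + sign * np.sin(np.radians(60.0)) * perp)
        hs.append(d + NH_LENGTH * direction)
    return hs[:n_h]


def place_polar_hydrogens(nuc: Nucleotide,
                          protonation: ProtonationFlags = frozenset()
                          ) -> dict[str, list[np.ndarray]]:
    """Idealized polar hydrogen positions, keyed by donor atom name."""
    donors = dict(DONORS[nuc.base_type])
    for atom in protonation:
        extra = PROTONATED_DONORS.get(nuc.base_type, {})
        if atom not in extra:
            raise ValueError(
                f"{nuc.base_type} cannot be protonated at {atom}")
        donors[atom] = extra[atom]
    coords = {name: rec.coords for name, rec in nuc.atoms.items()}
    out: dict[str, list[np.ndarray]] = {}
    for donor in donors:
        if donor not in nuc.atoms:
            raise ValueError(f"{nuc!r}: donor atom {donor} missing")
        out[donor] = h_positions_from_coords(
            nuc.base_type, coords, donor, protonated=donor in protonation)
    return out


def _acceptor_antecedents(nuc: Nucleotide, atom: str) -> list[np.ndarray]:
    return [nuc.coord(a) for a in BONDED_NEIGHBORS[nuc.base_type].get(atom, ())
            if a in nuc.atoms]


def _directed_bonds(donor_nuc: Nucleotide, acceptor_nuc: Nucleotide,
                    criteria: HBondCriteria, mode: str,
                    protonation: ProtonationFlags) -> list[HydrogenBond]:
    bonds = []
    donors = dict(DONORS[donor_nuc.base_type])
    protonated_atoms = set()
    for atom in protonation:
        if atom in PROTONATED_DONORS.get(donor_nuc.base_type, {}):
            donors[atom] = PROTONATED_DONORS[donor_nuc.base_type][atom]
            protonated_atoms.add(atom)
    hydrogens = (place_polar_hydrogens(donor_nuc, frozenset(protonated_atoms))
                 if mode == "explicit-h" else {})
    for donor_atom in donors:
        if donor_atom not in donor_nuc.atoms:
            continue
        d_pos = donor_nuc.coord(donor_atom)
        for acc_atom in ACCEPTORS[acceptor_nuc.base_type]:
            if acc_atom not in acceptor_nuc.atoms:
                continue
            a_pos = acceptor_nuc.coord(acc_atom)
            d_da = float(np.linalg.norm(d_pos - a_pos))
            if d_da > criteria.max_da:
                continue
            antecedents = _acceptor_antecedents(acceptor_nuc, acc_atom)
            if any(angle_deg(d_pos, a_pos, aa) < criteria.min_angle_daaa
                   for aa in antecedents):
                continue
            if mode == "heavy-atom":
                donor_ants = _acceptor_antecedents(donor_nuc, donor_atom)
                if any(angle_deg(dd, d_pos, a_pos) < 90.0 for dd in donor_ants):
                    continue
                bonds.append(HydrogenBond(
                    donor=(donor_nuc.res_id, donor_atom),
                    acceptor=(acceptor_nuc.res_id, acc_atom),
                    d_da=d_da, d_ha=None, angle_dha=None,
                    protonated=donor_atom in protonated_atoms))
                continue
            best = None
            for h_pos in hydrogens.get(donor_atom, ()):
                d_ha = float(np.linalg.norm(h_pos - a_pos))
                if d_ha > criteria.max_ha:
                    continue
                a_dha = angle_deg(d_pos, h_pos, a_pos)
                if a_dha < criteria.min_angle_dha:
                    continue
                if any(angle_deg(h_pos, a_pos, aa) < criteria.min_angle_haaa
                       for aa in antecedents):
                    continue
                if best is None or d_ha < best[0]:
                    best = (d_ha, a_dha)
            if best is not None:
                bonds.append(HydrogenBond(
                    donor=(donor_nuc.res_id, donor_atom),
                    acceptor=(acceptor_nuc.res_id, acc_atom),
                    d_da=d_da, d_ha=best[0], angle_dha=best[1],
                    protonated=donor_atom in protonated_atoms))
    return bonds


def find_base_hbonds(a: Nucleotide, b: Nucleotide,
                     criteria: HBondCriteria | None = None,
                     mode: str = "explicit-h",
                     protonation: dict[ResId, ProtonationFlags] | None = None,
                     ) -> list[HydrogenBond]:
    """All base-base hydrogen bonds between two nucleotides, both
    donor/acceptor directions. ``protonation`` maps residue ids to donor
    atoms to protonate."""
    if a.res_id == b.res_id:
        raise ValueError("cannot hydrogen-bond a nucleotide to itself")
    criteria = criteria or HBondCriteria()
    protonation = protonation or {}
    bonds = _directed_bonds(a, b, criteria, mode,
                            protonation.get(a.res_id, frozenset()))
    bonds += _directed_bonds(b, a, criteria, mode,
                             protonation.get(b.res_id, frozenset()))
    bonds.sort(key=lambda hb: (hb.donor, hb.acceptor))
    return bonds


def triple_hbond_filter(nucs: list[Nucleotide],
                        criteria: HBondCriteria | None = None,
                        mode: str = "explicit-h",
                        protonation_search: bool = False,
                        ) -> tuple[bool, tuple[int, int, int], list[HydrogenBond]]:
    """Admission filter for a candidate triple: every base must make at
    least two hydrogen bonds with the other two bases.

    With ``protonation_search`` the protonated variants (adenine N1+,
    cytosine N3+) are tried per base; a variant is kept only if it adds a
    bond that neutral chemistry cannot, and those bonds carry the
    ``protonated`` flag."""
    if len(nucs) != 3 or len({n.res_id for n in nucs}) != 3:
        raise ValueError("triple filter needs three distinct nucleotides")
    criteria = criteria or HBondCriteria()

    bonds: list[HydrogenBond] = []
    for i in range(3):
        for j in range(i + 1, 3):
            bonds.extend(find_base_hbonds(nucs[i], nucs[j], criteria, mode))

    if protonation_search:
        neutral_keys = {(hb.donor, hb.acceptor) for hb in bonds}
        for nuc in nucs:
            extra = PROTONATED_DONORS.get(nuc.base_type)
            if not extra:
                continue
            for atom in extra:
                flags = {nuc.res_id: frozenset({atom})}
                for other in nucs:
                    if other.res_id == nuc.res_id:
                        continue
                    for hb in find_base_hbonds(nuc, other, criteria, mode,
                                               protonation=flags):
                        if (hb.protonated
                                and (hb.donor, hb.acceptor) not in neutral_keys):
                            bonds.append(hb)
                            neutral_keys.add((hb.donor, hb.acceptor))
        bonds.sort(key=lambda hb: (hb.donor, hb.acceptor))

    counts = tuple(sum(1 for hb in bonds if hb.involves(n.res_id))
                   for n in nucs)
    return all(c >= 2 for c in counts), counts, bonds
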