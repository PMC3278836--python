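"""Synthetic structure generator: idealized planar bases placed at
canonical hydrogen-bonding geometries.

This is the no-download test surface for the whole package. Triples are
composed by rigid in-plane placement of idealized bases so that named
donor-acceptor contacts sit at a target distance (2.9 Å by default, the
ideal N/O hydrogen-bond separation); decoy bases are scattered at random
poses far enough away that planted counts are unambiguous. All
randomness is seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .config import ACCEPTORS, DONORS, EDGE_ATOMS, GLYCOSIDIC_N
from .geometry import dihedral, random_rotation
from .idealized import ideal_coords
from .structure_io import AtomRecord, Nucleotide

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_DISTANCE = 2.9  # Å, idealized donor-acceptor separation

#: Named pair geometries: (base_a, edge_a, base_b, edge_b, orientation)
#: -> list of (atom of a, atom of b) contacts held at the target distance.
PAIR_CONTACTS = {
    ("G", "WC", "C", "WC", "cis"): [("N1", "N3"), ("N2", "O2"), ("O6", "N4")],
    ("A", "WC", "U", "WC", "cis"): [("N1", "N3"), ("N6", "O4")],
    ("A", "WC", "U", "WC", "trans"): [("N1", "N3"), ("N6", "O2")],
    ("A", "H", "U", "WC", "cis"): [("N7", "N3"), ("N6", "O4")],   # Hoogsteen
    ("A", "H", "U", "WC", "trans"): [("N7", "N3"), ("N6", "O2")],
    ("G", "WC", "U", "WC", "cis"): [("N1", "O2"), ("O6", "N3")],  # wobble
    ("A", "WC", "C", "WC", "trans"): [("N1", "N3"), ("N6", "O2")],  # needs A-N1+
    ("A", "H", "C", "WC", "trans"): [("N7", "N4"), ("N6", "N3")],
    ("A", "WC", "G", "S", "trans"): [("N6", "N3"), ("N1", "N2")],  # amino-N3, N3-amino
    ("G", "S", "G", "WC", "trans"): [("N3", "N2"), ("N2", "N3")],
    ("U", "WC", "G", "H", "cis"): [("N3", "N7"), ("O4", "O6")],
}


@dataclass(frozen=True)
class PairingDirective:
    """One placement instruction: bond this base to an already-placed slot."""

    partner: int            # slot index of the placed partner
    own_edge: str           # WC | H | S (edge of the base being placed)
    partner_edge: str
    orientation: str | None = None   # "cis" | "trans" | None (don't care)
    distance: float = DEFAULT_CONTACT_DISTANCE
    contacts: tuple[tuple[str, str], ...] | None = None  # (own, partner) atoms

    def __post_init__(self):
        if not 2.4 <= self.distance <= 3.9:
            raise ValueError(f"target distance {self.distance} outside [2.4, 3.9] Å")
        for edge in (self.own_edge, self.partner_edge):
            if edge not in ("WC", "H", "S"):
                raise ValueError(f"unknown edge {edge!r}")
        if self.orientation not in (None, "cis", "trans"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class PlacementSpec:
    """Base types plus pairing directives; slot 0 is placed at the origin."""

    base_types: list[str]
    directives: dict[int, PairingDirective] = field(default_factory=dict)

    def __post_init__(self):
        for slot, d in self.directives.items():
            if not 0 < slot < len(self.base_types):
                raise ValueError(f"directive for undefined slot {slot}")
            if not 0 <= d.partner < len(self.base_types) or d.partner == slot:
                raise ValueError(f"slot {slot}: bad partner {d.partner}")


def _lookup_contacts(own_base, own_edge, partner_base, partner_edge, orientation):
    """Contact atom pairs for a directive: preset table first, then a
    deterministic donor/acceptor derivation from the edge tables."""
    for orient in ([orientation] if orientation else ["cis", "trans"]):
        key = (own_base, own_edge, partner_base, partner_edge, orient)
        if key in PAIR_CONTACTS:
            return PAIR_CONTACTS[key]
        rkey = (partner_base, partner_edge, own_base, own_edge, orient)
        if rkey in PAIR_CONTACTS:
            return [(b, a) for a, b in PAIR_CONTACTS[rkey]]
    own_edge_atoms = EDGE_ATOMS[own_base][own_edge]
    partner_edge_atoms = EDGE_ATOMS[partner_base][partner_edge]
    candidates = []
    for d in sorted(set(DONORS[own_base]) & own_edge_atoms):
        for a in sorted(set(ACCEPTORS[partner_base]) & partner_edge_atoms):
            candidates.append((d, a))
    for a in sorted(set(ACCEPTORS[own_base]) & own_edge_atoms):
        for d in sorted(set(DONORS[partner_base]) & partner_edge_atoms):
            candidates.append((a, d))
    picked, own_used, partner_used = [], set(), set()
    for own_atom, partner_atom in candidates:
        if own_atom in own_used or partner_atom in partner_used:
            continue
        picked.append((own_atom, partner_atom))
        own_used.add(own_atom)
        partner_used.add(partner_atom)
        if len(picked) == 2:
            break
    if len(picked) < 2:
        raise ValueError(
            f"no hydrogen-bonding contact pair derivable for "
            f"{own_base}({own_edge}) vs {partner_base}({partner_edge})")
    return picked


def _pair_orientation(fixed_atoms, fixed_base, moving_atoms, moving_base) -> str:
    d = dihedral(
        fixed_atoms["C1'"], fixed_atoms[GLYCOSIDIC_N[fixed_base]],
        moving_atoms[GLYCOSIDIC_N[moving_base]], moving_atoms["C1'"],
    )
    return "cis" if abs(d) <= 90.0 else "trans"


def _place_base(moving_base: str, fixed_atoms: dict, fixed_base: str,
                contacts, distance: float, orientation: str | None,
                all_placed_atoms: list[np.ndarray]):
    """Solve the in-plane rigid placement of ``moving_base`` against its
    partner.

    The first two contacts are enforced at the target distance; further
    contacts are soft (a rigid body has only three in-plane degrees of
    freedom, and real multi-bond pairs spread their donor-acceptor
    distances by ~0.1 Å around the ideal value). Both mirror states are
    tried; steric clash and the requested cis/trans orientation select
    among the discrete solutions."""
    from .config import DONORS as _DONORS
    from .config import PROTONATED_DONORS as _PDONORS
    from .geometry import angle_deg
    from .hbond import h_positions_from_coords

    local = ideal_coords(moving_base)
    names = sorted(local)
    targets = np.array([fixed_atoms[fa] for _, fa in contacts])
    partner_cloud = np.array([fixed_atoms[n] for n in sorted(fixed_atoms)])
    n_hard = min(2, len(contacts))
    weights = np.array([1.0] * n_hard + [0.1] * (len(contacts) - n_hard))

    # donor side of each contact (protonated ring nitrogens included, so
    # protonation-dependent fixtures still get linear N-H...A geometry)
    def _is_donor(base, atom):
        return atom in _DONORS[base] or atom in _PDONORS.get(base, {})

    def _donor_side(own_atom, fixed_atom):
        if _is_donor(moving_base, own_atom):
            return "own"
        if _is_donor(fixed_base, fixed_atom):
            return "fixed"
        return None

    donor_sides = [_donor_side(ma, fa) for ma, fa in contacts]

    def coords_for(flip: bool, params):
        tx, ty, theta = params
        pts = np.array([local[n] for n in names])
        if flip:
            pts = pts * np.array([1.0, -1.0, 1.0])
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return pts @ rot.T + np.array([tx, ty, 0.0])

    def residuals(params, flip):
        pts = coords_for(flip, params)
        pos = {n: pts[k] for k, n in enumerate(names)}
        res = [w * (np.linalg.norm(pos[ma] - targets[k]) - distance)
               for k, ((ma, _), w) in enumerate(zip(contacts, weights))]
        # hydrogen-bond linearity: best idealized D-H...A angle near 180°
        for (ma, fa), side in zip(contacts, donor_sides):
            if side == "own":
                d_pos, a_pos = pos[ma], fixed_atoms[fa]
                hs = h_positions_from_coords(moving_base, pos, ma,
                                             protonated=ma not in _DONORS[moving_base])
            elif side == "fixed":
                d_pos, a_pos = fixed_atoms[fa], pos[ma]
                hs = h_positions_from_coords(fixed_base, fixed_atoms, fa,
                                             protonated=fa not in _DONORS[fixed_base])
            else:
                continue
            best = min(180.0 - angle_deg(d_pos, h, a_pos) for h in hs)
            res.append(0.3 * best / 60.0)
        # soft steric repulsion keeps the optimizer out of overlapped minima
        d = np.linalg.norm(pts[:, None, :] - partner_cloud[None, :, :], axis=-1)
        res.extend(0.5 * np.maximum(0.0, 2.6 - d.ravel()))
        return np.asarray(res, dtype=float)

    solutions = []
    fixed_centroid = np.mean(list(fixed_atoms.values()), axis=0)
    outward = targets.mean(axis=0) - fixed_centroid
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    start = targets.mean(axis=0) + 3.0 * outward
    for flip in (False, True):
        for theta0 in np.linspace(0.0, 2 * np.pi, 16, endpoint=False):
            sol = least_squares(
                residuals, x0=[start[0], start[1], theta0], args=(flip,),
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            pts = coords_for(flip, sol.x)
            pos = {n: pts[k] for k, n in enumerate(names)}
            devs = [abs(np.linalg.norm(pos[ma] - targets[k]) - distance)
                    for k, (ma, _) in enumerate(contacts)]
            if max(devs[:n_hard]) > 0.05 or max(devs) > 0.5:
                continue
            clash = _min_cross_distance(pos, fixed_atoms,
                                        {ma for ma, _ in contacts},
                                        {fa for _, fa in contacts})
            for placed in all_placed_atoms:
                d = np.linalg.norm(
                    pts[:, None, :] - placed[None, :, :], axis=-1).min()
                clash = min(clash, d)
            if clash < 2.0:
                continue
            orient = _pair_orientation(fixed_atoms, fixed_base, pos, moving_base)
            if orientation is not None and orient != orientation:
                continue
            solutions.append((max(devs), pos))
    if not solutions:
        raise ValueError(
            f"unsatisfiable placement of {moving_base} against {fixed_base} "
            f"(contacts {contacts}, orientation {orientation})")
    solutions.sort(key=lambda t: t[0])
    return solutions[0][1]


def _min_cross_distance(pos_a, pos_b, exempt_a, exempt_b) -> float:
    best = np.inf
    for na, pa in pos_a.items():
        for nb, pb in pos_b.items():
            if na in exempt_a and nb in exempt_b:
                continue
            best = min(best, float(np.linalg.norm(pa - pb)))
    return best


def _as_nucleotide(base_type: str, atoms: dict[str, np.ndarray],
                   res_id) -> Nucleotide:
    records = {
        name: AtomRecord(name=name, element=name[0], coords=np.asarray(xyz))
        for name, xyz in atoms.items()
    }
    return Nucleotide(res_id=res_id, base_type=base_type, atoms=records)


_COMPOSE_CACHE: dict[str, list] = {}


def compose_triple(spec: PlacementSpec, chain: str = "A",
                   start_res: int = 1) -> list[Nucleotide]:
    """Compose a synthetic multi-base model from a placement spec.

    Slot 0 sits at the idealized reference pose; each further slot is
    rigidly placed against its directive's partner. Directives that put
    two bases on the same edge of one partner are rejected, as are
    placements whose contacts cannot be satisfied without steric clash.
    Placement is deterministic, so repeated composition of the same spec
    is served from a cache (fresh objects each call).
    """
    cache_key = repr((spec.base_types, sorted(spec.directives.items()),
                      chain, start_res))
    if cache_key in _COMPOSE_CACHE:
        placed = _COMPOSE_CACHE[cache_key]
        return [
            _as_nucleotide(bt, {k: v.copy() for k, v in atoms.items()},
                           (chain, start_res + i, ""))
            for i, (bt, atoms) in enumerate(zip(spec.base_types, placed))
        ]
    used_edges = set()
    placed: list[dict[str, np.ndarray]] = []
    for slot, base_type in enumerate(spec.base_types):
        if slot == 0:
            placed.append(ideal_coords(base_type))
            continue
        if slot not in spec.directives:
            raise ValueError(f"slot {slot} has no pairing directive")
        d = spec.directives[slot]
        edge_key = (d.partner, d.partner_edge)
        if edge_key in used_edges:
            raise ValueError(
                f"two bases placed on the {d.partner_edge} edge of slot {d.partner}")
        used_edges.add(edge_key)
        partner_base = spec.base_types[d.partner]
        contacts = d.contacts or _lookup_contacts(
            base_type, d.own_edge, partner_base, d.partner_edge, d.orientation)
        others = [np.array(list(placed[k].values()))
                  for k in range(len(placed)) if k != d.partner]
        pos = _place_base(base_type, placed[d.partner], partner_base,
                          contacts, d.distance, d.orientation, others)
        placed.append(pos)
    _COMPOSE_CACHE[cache_key] = placed
    return [
        _as_nucleotide(bt, {k: v.copy() for k, v in atoms.items()},
                       (chain, start_res + i, ""))
        for i, (bt, atoms) in enumerate(zip(spec.base_types, placed))
    ]


# -- ready-made specs used throughout the test suite and starter library --

def wc_gc_pair() -> PlacementSpec:
    return PlacementSpec(["G", "C"], {1: PairingDirective(0, "WC", "WC", "cis")})


def wc_au_pair() -> PlacementSpec:
    return PlacementSpec(["A", "U"], {1: PairingDirective(0, "WC", "WC", "cis")})


def uau_triple() -> PlacementSpec:
    """U·A·U: Watson-Crick A·U plus a second U on the adenine Hoogsteen edge."""
    return PlacementSpec(
        ["A", "U", "U"],
        {
            1: PairingDirective(0, "WC", "WC", "cis"),
            2: PairingDirective(0, "WC", "H", "cis"),
        },
    )


def gcg_triple() -> PlacementSpec:
    """G·C·G: Watson-Crick G·C with a second G on the guanine sugar edge."""
    return PlacementSpec(
        ["G", "C", "G"],
        {
            1: PairingDirective(0, "WC", "WC", "cis"),
            2: PairingDirective(0, "WC", "S", "trans"),
        },
    )


def agu_triple() -> PlacementSpec:
    """A·G·U: wobble G·U pair plus an adenine on the guanine sugar edge
    (the amino-N3, N3-amino arrangement)."""
    return PlacementSpec(
        ["G", "U", "A"],
        {
            1: PairingDirective(0, "WC", "WC", "cis"),
            2: PairingDirective(0, "WC", "S", "trans"),
        },
    )


def acc_protonated_triple() -> PlacementSpec:
    """A·C·C requiring adenine N1 protonation for the second cytosine:
    one C sits on the adenine Hoogsteen edge (2 neutral bonds), the other
    on its Watson-Crick edge where only N1(+)-H...N3 plus N6-H...O2 are
    possible."""
    return PlacementSpec(
        ["A", "C", "C"],
        {
            1: PairingDirective(0, "WC", "H", "trans"),
            2: PairingDirective(0, "WC", "WC", "trans"),
        },
    )


def displaced_near_miss(spec: PlacementSpec, shift: float = 1.2) -> list[Nucleotide]:
    """Compose a triple, then slide its last base ``shift`` Å in-plane away
    from its partner: a geometric near-miss that still matches patterns at
    moderate tolerance but fails the hydrogen-bond criterion (donor-
    acceptor distances exceed the 3.9 Å ceiling)."""
    from .pseudoatoms import ring_centroid

    m = compose_triple(spec)
    last, partner = m[-1], m[0]
    direction = ring_centroid(last) - ring_centroid(partner)
    direction = direction / np.linalg.norm(direction)
    atoms = {
        n: AtomRecord(name=r.name, element=r.element,
                      coords=r.coords + shift * direction)
        for n, r in last.atoms.items()
    }
    return m[:-1] + [Nucleotide(res_id=last.res_id, base_type=last.base_type,
                                atoms=atoms)]


def perturb(nucs: list[Nucleotide], sigma: float, seed: int) -> list[Nucleotide]:
    """Add i.i.d. Gaussian coordinate noise (std ``sigma`` Å per axis);
    reproducible for a fixed seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for nuc in nucs:
        atoms = {}
        for name, rec in nuc.atoms.items():
            noise = rng.normal(0.0, sigma, size=3) if sigma > 0 else 0.0
            atoms[name] = AtomRecord(name=rec.name, element=rec.element,
                                     coords=rec.coords + noise,
                                     altloc=rec.altloc, occupancy=rec.occupancy)
        out.append(Nucleotide(res_id=nuc.res_id, base_type=nuc.base_type,
                              atoms=atoms))
    return out


def transform(nucs: list[Nucleotide], rotation: np.ndarray,
              translation: np.ndarray) -> list[Nucleotide]:
    """Apply a rigid motion to a model."""
    out = []
    for nuc in nucs:
        atoms = {
            name: AtomRecord(name=rec.name, element=rec.element,
                             coords=rotation @ rec.coords + translation,
                             altloc=rec.altloc, occupancy=rec.occupancy)
            for name, rec in nuc.atoms.items()
        }
        out.append(Nucleotide(res_id=nuc.res_id, base_type=nuc.base_type,
                              atoms=atoms))
    return out


def make_field(planted_specs, n_decoys: int, seed: int,
               box: float = 60.0, min_separation: float = 8.0,
               chain: str = "A") -> list[Nucleotide]:
    """Scatter planted triples (at random rigid poses) and isolated decoy
    bases in a box, keeping every planted group and decoy at least
    ``min_separation`` Å from all other groups so hit counts are
    unambiguous."""
    rng = np.random.default_rng(seed)
    groups: list[list[Nucleotide]] = []
    clouds: list[np.ndarray] = []

    def try_place(model_nucs) -> bool:
        rot = random_rotation(rng)
        trans = rng.uniform(0.0, box, size=3)
        moved = transform(model_nucs, rot, trans)
        cloud = np.concatenate([
            np.array([rec.coords for rec in nuc.atoms.values()])
            for nuc in moved
        ])
        for other in clouds:
            d = np.linalg.norm(cloud[:, None, :] - other[None, :, :], axis=-1)
            if d.min() < min_separation:
                return False
        groups.append(moved)
        clouds.append(cloud)
        return True

    for spec in planted_specs:
        base = compose_triple(spec) if isinstance(spec, PlacementSpec) else spec
        for _ in range(200):
            if try_place(base):
                break
        else:
            raise RuntimeError("could not place planted group without overlap")
    base_choices = np.array(["A", "C", "G", "U"])
    for _ in range(n_decoys):
        bt = str(rng.choice(base_choices))
        decoy = [_as_nucleotide(bt, ideal_coords(bt), (chain, 0, ""))]
        for _ in range(500):
            if try_place(decoy):
                break
        else:
            raise RuntimeError("could not place decoy without overlap")

    nucs = [n for g in groups for n in g]
    return [
        Nucleotide(res_id=(chain, i + 1, ""), base_type=n.base_type, atoms=n.atoms)
        for i, n in enumerate(nucs)
    ]


def write_pdb(nucs: list[Nucleotide], path, pdb_id: str = "SYNT",
              resolution: float | None = 1.5) -> None:
    """Write a model as fixed-column PDB text (synthetic header included)."""
    lines = [f"HEADER    SYNTHETIC RNA FIXTURE                   01-JAN-00   {pdb_id.upper():<4s}"]
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.")
    serial = 1
    for nuc in nucs:
        chain_id, resnum, icode = nuc.res_id
        for name in sorted(nuc.atoms):
            rec = nuc.atoms[name]
            x, y, z = rec.coords
            if max(abs(x), abs(y), abs(z)) > 9999.999:
                raise ValueError("coordinate exceeds PDB fixed-column range")
            pdb_name = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{nuc.base_type:>3s} "
                f"{chain_id[:1]}{resnum:4d}{icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{rec.occupancy:6.2f}{0.0:6.2f}"
                f"          {rec.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
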