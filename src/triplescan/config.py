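"""Configurable chemistry tables and run parameters.

Everything a user might legitimately want to change — modified-residue
aliases, hydrogen-bond criteria, Leontis–Westhof edge membership — lives
here as data, not as constants buried in code. A minimal TOML config file
can override any table.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace

#: Pseudoatom recipe identifier written into pattern files; the matcher
#: refuses to mix patterns and structures built under different recipes.
DEFAULT_CONVENTION = "glyN-centroid-L2.0-v1"

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})
BASE_TYPES = ("A", "C", "G", "U")

#: Ring heavy atoms a nucleotide must carry to be admitted.
RING_ATOMS = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Glycosidic nitrogen per base type.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: Common modified residues mapped onto a parent base; extendable via config.
DEFAULT_MODIFIED_ALIASES = {
    "PSU": "U",  # pseudouridine
    "1MA": "A",
    "5MC": "C",
    "OMG": "G",
    "OMC": "C",
    "OMU": "U",
    "2MG": "G",
    "7MG": "G",
    "M2G": "G",
    "H2U": "U",
    "5MU": "U",
    "4SU": "U",
}

#: Base-edge membership in the Leontis–Westhof scheme (our operationalization;
#: some atoms sit on two edges and are resolved contextually by the classifier).
EDGE_ATOMS = {
    "A": {"WC": {"N1", "N6", "C2"}, "H": {"N7", "N6", "C8"}, "S": {"N3", "C2", "O2'"}},
    "G": {"WC": {"N1", "N2", "O6"}, "H": {"N7", "O6", "C8"}, "S": {"N3", "N2", "O2'"}},
    "C": {"WC": {"N3", "N4", "O2"}, "H": {"C5", "C6", "N4"}, "S": {"O2", "O2'"}},
    "U": {"WC": {"N3", "O4", "O2"}, "H": {"C5", "C6", "O4"}, "S": {"O2", "O2'"}},
}

#: Hydrogen-bond donors per base: atom -> number of polar hydrogens.
DONORS = {
    "A": {"N6": 2},
    "C": {"N4": 2},
    "G": {"N1": 1, "N2": 2},
    "U": {"N3": 1},
}

#: Extra donors available on protonated bases.
PROTONATED_DONORS = {
    "A": {"N1": 1},
    "C": {"N3": 1},
}

#: Hydrogen-bond acceptors per base.
ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "C": ("O2", "N3"),
    "G": ("O6", "N3", "N7"),
    "U": ("O2", "O4"),
}

#: Heavy-atom neighbors of each donor/acceptor, used for idealized hydrogen
#: placement and acceptor-antecedent angle checks.
BONDED_NEIGHBORS = {
    "A": {"N1": ("C2", "C6"), "N3": ("C2", "C4"), "N7": ("C5", "C8"), "N6": ("C6",)},
    "G": {"N1": ("C2", "C6"), "N3": ("C2", "C4"), "N7": ("C5", "C8"),
          "N2": ("C2",), "O6": ("C6",)},
    "C": {"N3": ("C2", "C4"), "O2": ("C2",), "N4": ("C4",)},
    "U": {"N3": ("C2", "C4"), "O2": ("C2",), "O4": ("C4",)},
}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond acceptance thresholds (HBPLUS defaults)."""

    max_da: float = 3.9      # donor–acceptor distance ceiling, Å
    max_ha: float = 2.5      # hydrogen–acceptor distance ceiling, Å
    min_angle_dha: float = 90.0   # donor–H–acceptor, degrees
    min_angle_daaa: float = 90.0  # donor–acceptor–antecedent, degrees
    min_angle_haaa: float = 90.0  # H–acceptor–antecedent, degrees

    def __post_init__(self):
        for name in ("max_da", "max_ha", "min_angle_dha",
                     "min_angle_daaa", "min_angle_haaa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Config:
    """Run-level configuration; defaults reproduce the standard survey setup."""

    resolution_cutoff: float = 3.0
    admit_missing_resolution: bool = False
    modified_aliases: dict = field(default_factory=lambda: dict(DEFAULT_MODIFIED_ALIASES))
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    hbond_mode: str = "explicit-h"  # or "heavy-atom"
    allow_protonation: bool = False
    convention: str = DEFAULT_CONVENTION


def load_config(path: str | None = None) -> Config:
    """Build a Config, optionally overridden from a small TOML file."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "resolution_cutoff" in data:
        cfg.resolution_cutoff = float(data["resolution_cutoff"])
    if "admit_missing_resolution" in data:
        cfg.admit_missing_resolution = bool(data["admit_missing_resolution"])
    if "hbond_mode" in data:
        if data["hbond_mode"] not in ("explicit-h", "heavy-atom"):
            raise ValueError(f"unknown hbond_mode {data['hbond_mode']!r}")
        cfg.hbond_mode = data["hbond_mode"]
    if "allow_protonation" in data:
        cfg.allow_protonation = bool(data["allow_protonation"])
    if "modified_aliases" in data:
        cfg.modified_aliases.update({k.upper(): v.upper()
                                     for k, v in data["modified_aliases"].items()})
    if "hbond" in data:
        cfg.hbond_criteria = replace(cfg.hbond_criteria, **{
            k: float(v) for k, v in data["hbond"].items()
        })
    return cfg
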