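"""Idealized planar base geometries in a standard reference frame.

Coordinates (Å) follow the widely used standard nucleobase reference
frames for fibre-quality base geometry: the base lies in the z = 0 plane
with the Watson-Crick edge facing +x. All base heavy atoms plus C1' are
included; ribose and phosphate are deliberately absent (the survey works
on base-base interactions only).
"""

from __future__ import annotations

import numpy as np

IDEAL_BASES: dict[str, dict[str, np.ndarray]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, 0.000),
        "N3": (-2.342, 2.364, 0.000),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.000),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.000),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000),
        "N3": (-0.302, 2.397, 0.000),
        "C4": (1.000, 2.760, 0.000),
        "O4": (1.934, 1.984, 0.000),
        "C5": (1.089, 4.198, 0.000),
        "C6": (-0.024, 4.962, 0.000),
    },
}

IDEAL_BASES = {
    base: {name: np.asarray(xyz, dtype=float) for name, xyz in atoms.items()}
    for base, atoms in IDEAL_BASES.items()
}


def ideal_coords(base_type: str) -> dict[str, np.ndarray]:
    """Fresh copy of the idealized coordinates for one base type."""
    return {name: xyz.copy() for name, xyz in IDEAL_BASES[base_type].items()}


def nominal_vector_lengths(base_type: str) -> tuple[float, float]:
    """(|X|, |Y|) pseudo-vector lengths implied by the idealized geometry;
    used to sanity-check pattern matrices without coordinates at hand."""
    from .config import GLYCOSIDIC_N, RING_ATOMS
    from .pseudoatoms import Y_HALF_LENGTH

    atoms = IDEAL_BASES[base_type]
    centroid = np.mean([atoms[n] for n in RING_ATOMS[base_type]], axis=0)
    n_gly = atoms[GLYCOSIDIC_N[base_type]]
    return 2.0 * float(np.linalg.norm(centroid - n_gly)), 2.0 * Y_HALF_LENGTH
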