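"""Amino-acid constant tables used by the descriptor families.

Everything here is a published physicochemical classification or scale:
the three-class encodings behind the composition/transition/distribution
(CTD) descriptors, the seven conjoint-triad classes, the Grantham (1974)
composition/polarity/volume table and distance formula, the
hydrophobicity/hydrophilicity/side-chain-mass scales behind pseudo
amino-acid composition, and the six functional residue groups used for
group-count features.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

#: The 20 standard residues, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Residues PSI-BLAST prints PSSM columns in (native order).
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguous / nonstandard one-letter codes rejected during cleaning.
NONSTANDARD = set("BJOUXZ")

# ---------------------------------------------------------------------------
# CTD: seven physicochemical attributes, each splitting the alphabet into
# three classes.  Order and class membership follow the conventional
# descriptor-library parameterization; the short names appear in
# composition-feature names, the positional prop1..prop7 ids in
# transition/distribution names.
# ---------------------------------------------------------------------------

CTD_PROPERTIES: list[tuple[str, tuple[str, str, str]]] = [
    ("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    ("normwaalsvolume", ("GASTPDC", "NVEQIL", "MHKFRYW")),
    ("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    ("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    ("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    ("secondarystruct", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    ("solventaccess", ("ALFCGIVW", "RKQEND", "MSPTHY")),
]

# ---------------------------------------------------------------------------
# Conjoint triad: seven classes by dipole and side-chain volume.
# ---------------------------------------------------------------------------

TRIAD_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

# ---------------------------------------------------------------------------
# Six functional residue groups (plus sequence length elsewhere).
# ---------------------------------------------------------------------------

AA_GROUPS: list[tuple[str, str]] = [
    ("hydrophobic", "VILFMWYC"),
    ("negative", "DE"),
    ("positive", "RKH"),
    ("conformational", "GP"),
    ("polar", "NQS"),
    ("other", "AT"),
]

# ---------------------------------------------------------------------------
# Scales used by PAAC/APAAC and the sequence-order descriptors.
# ---------------------------------------------------------------------------

#: Normalized hydrophobicity (PAAC convention).
HYDROPHOBICITY = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: Hopp–Woods hydrophilicity.
HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

#: Side-chain mass (Da), PAAC convention.
SIDE_CHAIN_MASS = {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0,
    "Q": 72.0, "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0,
    "L": 57.0, "K": 73.0, "M": 75.0, "F": 91.0, "P": 42.0,
    "S": 31.0, "T": 45.0, "W": 130.0, "Y": 107.0, "V": 43.0,
}

#: Kyte–Doolittle hydropathy (used in the sequence-order distance rebuild).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Grantham (1974) composition, polarity, side-chain volume.
GRANTHAM_PROPERTIES = {
    "A": (0.0, 8.1, 31.0), "R": (0.65, 10.5, 124.0), "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0), "C": (2.75, 5.5, 55.0), "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0), "G": (0.74, 9.0, 3.0), "H": (0.58, 10.4, 96.0),
    "I": (0.0, 5.2, 111.0), "L": (0.0, 4.9, 111.0), "K": (0.33, 11.3, 119.0),
    "M": (0.0, 5.7, 105.0), "F": (0.0, 5.2, 132.0), "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0), "T": (0.71, 8.6, 61.0), "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0), "V": (0.0, 5.9, 84.0),
}


def _scale_vector(scale: dict[str, float]) -> np.ndarray:
    return np.array([scale[aa] for aa in ALPHABET], dtype=float)


def standardized_scale(scale: dict[str, float]) -> np.ndarray:
    """Scale values over the alphabet, centred and reduced to unit variance.

    Uses the population standard deviation over the 20 residues, the
    convention of the pseudo amino-acid composition literature.
    """
    v = _scale_vector(scale)
    return (v - v.mean()) / v.std()


def grantham_matrix() -> np.ndarray:
    """20x20 Grantham chemical distance matrix, alphabet order.

    Rebuilt from the published formula
    ``D = rho * [alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2]^0.5``
    with alpha=1.833, beta=0.1018, gamma=0.000399 and rho normalizing the
    mean off-diagonal distance to 100.
    """
    alpha, beta, gamma = 1.833, 0.1018, 0.000399
    d = np.zeros((20, 20))
    for (i, x), (j, y) in itertools.product(enumerate(ALPHABET), repeat=2):
        cx, px, vx = GRANTHAM_PROPERTIES[x]
        cy, py, vy = GRANTHAM_PROPERTIES[y]
        d[i, j] = math.sqrt(
            alpha * (cx - cy) ** 2 + beta * (px - py) ** 2 + gamma * (vx - vy) ** 2
        )
    off = d[~np.eye(20, dtype=bool)]
    return d * (100.0 / off.mean())


def schneider_wrede_matrix() -> np.ndarray:
    """20x20 physicochemical distance matrix, alphabet order.

    Follows the Schneider–Wrede construction — Euclidean distance over
    standardized hydrophobicity, hydrophilicity and side-chain volume —
    rescaled so the largest distance is 1.  Values are rebuilt from the
    underlying scales rather than transcribed.
    """
    h1 = standardized_scale(KYTE_DOOLITTLE)
    h2 = standardized_scale(HYDROPHILICITY)
    vol = standardized_scale({aa: GRANTHAM_PROPERTIES[aa][2] for aa in ALPHABET})
    props = np.stack([h1, h2, vol], axis=1)
    diff = props[:, None, :] - props[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2) / 3.0)
    return d / d.max()


def encode(sequence: str) -> np.ndarray:
    """Integer-encode a cleaned sequence (alphabet order indices)."""
    try:
        return np.array([AA_INDEX[aa] for aa in sequence], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from exc
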