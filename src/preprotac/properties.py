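"""Residue alphabets, physicochemical scales and grouping tables.

Everything downstream (descriptors, mutagenesis) reads its residue-level
constants from here, so a user who wants a different grouping or scale edits
one place. All scales are indexed by the 20 canonical one-letter codes.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np

#: Canonical amino-acid alphabet, alphabetical order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# ---------------------------------------------------------------------------
# Numeric property scales (one value per residue).
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Hopp-Woods hydrophilicity.
HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

#: Grantham polarity.
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5, "E": 12.3,
    "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2,
    "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

#: Grantham side-chain volume.
VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}

#: Average side-chain mass (residue mass minus the glycine backbone), Da.
SIDE_CHAIN_MASS = {
    "A": 15.0, "R": 101.1, "N": 58.0, "D": 59.0, "C": 47.1, "Q": 72.1,
    "E": 73.1, "G": 1.0, "H": 81.1, "I": 57.1, "L": 57.1, "K": 72.1,
    "M": 75.1, "F": 91.1, "P": 41.1, "S": 31.0, "T": 45.0, "W": 130.2,
    "Y": 107.1, "V": 43.1,
}

#: Isoelectric point of the free amino acid.
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}

#: Net side-chain charge at physiological pH (His partially protonated).
NET_CHARGE = {
    "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0, "E": -1.0,
    "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0, "M": 0.0, "F": 0.0,
    "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0, "Y": 0.0, "V": 0.0,
}

#: Chothia accessible surface area of residue X in a Gly-X-Gly tripeptide, A^2.
SURFACE_AREA = {
    "A": 115.0, "R": 225.0, "N": 160.0, "D": 150.0, "C": 135.0, "Q": 180.0,
    "E": 190.0, "G": 75.0, "H": 195.0, "I": 175.0, "L": 170.0, "K": 200.0,
    "M": 185.0, "F": 210.0, "P": 145.0, "S": 115.0, "T": 140.0, "W": 255.0,
    "Y": 230.0, "V": 155.0,
}

#: Default scales for Geary autocorrelation (name -> scale), nlag pairs with
#: :data:`preprotac.config` defaults. Each scale is z-standardized over the
#: 20 residues before the autocorrelation is computed.
GEARY_SCALES: dict[str, dict[str, float]] = {
    "hydropathy": HYDROPATHY,
    "hydrophilicity": HYDROPHILICITY,
    "polarity": POLARITY,
    "volume": VOLUME,
    "side_chain_mass": SIDE_CHAIN_MASS,
    "isoelectric_point": ISOELECTRIC_POINT,
    "net_charge": NET_CHARGE,
    "surface_area": SURFACE_AREA,
}

# ---------------------------------------------------------------------------
# Grouping tables.
# ---------------------------------------------------------------------------

#: Five physicochemical groups for grouped tripeptide composition.
GTPC_GROUPS: dict[str, str] = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged_polar": "STCPNQ",
}

#: Seven conjoint-triad classes (side-chain volume and dipole clustering).
CTRIAD_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

#: Seven attributes x three classes used by the distribution descriptor.
#: Class order within each attribute is fixed and part of the feature naming.
CTD_ATTRIBUTES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

#: Opposite-property substitution table for in-silico mutational scanning:
#: positive -> negative, negative -> positive, polar -> hydrophobic,
#: hydrophobic/aromatic -> polar. Total over the alphabet, never the identity,
#: and an involution on the charge pairs (K<->E, D<->K via K->E).
OPPOSITE_RESIDUE: dict[str, str] = {
    "K": "E", "R": "E", "H": "D",            # positive -> negative
    "D": "K", "E": "K",                      # negative -> positive
    "S": "L", "T": "L", "N": "L", "Q": "L",  # polar -> hydrophobic
    "Y": "F", "C": "A",
    "A": "S", "V": "S", "L": "S", "I": "S", "M": "S",  # hydrophobic -> polar
    "F": "Y", "W": "Y",
    "P": "G", "G": "P",
}


def load_distance_matrix(path: str | Path | None = None) -> np.ndarray:
    """Load a 20x20 residue physicochemical distance matrix.

    The file format is plain TSV: a header row with the 20 one-letter codes,
    then 20 rows of ``letter<TAB>d1..d20``. Row/column order may be any
    permutation of the alphabet; the returned matrix is re-indexed to
    :data:`AMINO_ACIDS` order.

    With ``path=None`` the bundled default is used. That default is a
    *synthetic* matrix (see ``data/qso_distance_synthetic.tsv``): Euclidean
    distance over five z-standardized property scales (hydropathy,
    hydrophilicity, polarity, volume, side-chain mass), rescaled to max 1.
    It stands in for published amino-acid distance matrices whose numeric
    tables are not bundled; users reproducing a specific published
    quasi-sequence-order variant should pass their own matrix file.
    """
    if path is None:
        ref = importlib.resources.files("preprotac") / "data" / "qso_distance_synthetic.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    cols = header[1:] if header[0] in ("", "aa") else header
    if sorted(cols) != sorted(AMINO_ACIDS):
        raise ValueError("distance matrix header must contain the 20 canonical residues")
    mat = np.zeros((20, 20))
    seen = set()
    for ln in lines[1:]:
        parts = ln.split("\t")
        aa = parts[0]
        if aa not in AA_SET or aa in seen:
            raise ValueError(f"bad or duplicate row label {aa!r} in distance matrix")
        seen.add(aa)
        vals = [float(v) for v in parts[1:]]
        if len(vals) != 20:
            raise ValueError(f"row {aa!r} has {len(vals)} values, expected 20")
        for col, v in zip(cols, vals):
            mat[AA_INDEX[aa], AA_INDEX[col]] = v
    if seen != AA_SET:
        raise ValueError("distance matrix is missing residue rows")
    return mat


def build_synthetic_distance_matrix() -> np.ndarray:
    """Construct the synthetic residue distance matrix shipped as the default.

    Five property scales are z-standardized over the 20 residues; the distance
    between two residues is the Euclidean distance of their property vectors,
    divided by the largest pairwise distance so values lie in [0, 1].
    """
    scales = [HYDROPATHY, HYDROPHILICITY, POLARITY, VOLUME, SIDE_CHAIN_MASS]
    prop = np.array([[s[aa] for s in scales] for aa in AMINO_ACIDS])
    prop = (prop - prop.mean(axis=0)) / prop.std(axis=0)
    diff = prop[:, None, :] - prop[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return dist / dist.max()
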