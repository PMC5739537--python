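"""Residue-contact pair potentials.

Binding disruption and the default stability proxy are scored with a
symmetric 20x20 residue-contact potential (lower = more favourable contact).
The potential is pluggable: any complete whitespace-delimited 20x20 matrix
with a one-letter amino-acid header row and column can be loaded, so a user
may substitute their preferred statistical potential.

The default matrix is a quasichemical-style construction from two published
scales: an additive transfer-free-energy term from the Kyte-Doolittle
hydropathy scale (hydrophobic-hydrophobic contacts are favourable) plus an
electrostatic complementarity term from unit side-chain charges (opposite
charges attract, like charges repel).  Statistical contact potentials are
known to be dominated by exactly such an additive hydrophobicity component.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Kyte-Doolittle hydropathy (positive = hydrophobic).
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Nominal side-chain charges at neutral pH.
CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}


class PairPotential:
    """Symmetric amino-acid contact potential (arbitrary energy units)."""

    def __init__(self, matrix: np.ndarray, name: str = "custom"):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (20, 20):
            raise ValueError("pair potential must be 20x20")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("pair potential must be symmetric")
        if not np.isfinite(matrix).all():
            raise ValueError("pair potential must be finite")
        self.matrix = matrix
        self.name = name

    def __call__(self, a: str, b: str) -> float:
        return float(self.matrix[_AA_INDEX[a], _AA_INDEX[b]])

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("  " + " ".join(AMINO_ACIDS) + "\n")
            for i, aa in enumerate(AMINO_ACIDS):
                fh.write(aa + " " + " ".join(f"{v:.4f}" for v in self.matrix[i]) + "\n")


def default_potential(hydro_weight: float = 0.5,
                      charge_weight: float = 0.6) -> PairPotential:
    """The hydropathy+charge contact potential described in the module docs.

    ``e(a, b) = -hydro_weight * (h_a + h_b) + charge_weight * q_a * q_b``
    """
    h = np.array([KD_HYDROPATHY[a] for a in AMINO_ACIDS])
    q = np.array([CHARGE.get(a, 0.0) for a in AMINO_ACIDS])
    m = -hydro_weight * (h[:, None] + h[None, :]) + charge_weight * q[:, None] * q[None, :]
    return PairPotential(m, name="hydropathy-charge")


def load_potential(path: str | Path, name: str | None = None) -> PairPotential:
    """Load a whitespace-delimited 20x20 matrix with AA header row/column."""
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = [t.upper() for t in lines[0]]
    if len(header) != 20 or set(header) != set(AMINO_ACIDS):
        raise ValueError("header must list the 20 standard amino acids")
    order = [_AA_INDEX[a] for a in header]
    m = np.full((20, 20), np.nan)
    for row in lines[1:]:
        i = _AA_INDEX[row[0].upper()]
        vals = np.array([float(v) for v in row[1:]])
        if len(vals) != 20:
            raise ValueError(f"row {row[0]}: expected 20 values")
        m[i, order] = vals
    if np.isnan(m).any():
        raise ValueError("matrix incomplete")
    return PairPotential(m, name=name or Path(path).stem)
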