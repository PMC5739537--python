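"""Structure I/O, solvent accessibility and geometric primitives.

Antigen and antibody structures are held in a light-weight container keyed by
author residue numbering, so that mutation labels such as ``M154E`` match the
conventions used in mutagenesis work.  Only heavy atoms are kept: crystal
structures rarely resolve hydrogens and every distance criterion in this
package (contact footprints, interface epitopes) is defined on heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is treated as methionine
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

#: van der Waals radii (A) used for solvent-accessible surface computation.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Theoretical maximal accessible surface areas (A^2) per amino acid
#: (Gly-X-Gly based theoretical values, Tien et al. 2013), used to turn
#: absolute SASA into relative solvent accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


class ResidueKey(NamedTuple):
    """Identifies one residue by chain, author number and insertion code."""

    chain: str
    number: int
    icode: str = ""

    def label(self) -> str:
        return f"{self.chain}:{self.number}{self.icode}"

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        chain, _, rest = text.strip().partition(":")
        num = rest.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        return cls(chain, int(num), rest[len(num):])


@dataclass
class Residue:
    """One residue: amino-acid code plus its heavy atoms."""

    aa: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) float64, Angstrom

    def atom(self, name: str) -> np.ndarray | None:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            return None


class Structure:
    """Ordered map of :class:`ResidueKey` to :class:`Residue`.

    Residues keep author (PDB) numbering verbatim.  Flattened coordinate
    arrays are cached for fast neighbour searches.
    """

    def __init__(self, residues: Mapping[ResidueKey, Residue], name: str = ""):
        if not residues:
            raise ValueError("a Structure needs at least one residue")
        self.residues: dict[ResidueKey, Residue] = dict(residues)
        self.name = name
        self.missing_backbone: list[ResidueKey] = []
        self._flat: tuple[np.ndarray, np.ndarray] | None = None
        for key, res in self.residues.items():
            if res.coords.size == 0 or not np.isfinite(res.coords).all():
                raise ValueError(f"residue {key.label()} has no finite heavy atoms")

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.residues

    def keys(self) -> list[ResidueKey]:
        return list(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues.values())

    def flat_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and the residue index of each atom."""
        if self._flat is None:
            coords = np.concatenate([r.coords for r in self.residues.values()])
            idx = np.concatenate([
                np.full(len(r.coords), i)
                for i, r in enumerate(self.residues.values())
            ]).astype(int)
            self._flat = (coords, idx)
        return self._flat

    def ca(self, key: ResidueKey) -> np.ndarray:
        xyz = self.residues[key].atom("CA")
        if xyz is None:
            raise ValueError(f"residue {key.label()} has no CA atom")
        return xyz

    def subset(self, keys: Iterable[ResidueKey]) -> "Structure":
        keys = list(keys)
        missing = [k for k in keys if k not in self.residues]
        if missing:
            raise KeyError(f"residues not in structure: {missing}")
        return Structure({k: self.residues[k] for k in keys}, name=self.name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy (used by tests and the synthetic generator)."""
        out = {}
        for key, res in self.residues.items():
            out[key] = Residue(res.aa, list(res.atom_names), list(res.elements),
                               res.coords @ rotation.T + translation)
        s = Structure(out, name=self.name)
        s.missing_backbone = list(self.missing_backbone)
        return s


@dataclass
class AccessibilityMap:
    """Relative solvent accessibility per residue.

    ``rsa`` is absolute SASA divided by the per-amino-acid reference maximum,
    so values usually fall in [0, ~1.2].  Residue types without a reference
    area are flagged and carry ``nan`` (they never count as surface).
    """

    rsa: dict[ResidueKey, float]
    flagged: list[ResidueKey] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O


def _select_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy wins, ties by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path: str | Path, chain: str | Sequence[str] | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Hydrogens, waters and hetero groups are dropped (selenomethionine is kept
    and treated as methionine); alternate locations resolve to the highest
    occupancy.  ``chain`` restricts to one chain id or a sequence of them.
    Residues missing backbone atoms (N, CA, C) are reported via logging and
    listed in ``Structure.missing_backbone``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    wanted = None
    if chain is not None:
        wanted = [chain] if isinstance(chain, str) else list(chain)
    residues: dict[ResidueKey, Residue] = {}
    missing: list[ResidueKey] = []
    model = st[0]
    seen_chains = []
    for ch in model:
        seen_chains.append(ch.name)
        if wanted is not None and ch.name not in wanted:
            continue
        for res in ch:
            if res.is_water():
                continue
            if res.het_flag == "H" and res.name != "MSE":
                continue
            aa = THREE_TO_ONE.get(res.name, "X")
            names, elems, xyz = [], [], []
            for atom in _select_altloc(res):
                if atom.element.name in ("H", "D"):
                    continue
                names.append(atom.name)
                elems.append(atom.element.name.upper())
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if not xyz:
                continue
            key = ResidueKey(ch.name, res.seqid.num, (res.seqid.icode or " ").strip())
            residues[key] = Residue(aa, names, elems, np.asarray(xyz, dtype=float))
            if not {"N", "CA", "C"}.issubset(names):
                missing.append(key)
    if wanted is not None and not residues:
        raise ValueError(f"{path}: chain(s) {wanted} not found or empty "
                         f"(available: {sorted(set(seen_chains))})")
    if not residues:
        raise ValueError(f"{path}: no heavy atoms after filtering")
    s = Structure(residues, name=path.stem)
    s.missing_backbone = missing
    if missing:
        log.warning("%s: %d residue(s) missing backbone atoms: %s", path.name,
                    len(missing), ", ".join(k.label() for k in missing[:10]))
    return s


def write_pdb(path: str | Path, *structures: Structure) -> None:
    """Write structures (e.g. an antigen and an antibody pose) to one PDB file."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    model = gemmi.Model("1")
    for s in structures:
        chains: dict[str, gemmi.Chain] = {}
        for key, res in s.residues.items():
            ch = chains.setdefault(key.chain, gemmi.Chain(key.chain))
            gres = gemmi.Residue()
            gres.name = ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(key.number, key.icode or " ")
            for name, elem, xyz in zip(res.atom_names, res.elements, res.coords):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(elem)
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            ch.add_residue(gres)
        for ch in chains.values():
            model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere sampling.

    Each atom is inflated by the probe radius and covered with ``n_points``
    evenly spread test points; the accessible fraction times the sphere area
    gives the atom's SASA.  Deterministic for a fixed point count.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    out = np.empty(len(coords))
    for i, (c, r) in enumerate(zip(coords, radii)):
        test = c + pts * r
        nbrs = [j for j in tree.query_ball_point(c, r + rmax) if j != i]
        if nbrs:
            d2 = ((test[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (radii[nbrs] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * r * r
    return out


def relative_accessibility(s: Structure, probe: float = 1.4,
                           n_points: int = 960) -> AccessibilityMap:
    """Relative solvent accessibility for every residue of ``s``."""
    coords, res_idx = s.flat_coords()
    elements = np.concatenate([[e for e in r.elements] for r in s.residues.values()])
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements])
    atom_sasa = shrake_rupley_sasa(coords, radii, probe=probe, n_points=n_points)
    rsa: dict[ResidueKey, float] = {}
    flagged: list[ResidueKey] = []
    for i, (key, res) in enumerate(s.residues.items()):
        total = float(atom_sasa[res_idx == i].sum())
        ref = MAX_ASA.get(res.aa)
        if ref is None:
            flagged.append(key)
            rsa[key] = float("nan")
        else:
            rsa[key] = total / ref
    if flagged:
        log.warning("no reference area for %d residue(s); excluded from surface",
                    len(flagged))
    return AccessibilityMap(rsa=rsa, flagged=flagged)


def surface_residues(a: AccessibilityMap, threshold: float = 0.07) -> set[ResidueKey]:
    """Residues with relative accessibility strictly above ``threshold``.

    The default 7% cut is the conventional definition of 'surface' used when
    restricting candidate mutation sites.
    """
    return {k for k, v in a.rsa.items() if v == v and v > threshold}


# ---------------------------------------------------------------------------
# Contacts and geometry


def heavy_atom_contacts(a: Structure, b: Structure,
                        cutoff: float = 5.0) -> set[tuple[ResidueKey, ResidueKey]]:
    """Residue pairs (one from ``a``, one from ``b``) with any heavy-atom pair
    within ``cutoff`` Angstrom.  Selections must be disjoint."""
    overlap = set(a.residues) & set(b.residues)
    if overlap:
        raise ValueError(f"overlapping selections: {sorted(overlap)[:5]}")
    ca_, ia = a.flat_coords()
    cb_, ib = b.flat_coords()
    keys_a, keys_b = a.keys(), b.keys()
    tree = cKDTree(cb_)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    for hits, ra in zip(tree.query_ball_point(ca_, cutoff), ia):
        for j in hits:
            pairs.add((keys_a[ra], keys_b[ib[j]]))
    return pairs


def mean_pairwise_ca_distance(s: Structure, positions: Iterable[ResidueKey]) -> float:
    """Mean CA-CA Euclidean distance over unordered position pairs.

    A single position has spread 0 by convention; this is the 'spread' used
    to keep the mutations of one variant spatially coherent.
    """
    positions = sorted(set(positions))
    if not positions:
        raise ValueError("need at least one position")
    cas = np.array([s.ca(k) for k in positions])
    if len(cas) == 1:
        return 0.0
    return float(pdist(cas).mean())
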