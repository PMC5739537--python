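"""Shared fixtures: hand-built PDB text, toy structures and small scenarios."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from episcope.structures import Residue, ResidueKey, Structure
from episcope.synthetic import make_scenario

logging.getLogger("episcope").setLevel(logging.ERROR)


def atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
              xyz, element: str, occ: float = 1.0, altloc: str = " ",
              icode: str = " ", record: str = "ATOM") -> str:
    """One fixed-width PDB ATOM/HETATM record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (f"{record:<6s}{serial:5d} {name_field}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")


def single_atom_structure(spec, chain_default="A") -> Structure:
    """Structure from [(chain, number, aa, xyz), ...], one CA atom each."""
    residues = {}
    for item in spec:
        chain, number, aa, xyz = item
        residues[ResidueKey(chain, number)] = Residue(
            aa=aa, atom_names=["CA"], elements=["C"],
            coords=np.asarray([xyz], dtype=float))
    return Structure(residues)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact localization scenario shared by read-only tests."""
    return make_scenario(n_res=40, n_models=6, footprint_size=6,
                         msa_depth=6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
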