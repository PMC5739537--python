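"""Docking-ensemble ingestion, footprints and model-quality metrics.

A docking ensemble is an unweighted, unranked list of rigid antibody poses
against one fixed antigen.  Each pose defines a *footprint*: the antigen
residues with a heavy atom within a contact cutoff (default 5 A) of any
antibody heavy atom.  Footprints are the unit of everything downstream —
candidate mutation sites, coverage accounting and model filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import ResidueKey, Structure, heavy_atom_contacts, read_structure

DEFAULT_CONTACT_CUTOFF = 5.0


def footprint(ab: Structure, ag: Structure,
              cutoff: float = DEFAULT_CONTACT_CUTOFF) -> set[ResidueKey]:
    """Antigen residues with >=1 heavy atom within ``cutoff`` of the antibody."""
    ag_coords, ag_idx = ag.flat_coords()
    ab_coords, _ = ab.flat_coords()
    keys = ag.keys()
    tree = cKDTree(ab_coords)
    hits = tree.query_ball_point(ag_coords, cutoff)
    return {keys[ag_idx[i]] for i, h in enumerate(hits) if h}


@dataclass
class DockingModel:
    """One antibody pose against the shared antigen."""

    id: str
    ab: Structure
    ag: Structure
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    _footprint: set[ResidueKey] | None = field(default=None, repr=False)

    @property
    def footprint(self) -> set[ResidueKey]:
        if self._footprint is None:
            self._footprint = footprint(self.ab, self.ag, self.cutoff)
        return self._footprint

    def footprint_at(self, cutoff: float) -> set[ResidueKey]:
        return footprint(self.ab, self.ag, cutoff)


@dataclass
class DockingEnsemble:
    """Ordered docking models sharing one antigen."""

    models: list[DockingModel]
    antigen: Structure
    source_label: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValueError("an ensemble needs at least one model")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def model(self, model_id: str) -> DockingModel:
        for m in self.models:
            if m.id == model_id:
                return m
        raise KeyError(model_id)

    def footprints(self) -> dict[str, set[ResidueKey]]:
        return {m.id: m.footprint for m in self.models}


def _same_antigen(a: Structure, b: Structure, tol: float = 1e-3) -> bool:
    if list(a.residues) != list(b.residues) or a.sequence != b.sequence:
        return False
    ca_, _ = a.flat_coords()
    cb_, _ = b.flat_coords()
    return ca_.shape == cb_.shape and float(np.abs(ca_ - cb_).max()) <= tol


def load_ensemble(directory: str | Path, ag_chain: str,
                  ab_chains: str | Sequence[str],
                  cutoff: float = DEFAULT_CONTACT_CUTOFF,
                  source_label: str = "") -> DockingEnsemble:
    """Load a directory of pose PDB files (antigen + antibody per file).

    Files are ordered by name; the antigen must be coordinate-identical
    (within 1e-3 A) across poses.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.glob("*.pdb")) + \
        sorted(p for p in directory.glob("*.cif"))
    if not files:
        raise ValueError(f"no pose files in {directory}")
    antigen: Structure | None = None
    models: list[DockingModel] = []
    for path in files:
        ag = read_structure(path, chain=ag_chain)
        ab = read_structure(path, chain=ab_chains)
        if antigen is None:
            antigen = ag
        elif not _same_antigen(antigen, ag):
            raise ValueError(f"{path.name}: antigen coordinates differ from "
                             f"{files[0].name} (must be identical across poses)")
        models.append(DockingModel(id=path.stem, ab=ab, ag=antigen, cutoff=cutoff))
    return DockingEnsemble(models=models, antigen=antigen,
                           source_label=source_label or directory.name)


def surface_coverage(e: DockingEnsemble, surface: set[ResidueKey]) -> float:
    """Fraction of the surface touched by the union of all footprints."""
    if not surface:
        raise ValueError("surface set is empty")
    union: set[ResidueKey] = set()
    for m in e.models:
        union |= m.footprint
    return len(union & surface) / len(surface)


def fnat(m: DockingModel, reference_ag: Structure, reference_ab: Structure,
         cutoff: float = DEFAULT_CONTACT_CUTOFF) -> float:
    """Fraction of native interface residue contacts reproduced by a model.

    The native contacts are the heavy-atom residue pairs (<= ``cutoff``) of a
    reference complex sharing the antigen residue numbering; 1.0 means every
    native contact pair is present in the model.
    """
    native = heavy_atom_contacts(reference_ag, reference_ab, cutoff)
    if not native:
        raise ValueError("reference complex has no interface contacts")
    found = heavy_atom_contacts(m.ag, m.ab, cutoff)
    return len(native & found) / len(native)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def ensemble_overlap(a: DockingEnsemble, b: DockingEnsemble,
                     min_jaccard: float = 0.25) -> float:
    """Fraction of ``a``'s models whose footprint matches some model of ``b``.

    Two footprints 'match' when their Jaccard index reaches ``min_jaccard``.
    This is a proxy measure for dock-overlap heat maps; the threshold is a
    reporting choice and is configurable.
    """
    b_fp = [m.footprint for m in b.models]
    hit = sum(1 for m in a.models
              if any(_jaccard(m.footprint, fp) >= min_jaccard for fp in b_fp))
    return hit / len(a.models)


def overlap_matrix(ensembles: dict[str, DockingEnsemble],
                   min_jaccard: float = 0.25):
    """Pairwise dock-overlap matrix over antibody labels (rows: fraction of
    the row antibody's models matched by the column antibody's)."""
    import pandas as pd

    labels = list(ensembles)
    m = np.zeros((len(labels), len(labels)))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            m[i, j] = ensemble_overlap(ensembles[la], ensembles[lb], min_jaccard)
    return pd.DataFrame(m, index=labels, columns=labels)


def write_footprints_tsv(e: DockingEnsemble, path: str | Path) -> None:
    """TSV of per-model footprints: model id, comma-separated residue labels."""
    with open(path, "w") as fh:
        fh.write("model_id\tn_residues\tfootprint\n")
        for m in e.models:
            labels = ",".join(k.label() for k in sorted(m.footprint))
            fh.write(f"{m.id}\t{len(m.footprint)}\t{labels}\n")


def write_metrics_json(metrics: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
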