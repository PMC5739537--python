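"""Synthetic antigens, docking ensembles and homolog alignments.

Every stage of the pipeline is testable without downloads via toy scenarios:
a convex pseudo-antigen whose residues (N, CA, C, O, CB pseudo-atoms, random
sequence) sit on a spherical lattice, rigid antibody 'pseudo-bodies' (~50
atom clouds) hovering 4-5 A above chosen surface patches, and a synthetic
homolog alignment offering substitutions at a controlled rate.  One pose can
be flagged as the *true* binding mode, in which case the ground-truth
epitope is exactly that pose's footprint — the construction behind the
guaranteed-success property exercised by the test suite.

The pseudo-paratope contact atoms all belong to tyrosine pseudo-residues:
tyrosine dominates real paratope contacts, and a fixed identity keeps the
pseudo-antibody neutral so the scenarios probe the antigen-side geometry
rather than accidental paratope composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .docking import DockingEnsemble, DockingModel, footprint
from .evaluation import EpitopeSpec
from .potentials import AMINO_ACIDS
from .structures import Residue, ResidueKey, Structure, write_pdb

_SPACING = 6.0  # target CA-CA lattice spacing, A


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _tangents(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(u, t1)


def make_toy_antigen(n_res: int, seed: int, chain: str = "A") -> Structure:
    """Spherical-lattice pseudo-antigen with backbone+CB pseudo-atoms.

    All residues are fully solvent exposed (the lattice is convex), so the
    whole chain is 'surface' under the 7% accessibility rule.
    """
    if n_res < 20:
        raise ValueError("n_res must be >= 20")
    rng = np.random.default_rng(seed)
    radius = _SPACING * np.sqrt(n_res / (4.0 * np.pi))
    dirs = _fibonacci_directions(n_res)
    seq = rng.choice(list(AMINO_ACIDS), size=n_res)
    residues: dict[ResidueKey, Residue] = {}
    for i, u in enumerate(dirs):
        ca = u * radius
        t1, t2 = _tangents(u)
        coords = np.array([
            ca + 1.46 * t1,                 # N
            ca,                             # CA
            ca - 1.02 * t1 + 1.09 * t2,     # C
            ca - 1.06 * t1 + 2.30 * t2,     # O
            ca + 1.53 * u,                  # CB
        ])
        residues[ResidueKey(chain, i + 1)] = Residue(
            aa=str(seq[i]), atom_names=["N", "CA", "C", "O", "CB"],
            elements=["N", "C", "C", "O", "C"], coords=coords)
    s = Structure(residues, name=f"toy{n_res}")
    return s


def _patch(antigen: Structure, center: ResidueKey, size: int) -> list[ResidueKey]:
    keys = antigen.keys()
    cas = np.array([antigen.ca(k) for k in keys])
    d = np.linalg.norm(cas - antigen.ca(center), axis=1)
    return [keys[i] for i in np.argsort(d, kind="stable")[:size]]


def make_pseudo_antibody(antigen: Structure, patch: list[ResidueKey],
                         pose_id: int, n_atoms: int = 50,
                         standoff: float = 4.3, chain: str = "H") -> Structure:
    """Rigid tyrosine atom cloud touching exactly the given surface patch.

    One contact atom hovers ``standoff`` A radially above each patch
    residue's CB (inside the 5 A contact cutoff); the remaining atoms pad
    the cloud 8-12 A out, beyond contact range of any antigen residue.
    """
    residues: dict[ResidueKey, Residue] = {}
    num = 1
    for key in patch:
        cb = antigen.residues[key].atom("CB")
        u = cb / np.linalg.norm(cb)
        residues[ResidueKey(chain, num)] = Residue(
            aa="Y", atom_names=["CA"], elements=["C"],
            coords=(cb + standoff * u)[None, :])
        num += 1
    centroid = np.mean([antigen.residues[k].atom("CB") for k in patch], axis=0)
    u = centroid / np.linalg.norm(centroid)
    t1, t2 = _tangents(u)
    filler = max(0, n_atoms - len(patch))
    for j in range(filler):
        # deterministic spiral of padding atoms, 8-12 A above the patch
        r = 8.0 + 4.0 * (j / max(1, filler - 1)) if filler > 1 else 9.0
        ang = 2.399963 * j  # golden angle
        off = 1.8 * (np.cos(ang) * t1 + np.sin(ang) * t2)
        residues[ResidueKey(chain, num)] = Residue(
            aa="Y", atom_names=["CA"], elements=["C"],
            coords=(centroid + r * u + off)[None, :])
        num += 1
    return Structure(residues, name=f"pose_{pose_id:03d}")


def _make_msa(antigen: Structure, depth: int, sub_rate: float,
              rng: np.random.Generator, min_covered: float = 0.8) -> list[tuple[str, str]]:
    """Synthetic homolog alignment (no gaps) over the antigen sequence.

    Each homolog substitutes each column with probability ``sub_rate``; the
    alignment is then patched so that at least ``min_covered`` of positions
    offer one or more substitutions, matching the generator's contract that
    most surface positions are designable.
    """
    wt = list(antigen.sequence)
    n = len(wt)
    rows = []
    aa = np.array(list(AMINO_ACIDS))
    for h in range(depth):
        row = list(wt)
        flips = rng.random(n) < sub_rate
        for i in np.flatnonzero(flips):
            choices = [a for a in AMINO_ACIDS if a != wt[i]]
            row[i] = choices[rng.integers(len(choices))]
        rows.append(row)
    covered = [any(rows[h][i] != wt[i] for h in range(depth)) for i in range(n)]
    deficit = int(np.ceil(min_covered * n)) - sum(covered)
    if deficit > 0:
        for i in [j for j in range(n) if not covered[j]][:deficit]:
            choices = [a for a in AMINO_ACIDS if a != wt[i]]
            rows[i % depth][i] = choices[rng.integers(len(choices))]
    out = [("antigen", "".join(wt))]
    out += [(f"homolog_{h + 1}", "".join(rows[h])) for h in range(depth)]
    return out


@dataclass
class SyntheticScenario:
    """A fully synthetic localization problem with known ground truth."""

    antigen: Structure
    ensemble: DockingEnsemble
    msa: list[tuple[str, str]]
    true_model_id: str | None
    epitope: EpitopeSpec | None
    seed: int
    params: dict = field(default_factory=dict)

    def write_files(self, directory: str | Path) -> dict[str, Path]:
        """Serialize to PDB/FASTA/text files (for the CLI and round-trips)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ag_path = directory / "antigen.pdb"
        write_pdb(ag_path, self.antigen)
        poses = directory / "poses"
        poses.mkdir(exist_ok=True)
        for m in self.ensemble.models:
            write_pdb(poses / f"{m.id}.pdb", self.antigen, m.ab)
        msa_path = directory / "homologs.fasta"
        with open(msa_path, "w") as fh:
            for name, seq in self.msa:
                fh.write(f">{name}\n{seq}\n")
        out = {"antigen": ag_path, "poses": poses, "msa": msa_path}
        if self.epitope is not None:
            epi_path = directory / "epitope.txt"
            epi_path.write_text("".join(f"{k.label()}\n"
                                        for k in sorted(self.epitope.residues)))
            out["epitope"] = epi_path
        return out


def make_scenario(n_res: int = 60, n_models: int = 20, footprint_size: int = 8,
                  include_true_pose: bool = True, msa_depth: int = 8,
                  sub_rate: float = 0.3, seed: int = 0,
                  contact_cutoff: float = 5.0) -> SyntheticScenario:
    """Deterministic synthetic localization scenario.

    ``n_models`` pseudo-antibody poses are placed over seeded random surface
    patches of ``footprint_size`` residues; when ``include_true_pose`` is
    set, the first pose is the designated true binding mode and the
    ground-truth epitope is its contact footprint.
    """
    if n_res < 20 or n_models < 1:
        raise ValueError("need n_res >= 20 and n_models >= 1")
    if footprint_size > n_res:
        raise ValueError("footprint_size exceeds the antigen surface")
    rng = np.random.default_rng(seed)
    antigen = make_toy_antigen(n_res, seed=int(rng.integers(2 ** 31)))
    keys = antigen.keys()
    centers = rng.choice(n_res, size=n_models, replace=n_models > n_res)
    models = []
    for i, ci in enumerate(centers):
        patch = _patch(antigen, keys[int(ci)], footprint_size)
        ab = make_pseudo_antibody(antigen, patch, pose_id=i)
        models.append(DockingModel(id=f"pose_{i:03d}", ab=ab, ag=antigen,
                                   cutoff=contact_cutoff))
    ensemble = DockingEnsemble(models=models, antigen=antigen,
                               source_label=f"synthetic-seed{seed}")
    msa = _make_msa(antigen, msa_depth, sub_rate, rng)
    true_id = "pose_000" if include_true_pose else None
    epitope = None
    if include_true_pose:
        epitope = EpitopeSpec(residues=set(ensemble.model(true_id).footprint),
                              provenance="true-pose-footprint")
    return SyntheticScenario(antigen=antigen, ensemble=ensemble, msa=msa,
                             true_model_id=true_id, epitope=epitope, seed=seed,
                             params=dict(n_res=n_res, n_models=n_models,
                                         footprint_size=footprint_size,
                                         msa_depth=msa_depth, sub_rate=sub_rate,
                                         contact_cutoff=contact_cutoff))


def scenario_multi_ab(n_abs: int, n_groups: int, seed: int = 0,
                      n_res: int = 80, models_per_ab: int = 8,
                      footprint_size: int = 8, msa_depth: int = 8,
                      sub_rate: float = 0.3,
                      contact_cutoff: float = 5.0) -> dict[str, SyntheticScenario]:
    """Antibody panel scenario: groups of antibodies sharing epitope patches.

    Antibodies are assigned round-robin to ``n_groups`` groups; each group
    owns a surface patch (patches pairwise disjoint, placed by farthest-point
    selection), and every model of a group-member antibody is centred on a
    residue of that patch.  Supports epitope-binning tests: the average
    Hausdorff distance between per-antibody designs recovers the groups.
    """
    if n_groups > n_abs:
        raise ValueError("more groups than antibodies")
    rng = np.random.default_rng(seed)
    antigen = make_toy_antigen(n_res, seed=int(rng.integers(2 ** 31)))
    keys = antigen.keys()
    cas = np.array([antigen.ca(k) for k in keys])
    # farthest-point placement of group centres
    centres = [int(rng.integers(n_res))]
    while len(centres) < n_groups:
        d = np.min(np.linalg.norm(cas[:, None] - cas[centres][None], axis=2), axis=1)
        centres.append(int(d.argmax()))
    patches = [_patch(antigen, keys[c], footprint_size) for c in centres]
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            if set(patches[i]) & set(patches[j]):
                raise ValueError("cannot place that many disjoint patches "
                                 f"on a {n_res}-residue antigen")
    msa = _make_msa(antigen, msa_depth, sub_rate, rng)
    out: dict[str, SyntheticScenario] = {}
    for a in range(n_abs):
        group = a % n_groups
        patch = patches[group]
        models = []
        for i in range(models_per_ab):
            centre = patch[int(rng.integers(min(3, len(patch))))]
            mpatch = _patch(antigen, centre, footprint_size)
            ab = make_pseudo_antibody(antigen, mpatch, pose_id=i)
            models.append(DockingModel(id=f"pose_{i:03d}", ab=ab, ag=antigen,
                                       cutoff=contact_cutoff))
        ensemble = DockingEnsemble(models=models, antigen=antigen,
                                   source_label=f"Ab{a + 1}")
        epitope = EpitopeSpec(residues=set(models[0].footprint),
                              provenance="true-pose-footprint")
        out[f"Ab{a + 1}"] = SyntheticScenario(
            antigen=antigen, ensemble=ensemble, msa=msa,
            true_model_id="pose_000", epitope=epitope, seed=seed,
            params=dict(group=group, n_res=n_res,
                        footprint_size=footprint_size))
    return out
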