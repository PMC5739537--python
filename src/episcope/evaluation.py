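"""Epitope definitions, localization scoring and retrospective statistics.

An epitope is a set of antigen residues, either a curated experimentally
verified list or the 5 A heavy-atom binding interface of a reference
co-crystal complex.  Localization *succeeds* when at least one design of the
selected panel carries a mutation inside the epitope — the same criterion a
binding assay would report when that variant loses antibody recognition.

The module also provides the size-matched random-mutagenesis baseline
(random surface triples selected by the same clustering machinery) and the
summary statistics over the packaged 33-complex retrospective benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .docking import DockingEnsemble
from .panel import Panel, hausdorff_matrix_fixed, kmedoids_matrix
from .structures import (ResidueKey, Structure, heavy_atom_contacts)

log = logging.getLogger(__name__)


@dataclass
class EpitopeSpec:
    """Antigen residues constituting an epitope, with provenance."""

    residues: set[ResidueKey]
    provenance: str = "curated-list"   # or "interface-5A"

    def __post_init__(self):
        if not self.residues:
            raise ValueError("an epitope needs at least one residue")


def interface_epitope(ag: Structure, ab: Structure,
                      cutoff: float = 5.0) -> EpitopeSpec:
    """Binding-interface epitope: antigen residues within ``cutoff`` (heavy
    atoms) of the antibody in a reference complex."""
    pairs = heavy_atom_contacts(ag, ab, cutoff)
    if not pairs:
        raise ValueError("partners share no contacts — not a complex")
    return EpitopeSpec(residues={ra for ra, _ in pairs},
                       provenance=f"interface-{cutoff:g}A")


def read_epitope_list(path: str | Path) -> EpitopeSpec:
    """Plain-text epitope list, one ``chain:number`` label per line."""
    residues = {ResidueKey.parse(ln) for ln in Path(path).read_text().splitlines()
                if ln.strip() and not ln.startswith("#")}
    return EpitopeSpec(residues=residues, provenance="curated-list")


@dataclass
class LocalizationResult:
    """Outcome of scoring a panel against an epitope."""

    success: bool
    hit_designs: list[str]
    consistent_models: list[str] = field(default_factory=list)
    consistent_surface_fraction: float = 0.0


def localization_success(panel: Panel, epitope: EpitopeSpec) -> LocalizationResult:
    """Success iff some panel design mutates a residue inside the epitope."""
    if not panel.designs:
        raise ValueError("panel is empty")
    hits = sorted(d.id for d in panel.designs
                  if set(d.positions) & epitope.residues)
    return LocalizationResult(success=bool(hits), hit_designs=hits)


def consistent_models(panel: Panel, disruptive_design_ids: Sequence[str],
                      e: DockingEnsemble,
                      surface: set[ResidueKey]) -> tuple[list[str], float]:
    """Docking models consistent with experimentally disruptive designs.

    A model is *consistent* when its footprint contains a mutated position
    of at least one design observed to ablate binding; the union of the
    consistent footprints, as a fraction of the surface, is the residual
    epitope search space.
    """
    by_id = {d.id: d for d in panel.designs}
    unknown = [i for i in disruptive_design_ids if i not in by_id]
    if unknown:
        raise KeyError(f"unknown design id(s): {unknown}")
    positions: set[ResidueKey] = set()
    for i in disruptive_design_ids:
        positions |= set(by_id[i].positions)
    consistent = sorted(m.id for m in e.models if m.footprint & positions)
    union: set[ResidueKey] = set()
    for mid in consistent:
        union |= e.model(mid).footprint
    frac = len(union & surface) / len(surface) if surface else 0.0
    return consistent, frac


# ---------------------------------------------------------------------------
# Random-design baseline


@dataclass
class BaselineResult:
    success_rate: float
    ci_low: float
    ci_high: float
    successes: int
    reps: int
    per_rep: np.ndarray = field(repr=False, default=None)


def sample_spread_limited_sets(ca: np.ndarray, k: int, n: int,
                               max_spread: float, rng: np.random.Generator,
                               max_batches: int = 2000) -> np.ndarray:
    """Uniform k-position index sets with mean pairwise CA distance < max_spread."""
    n_res = len(ca)
    iu = np.triu_indices(k, 1)
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_batches):
        batch = max(256, n - got)
        idx = np.argsort(rng.random((batch, n_res)), axis=1)[:, :k]
        pts = ca[idx]                                   # (batch, k, 3)
        d = np.linalg.norm(pts[:, iu[0]] - pts[:, iu[1]], axis=2)
        keep = idx[d.mean(axis=1) < max_spread]
        if keep.size:
            out.append(keep)
            got += len(keep)
        if got >= n:
            return np.concatenate(out)[:n]
    raise ValueError("spread constraint infeasible for this surface")


def random_baseline(s: Structure, surface: set[ResidueKey],
                    epitope: EpitopeSpec, n_designs: int, k: int = 3,
                    max_spread: float = 12.0, reps: int = 1000,
                    pool: int = 1000, seed: int = 0,
                    restarts: int = 10) -> BaselineResult:
    """Success rate of size-matched random mutagenesis plans.

    Each repetition draws ``pool`` random k-position surface sets obeying
    the spread constraint, clusters them with the same Hausdorff/K-medoids
    machinery into ``n_designs`` clusters, takes the medoids as the selected
    plan, and scores success as any selected set touching the epitope.
    Amino-acid identity is irrelevant to this position-overlap metric, so
    only positions are randomised.  Returns the mean success over ``reps``
    with a Wilson binomial confidence interval.
    """
    surf = sorted(surface)
    if len(surf) < k:
        raise ValueError("surface smaller than k")
    ca = np.array([s.ca(p) for p in surf])
    epi_mask = np.array([p in epitope.residues for p in surf])
    rng = np.random.default_rng(seed)
    wins = np.zeros(reps, dtype=bool)
    for rep in range(reps):
        idx = sample_spread_limited_sets(ca, k, pool, max_spread, rng)
        if n_designs >= pool:
            chosen = np.arange(pool)
        else:
            D = hausdorff_matrix_fixed(ca[idx])
            res = kmedoids_matrix(D, n_designs,
                                  seed=int(rng.integers(2 ** 31)),
                                  restarts=restarts)
            chosen = np.array(res.medoids)
        wins[rep] = bool(epi_mask[idx[chosen]].any())
    successes = int(wins.sum())
    ci = stats.binomtest(successes, reps).proportion_ci(method="wilson")
    return BaselineResult(success_rate=successes / reps,
                          ci_low=float(ci.low), ci_high=float(ci.high),
                          successes=successes, reps=reps, per_rep=wins)


# ---------------------------------------------------------------------------
# Retrospective summary statistics


NUMERIC_COLUMNS = [
    "n_residues_whole", "n_residues_surface", "n_epitope_residues",
    "n_designs_crystal", "n_designs_model", "fnat_crystal", "fnat_model",
    "n_decoys_crystal", "n_decoys_model",
]
SUCCESS_COLUMNS = [
    "success_iedb_crystal", "success_interface_crystal",
    "success_iedb_model", "success_interface_model",
]


def _safe_corr(fn, x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return {"value": None, "degenerate": True}
    r = fn(x, y)
    return {"value": float(r.statistic), "p": float(r.pvalue), "degenerate": False}


def summarize_retrospective(table: pd.DataFrame) -> dict:
    """Column means/SDs, success rates, and the design-count correlations.

    Kendall's tau (tau-b, tie-corrected) relates the number of docking
    decoys to the number of designs per structure source; Pearson's r
    relates antigen size to the number of designs (whole-chain residue
    count primary, surface count also emitted).
    """
    missing = [c for c in NUMERIC_COLUMNS + SUCCESS_COLUMNS
               if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns: {missing}")
    if table[NUMERIC_COLUMNS].isna().any().any():
        raise ValueError("table has missing numeric cells")
    out: dict = {"n_rows": int(len(table)), "columns": {}}
    for col in NUMERIC_COLUMNS:
        out["columns"][col] = {
            "mean": float(table[col].mean()),
            "sd": float(table[col].std(ddof=1)),
        }
    out["success"] = {}
    for col in SUCCESS_COLUMNS:
        flags = table[col].astype(bool)
        out["success"][col] = {
            "n_success": int(flags.sum()),
            "rate": float(flags.mean()),
        }
    out["kendall_tau_decoys_designs"] = {
        "crystal": _safe_corr(stats.kendalltau, table["n_decoys_crystal"],
                              table["n_designs_crystal"]),
        "model": _safe_corr(stats.kendalltau, table["n_decoys_model"],
                            table["n_designs_model"]),
    }
    out["pearson_size_designs"] = {
        "whole_crystal": _safe_corr(stats.pearsonr, table["n_residues_whole"],
                                    table["n_designs_crystal"]),
        "whole_model": _safe_corr(stats.pearsonr, table["n_residues_whole"],
                                  table["n_designs_model"]),
        "surface_crystal": _safe_corr(stats.pearsonr, table["n_residues_surface"],
                                      table["n_designs_crystal"]),
        "primary": "whole_crystal",
    }
    return out
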