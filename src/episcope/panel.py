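"""Panel selection: Hausdorff clustering and minimal coverage of dock models.

Candidate variants are clustered by the Hausdorff distance between the CA
coordinates of their mutated positions.  Starting from K=1, the number of
clusters grows until some combination of designs, one per cluster, disrupts
every coverable docking model; among fully covering combinations the one
with the largest summed disruptiveness wins.  The panel size is therefore
decided by the data — it is the number of experiments a user must run.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .design import VariantDesign, write_designs_tsv
from .docking import DockingEnsemble, DockingModel
from .structures import Structure

log = logging.getLogger(__name__)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two 3D point sets.

    ``max(max_a min_b d(a,b), max_b min_a d(b,a))`` with Euclidean d.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def design_points(d: VariantDesign, s: Structure) -> np.ndarray:
    """CA coordinates of a design's mutated positions."""
    return np.array([s.ca(p) for p in d.positions])


def hausdorff_matrix(point_sets: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise symmetric Hausdorff distances for a list of point sets."""
    n = len(point_sets)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = hausdorff(point_sets[i], point_sets[j])
    return m


def hausdorff_matrix_fixed(points: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Pairwise Hausdorff matrix for ``(n, k, 3)`` equal-size point sets.

    Vectorised for the random-baseline workload where thousands of small
    equal-cardinality sets must be compared.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    out = np.zeros((n, n))
    for s in range(0, n, chunk):
        block = points[s:s + chunk]
        # d2[i, j, a, b] = |block[i, a] - points[j, b]|^2
        diff = block[:, None, :, None, :] - points[None, :, None, :, :]
        d = np.sqrt((diff ** 2).sum(-1))
        fwd = d.min(axis=3).max(axis=2)   # max_a min_b
        bwd = d.min(axis=2).max(axis=2)   # max_b min_a
        out[s:s + chunk] = np.maximum(fwd, bwd)
    return np.maximum(out, out.T)


# ---------------------------------------------------------------------------
# K-medoids (PAM)


@dataclass
class KMedoidsResult:
    medoids: tuple[int, ...]
    labels: np.ndarray
    cost: float

    def clusters(self) -> list[list[int]]:
        return [sorted(np.flatnonzero(self.labels == c)) for c in range(len(self.medoids))]


def kmedoids_matrix(D: np.ndarray, k: int, seed: int = 0,
                    restarts: int = 10, max_iter: int = 100) -> KMedoidsResult:
    """PAM-style K-medoids on a precomputed distance matrix.

    Random initialisation with ``restarts`` independent starts, steepest
    single-swap descent, best objective kept.  Deterministic for a fixed
    seed; ties break toward the lexicographically smallest medoid tuple.
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} items")
    rng = np.random.default_rng(seed)
    best: tuple[float, tuple[int, ...]] | None = None
    for _ in range(max(1, restarts)):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        cost = D[medoids].min(axis=0).sum()
        for _ in range(max_iter):
            dm = D[medoids]                      # (k, n)
            order = np.argsort(dm, axis=0)
            d1 = dm[order[0], np.arange(n)]
            nearest = order[0]
            d2 = dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
            improved = False
            for mi in range(k):
                mask = nearest == mi
                # cost of swapping medoid mi for every candidate h at once
                cand = (np.minimum(D[mask], d2[mask, None]).sum(axis=0)
                        + np.minimum(D[~mask], d1[~mask, None]).sum(axis=0))
                cand[medoids] = np.inf
                h = int(cand.argmin())
                if cand[h] + 1e-12 < cost:
                    medoids = np.sort(np.concatenate([
                        np.delete(medoids, mi), [h]]))
                    cost = float(D[medoids].min(axis=0).sum())
                    improved = True
                    break
            if not improved:
                break
        key = (float(cost), tuple(int(m) for m in medoids))
        if best is None or key < best:
            best = key
    cost, medoids = best
    labels = np.asarray(D[list(medoids)]).argmin(axis=0)
    # every cluster keeps its own medoid even under distance ties
    for ci, m in enumerate(medoids):
        labels[m] = ci
    return KMedoidsResult(medoids=medoids, labels=labels, cost=cost)


def kmedoids(designs: Sequence[VariantDesign], K: int, seed: int,
             s: Structure, restarts: int = 10) -> list[list[VariantDesign]]:
    """Cluster designs by Hausdorff distance of their mutated-CA point sets."""
    if K > len(designs):
        raise ValueError(f"K={K} exceeds the {len(designs)} designs")
    D = hausdorff_matrix([design_points(d, s) for d in designs])
    res = kmedoids_matrix(D, K, seed=seed, restarts=restarts)
    return [[designs[i] for i in cluster] for cluster in res.clusters()]


# ---------------------------------------------------------------------------
# Panel selection


@dataclass
class Panel:
    """The selected variant panel and its coverage of docking models."""

    designs: list[VariantDesign]
    coverage: dict[str, list[str]]        # model id -> covering design ids
    uncovered: list[str]                  # models no design can disrupt
    objective: float                      # summed disruptiveness
    k_clusters: int = 0
    clusters: list[list[str]] = field(default_factory=list)
    search: str = "exhaustive"

    def design_ids(self) -> list[str]:
        return [d.id for d in self.designs]


def _coverage_of(combo: Sequence[VariantDesign]) -> set[str]:
    out: set[str] = set()
    for d in combo:
        out |= d.covered_models
    return out


def _greedy_cover(designs: Sequence[VariantDesign], target: set[str]) -> list[VariantDesign]:
    chosen: list[VariantDesign] = []
    left = set(target)
    pool = list(designs)
    while left and pool:
        best = min(pool, key=lambda d: (-len(d.covered_models & left),
                                        -d.total_disruption, d.id))
        gain = best.covered_models & left
        if not gain:
            break
        chosen.append(best)
        pool.remove(best)
        left -= gain
    return sorted(chosen, key=lambda d: d.id)


def select_panel(designs: Sequence[VariantDesign], e: DockingEnsemble,
                 seed: int = 0, combo_budget: int = 10 ** 6,
                 restarts: int = 10) -> Panel:
    """Smallest-K covering panel with maximal summed disruptiveness.

    K is grown from 1; at each K the designs are Hausdorff/K-medoids
    clustered and every one-design-per-cluster combination is tested for
    full coverage of the coverable models (models disrupted by no design at
    all are excluded from the requirement and reported as uncovered).  Among
    covering combinations the largest summed disruptiveness wins, ties going
    to the lexicographically smallest design-id tuple.  If the combination
    count exceeds ``combo_budget`` the search falls back to greedy
    max-coverage with a logged warning.
    """
    designs = list(designs)
    if not designs:
        raise ValueError("no designs to select from")
    s = e.antigen
    all_models = {m.id for m in e.models}
    coverable = set().union(*(d.covered_models for d in designs)) & all_models
    uncovered = sorted(all_models - coverable)

    def build_panel(selected: list[VariantDesign], K: int,
                    clusters: list[list[VariantDesign]], search: str) -> Panel:
        selected = sorted(selected, key=lambda d: d.id)
        cov = {m.id: sorted(d.id for d in selected if m.id in d.covered_models)
               for m in e.models if m.id in coverable}
        return Panel(designs=selected, coverage=cov, uncovered=uncovered,
                     objective=sum(d.total_disruption for d in selected),
                     k_clusters=K,
                     clusters=[sorted(d.id for d in c) for c in clusters],
                     search=search)

    for K in range(1, len(designs) + 1):
        clusters = kmedoids(designs, K, seed=seed, s=s, restarts=restarts)
        n_combos = int(np.prod([len(c) for c in clusters], dtype=float))
        if n_combos > combo_budget:
            log.warning("combination search at K=%d needs %d tuples "
                        "(budget %d); falling back to greedy max-coverage",
                        K, n_combos, combo_budget)
            chosen = _greedy_cover(designs, coverable)
            if _coverage_of(chosen) >= coverable:
                return build_panel(chosen, K, clusters, search="greedy")
            continue
        best: tuple[float, tuple[str, ...], tuple[VariantDesign, ...]] | None = None
        for combo in itertools.product(*clusters):
            if _coverage_of(combo) >= coverable:
                ids = tuple(sorted(d.id for d in combo))
                key = (-sum(d.total_disruption for d in combo), ids)
                if best is None or key < best[:2]:
                    best = (*key, combo)
        if best is not None:
            return build_panel(list(best[2]), K, clusters, search="exhaustive")
    # with K == n(designs) every design is its own cluster and the single
    # combination is the full design set, which covers `coverable` by
    # construction — so this point is unreachable
    raise AssertionError("coverable models could not be covered")


def pool_ensembles(ensembles: Mapping[str, DockingEnsemble] |
                   Sequence[DockingEnsemble]) -> DockingEnsemble:
    """Concatenate per-antibody ensembles over one shared antigen.

    Model ids gain an antibody-label prefix (``label:model``) so a pooled
    design run can interrogate all antibodies' docking models at once.
    """
    if isinstance(ensembles, Mapping):
        items = list(ensembles.items())
    else:
        items = [(e.source_label or str(i), e) for i, e in enumerate(ensembles)]
    if not items:
        raise ValueError("no ensembles to pool")
    first = items[0][1]
    models: list[DockingModel] = []
    for label, e in items:
        if e.antigen is not first.antigen:
            from .docking import _same_antigen

            if not _same_antigen(e.antigen, first.antigen):
                raise ValueError(f"ensemble {label}: antigen differs")
        for m in e.models:
            mid = m.id if len(items) == 1 else f"{label}:{m.id}"
            models.append(DockingModel(id=mid, ab=m.ab, ag=first.antigen,
                                       cutoff=m.cutoff, _footprint=m._footprint))
    return DockingEnsemble(models=models, antigen=first.antigen,
                           source_label="+".join(l for l, _ in items))


def design_distance_matrix(per_ab_designs: Mapping[str, Sequence[VariantDesign]],
                           s: Structure):
    """Average Hausdorff distance between the variants designed per antibody.

    Entry (i, j) is the mean over all (design-of-i, design-of-j) pairs; the
    diagonal averages distinct pairs within one antibody (0 for a single
    design).  Low values flag antibodies predicted to share an epitope bin.
    """
    import pandas as pd

    labels = list(per_ab_designs)
    if len(labels) < 2:
        raise ValueError("need designs for at least two antibodies")
    pts = {}
    for label, designs in per_ab_designs.items():
        if not designs:
            raise ValueError(f"no designs for antibody {label!r}")
        pts[label] = [design_points(d, s) for d in designs]
    m = np.zeros((len(labels), len(labels)))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if i == j:
                pairs = [hausdorff(a, b)
                         for a, b in itertools.combinations(pts[la], 2)]
                m[i, j] = float(np.mean(pairs)) if pairs else 0.0
            elif j > i:
                pairs = [hausdorff(a, b) for a in pts[la] for b in pts[lb]]
                m[i, j] = m[j, i] = float(np.mean(pairs))
    return pd.DataFrame(m, index=labels, columns=labels)


def write_panel(panel: Panel, prefix: str | Path) -> tuple[Path, Path]:
    """Write the panel TSV and the JSON report; byte-stable across reruns."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    write_designs_tsv(panel.designs, tsv)
    report = {
        "K": panel.k_clusters,
        "search": panel.search,
        "objective": round(panel.objective, 6),
        "clusters": panel.clusters,
        "coverage": panel.coverage,
        "uncovered_models": panel.uncovered,
    }
    js = prefix.with_suffix(".json")
    js.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return tsv, js
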