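"""Design of disruptive antigen variants, one docking model at a time.

For each docking model, candidate point mutations are drawn from the
intersection of the model's footprint with the antigen surface, restricted
to substitutions observed in homologous sequences (nature's own viability
filter).  Candidates must be *disruptive*: replacing the wild-type residue
must worsen the predicted contact energy against the antibody residues it
touches.  Sets of ``k`` mutations are then assembled per model, balancing
total binding disruption against a predicted stability penalty in Pareto
fashion, subject to a geometric coherence constraint (mean pairwise CA
distance of the mutated sites <= 12 A by default) and to the requirement
that a variant is predicted to be no less stable than the wild type.

Sign convention: disruptiveness is normalised so that *positive* scores are
binding-disruptive; stability deltas are (mutant - wild type), so *negative
or zero* means acceptable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .docking import DockingEnsemble, DockingModel
from .potentials import AMINO_ACIDS, PairPotential, default_potential
from .structures import (ResidueKey, Structure, mean_pairwise_ca_distance)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Homolog substitution filter


@dataclass
class SubstitutionTable:
    """Evolutionarily accepted substitutions per antigen position."""

    allowed: dict[ResidueKey, set[str]]

    def __getitem__(self, key: ResidueKey) -> set[str]:
        return self.allowed.get(key, set())


def _read_alignment(msa) -> list[str]:
    """Accept a FASTA path, Bio alignment, or list of aligned strings."""
    if isinstance(msa, (str, Path)):
        from Bio import AlignIO

        aln = AlignIO.read(str(msa), "fasta")
        return [str(rec.seq).upper() for rec in aln]
    if isinstance(msa, (list, tuple)) and msa and isinstance(msa[0], str):
        return [s.upper() for s in msa]
    return [str(rec.seq).upper() for rec in msa]


def allowed_substitutions(msa, antigen: Structure,
                          min_count: int = 1) -> SubstitutionTable:
    """Per-position substitutions observed in >= ``min_count`` homolog rows.

    The first alignment row must be the antigen sequence (gaps allowed);
    gap characters and non-standard letters in homolog rows are ignored.
    """
    rows = _read_alignment(msa)
    first = rows[0]
    ungapped = first.replace("-", "").replace(".", "")
    if ungapped != antigen.sequence:
        raise ValueError("first MSA row does not match the antigen sequence "
                         f"({len(ungapped)} vs {len(antigen.sequence)} residues)")
    keys = antigen.keys()
    allowed: dict[ResidueKey, set[str]] = {}
    pos = 0
    for col, wt in enumerate(first):
        if wt in "-.":
            continue
        key = keys[pos]
        counts: dict[str, int] = {}
        for row in rows[1:]:
            aa = row[col]
            if aa in AMINO_ACIDS and aa != wt:
                counts[aa] = counts.get(aa, 0) + 1
        subs = {aa for aa, c in counts.items() if c >= min_count}
        if subs:
            allowed[key] = subs
        pos += 1
    return SubstitutionTable(allowed=allowed)


# ---------------------------------------------------------------------------
# Scores


@dataclass(frozen=True)
class Mutation:
    """One point mutation with its per-model disruptiveness scores."""

    position: ResidueKey
    wt: str
    mut: str
    disruptiveness: tuple[tuple[str, float], ...] = ()  # (model id, score)

    def __post_init__(self):
        if self.wt == self.mut:
            raise ValueError("wild type and mutant amino acid are identical")

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.disruptiveness)

    def label(self) -> str:
        return f"{self.wt}{self.position.number}{self.position.icode}{self.mut}"


def _contacting_ab_residues(pos: ResidueKey, m: DockingModel,
                            cutoff: float | None = None) -> list[str]:
    """Amino acids of antibody residues contacting an antigen position."""
    cutoff = m.cutoff if cutoff is None else cutoff
    res = m.ag.residues[pos]
    ab_coords, ab_idx = m.ab.flat_coords()
    ab_keys = m.ab.keys()
    tree = cKDTree(ab_coords)
    hit_res = {ab_idx[j] for h in tree.query_ball_point(res.coords, cutoff) for j in h}
    return [m.ab.residues[ab_keys[i]].aa for i in sorted(hit_res)]


def disruptiveness(pos: ResidueKey, aa: str, m: DockingModel,
                   p: PairPotential, cutoff: float | None = None) -> float:
    """Predicted binding disruption of mutating ``pos`` to ``aa`` for model ``m``.

    Sum over contacting antibody residues of the contact-energy change
    (mutant minus wild type); positive = disruptive (the contact worsens).
    """
    if pos not in m.footprint:
        raise ValueError(f"{pos.label()} is outside the footprint of {m.id}")
    wt = m.ag.residues[pos].aa
    if aa == wt:
        return 0.0
    return float(sum(p(aa, ab) - p(wt, ab) for ab in _contacting_ab_residues(pos, m, cutoff)))


class ContactStabilityScorer:
    """Default stability proxy: contact-potential delta plus a clash penalty.

    The (mutant - wild type) energy is summed over antigen residues with a
    heavy atom within ``contact_cutoff`` of each mutated position, using the
    same style of residue-contact potential as the binding score, and a hard
    steric penalty (+inf) is added when two mutated positions' CB-proxy
    atoms come within ``clash_cutoff``.  More negative = more stable.
    """

    def __init__(self, potential: PairPotential | None = None,
                 contact_cutoff: float = 5.0, clash_cutoff: float = 2.5):
        self.potential = potential or default_potential()
        self.contact_cutoff = contact_cutoff
        self.clash_cutoff = clash_cutoff

    def _neighbours(self, s: Structure, pos: ResidueKey) -> list[ResidueKey]:
        coords, idx = s.flat_coords()
        keys = s.keys()
        tree = cKDTree(coords)
        res = s.residues[pos]
        hit = {idx[j] for h in tree.query_ball_point(res.coords, self.contact_cutoff)
               for j in h}
        return [keys[i] for i in sorted(hit) if keys[i] != pos]

    def _cb_proxy(self, s: Structure, pos: ResidueKey) -> np.ndarray:
        res = s.residues[pos]
        xyz = res.atom("CB")
        return xyz if xyz is not None else res.coords.mean(axis=0)

    def __call__(self, s: Structure, mutations: Iterable[Mutation]) -> float:
        mutations = list(mutations)
        if not mutations:
            return 0.0
        mutated = {m.position: m.mut for m in mutations}
        p = self.potential
        total = 0.0
        for m in mutations:
            for nb in self._neighbours(s, m.position):
                nb_wt = s.residues[nb].aa
                nb_new = mutated.get(nb, nb_wt)
                # halve doubly-mutated pairs (counted from both ends)
                w = 0.5 if nb in mutated else 1.0
                total += w * (p(m.mut, nb_new) - p(m.wt, nb_wt))
        for a, b in itertools.combinations(mutations, 2):
            d = np.linalg.norm(self._cb_proxy(s, a.position) - self._cb_proxy(s, b.position))
            if d < self.clash_cutoff:
                return float("inf")
        return float(total)


class SolvationStabilityScorer(ContactStabilityScorer):
    """Solvent-reference stability proxy (the package default).

    Treats every residue as having a fixed coordination number Z: with c
    protein contacts, the remaining Z - c contacts are solvent contacts
    whose energy is the amino acid's transfer penalty s(a) (hydrophobic in
    water is unfavourable).  The mutation delta is then

        sum_contacts [e(mut, nb) - e(wt, nb)] + (Z - c) * [s(mut) - s(wt)]

    plus the inherited steric-clash penalty.  For buried sites (c ~ Z) this
    reduces to the plain contact-potential delta; for exposed sites the
    solvation term dominates, so surface substitutions toward polar or
    charged residues are not spuriously penalised by the same potential
    that rewards hydrophobic packing in the core.  The default transfer
    penalties mirror the default potential's hydropathy term
    (``s(a) = hydro_weight * h_a``, Kyte-Doolittle h); supply a custom
    ``solvation`` vector alongside a custom potential.
    """

    def __init__(self, potential: PairPotential | None = None,
                 coordination: int = 12,
                 solvation: dict[str, float] | None = None,
                 hydro_weight: float = 0.5, **kw):
        super().__init__(potential=potential, **kw)
        from .potentials import KD_HYDROPATHY

        self.coordination = coordination
        self.solvation = solvation or {
            a: hydro_weight * h for a, h in KD_HYDROPATHY.items()}

    def __call__(self, s: Structure, mutations: Iterable[Mutation]) -> float:
        mutations = list(mutations)
        base = super().__call__(s, mutations)
        if not np.isfinite(base):
            return base
        solv = 0.0
        for m in mutations:
            c = len(self._neighbours(s, m.position))
            solvent_contacts = max(0, self.coordination - c)
            solv += solvent_contacts * (self.solvation[m.mut] - self.solvation[m.wt])
        return float(base + solv)


StabilityScorer = Callable[[Structure, Iterable[Mutation]], float]


def stability_delta(s: Structure, mutations: Iterable[Mutation],
                    scorer: StabilityScorer | None = None) -> float:
    """(mutant - wild type) stability estimate; empty mutation set is 0."""
    scorer = scorer or ContactStabilityScorer()
    try:
        return scorer(s, mutations)
    except Exception as exc:  # propagate with position context
        labels = ",".join(m.label() for m in mutations)
        raise RuntimeError(f"stability scorer failed for [{labels}]: {exc}") from exc


# ---------------------------------------------------------------------------
# Designs


@dataclass
class VariantDesign:
    """A set of 1-4 point mutations forming one antigen variant."""

    mutations: tuple[Mutation, ...]
    covered_models: frozenset[str]
    total_disruption: float
    stability_delta: float
    spread: float
    id: str = ""

    def __post_init__(self):
        if not 1 <= len(self.mutations) <= 4:
            raise ValueError("a design carries 1-4 mutations")
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise ValueError("mutation positions must be distinct")
        object.__setattr__(self, "mutations",
                           tuple(sorted(self.mutations, key=lambda m: m.position)))

    @property
    def positions(self) -> tuple[ResidueKey, ...]:
        return tuple(m.position for m in self.mutations)

    def mutation_label(self) -> str:
        return ";".join(m.label() for m in self.mutations)


@dataclass
class DesignParams:
    """Tunable knobs of the variant-design stage.

    k: mutations per design (1-4; 3 balances effort against resolution).
    max_spread: maximal mean pairwise CA distance of mutated sites (A).
    contact_cutoff: heavy-atom contact cutoff for footprints/neighbours (A).
    pareto_cap: designs kept per docking model (bounds the cover search).
    min_homolog_count: rows of the MSA that must show a substitution.
    surface_threshold: relative-accessibility cut defining 'surface'.
    """

    k: int = 3
    max_spread: float = 12.0
    contact_cutoff: float = 5.0
    pareto_cap: int = 50
    rng_seed: int = 0
    min_homolog_count: int = 1
    surface_threshold: float = 0.07

    def __post_init__(self):
        if not 1 <= self.k <= 4:
            raise ValueError("k must be 1-4")
        if self.max_spread <= 0:
            raise ValueError("max_spread must be positive")


def candidate_mutations(m: DockingModel, surface: set[ResidueKey],
                        subs: SubstitutionTable, p: PairPotential,
                        cutoff: float | None = None) -> list[Mutation]:
    """All positively disruptive single mutations available for model ``m``.

    Positions are limited to footprint-and-surface; substitutions to those
    accepted by homologs; candidates with non-positive disruptiveness toward
    ``m`` are dropped.
    """
    out: list[Mutation] = []
    for pos in sorted(m.footprint & surface):
        wt = m.ag.residues[pos].aa
        for aa in sorted(subs[pos]):
            if aa == wt:
                continue
            d = disruptiveness(pos, aa, m, p, cutoff)
            if d > 0:
                out.append(Mutation(pos, wt, aa, ((m.id, d),)))
    return out


def _pareto_front(points: list[tuple[float, float]]) -> list[int]:
    """Indices of the frontier maximising x and minimising y."""
    front = []
    for i, (xi, yi) in enumerate(points):
        dominated = any(
            (xj >= xi and yj <= yi) and (xj > xi or yj < yi)
            for j, (xj, yj) in enumerate(points) if j != i)
        if not dominated:
            front.append(i)
    return front


def pareto_designs(m: DockingModel, candidates: Sequence[Mutation],
                   params: DesignParams, s: Structure,
                   scorer: StabilityScorer | None = None) -> list[VariantDesign]:
    """Pareto-optimal k-mutation designs for one docking model.

    One mutation per position (the most disruptive toward ``m``); all
    k-subsets of positions are enumerated, filtered on spread and on
    stability (no worse than wild type), and the frontier over
    (maximise disruption, minimise stability delta) is returned, capped at
    ``pareto_cap`` by descending disruptiveness then position order.
    When fewer than k candidate positions exist, all of them are used.
    """
    if not candidates:
        raise ValueError("no candidate mutations supplied")
    scorer = scorer or ContactStabilityScorer()
    best: dict[ResidueKey, Mutation] = {}
    for mut in candidates:
        score = mut.scores.get(m.id, 0.0)
        cur = best.get(mut.position)
        if cur is None or (score, -ord(mut.mut[0])) > (cur.scores.get(m.id, 0.0),
                                                       -ord(cur.mut[0])):
            best[mut.position] = mut
    positions = sorted(best)
    k = min(params.k, len(positions))
    feasible: list[tuple[tuple[Mutation, ...], float, float, float]] = []
    for combo in itertools.combinations(positions, k):
        muts = tuple(best[p] for p in combo)
        spread = mean_pairwise_ca_distance(s, combo)
        if spread > params.max_spread:
            continue
        stab = stability_delta(s, muts, scorer)
        if stab > 0:
            continue
        disr = sum(mu.scores[m.id] for mu in muts)
        feasible.append((muts, disr, stab, spread))
    if not feasible:
        log.warning("model %s: no feasible %d-mutation design "
                    "(spread <= %.1f A, stability <= 0)", m.id, k, params.max_spread)
        return []
    front = _pareto_front([(f[1], f[2]) for f in feasible])
    chosen = sorted((feasible[i] for i in front),
                    key=lambda f: (-f[1], tuple(mu.position for mu in f[0])))
    designs = [VariantDesign(mutations=muts, covered_models=frozenset({m.id}),
                             total_disruption=disr, stability_delta=stab, spread=spread)
               for muts, disr, stab, spread in chosen[: params.pareto_cap]]
    return designs


def merge_and_annotate(designs: Sequence[VariantDesign], e: DockingEnsemble,
                       p: PairPotential, scorer: StabilityScorer | None = None,
                       cutoff: float | None = None,
                       id_prefix: str = "Ag") -> list[VariantDesign]:
    """Merge per-model designs into one coherent, ensemble-annotated list.

    (i) a mutation in contact with a docking model toward which it is not
    disruptive is removed (a design left without mutations is dropped);
    (ii) identical positions carrying different substitutions are unified to
    the most disruptive surviving one; (iii) coverage is recomputed: a design
    covers a model iff one of its mutations lies in that model's footprint
    (with positive disruptiveness, which (i) guarantees).  Duplicates are
    collapsed, stability is re-evaluated after unification, and deterministic
    ids are assigned.
    """
    scorer = scorer or ContactStabilityScorer()
    antigen = e.antigen

    # score every distinct (position, aa) against every contacting model
    score_cache: dict[tuple[ResidueKey, str], dict[str, float]] = {}

    def scores_for(pos: ResidueKey, aa: str) -> dict[str, float]:
        key = (pos, aa)
        if key not in score_cache:
            score_cache[key] = {
                m.id: disruptiveness(pos, aa, m, p, cutoff)
                for m in e.models if pos in m.footprint}
        return score_cache[key]

    # (i) global disruptiveness filter
    surviving: dict[tuple[ResidueKey, str], dict[str, float]] = {}
    for d in designs:
        for mu in d.mutations:
            sc = scores_for(mu.position, mu.mut)
            if all(v > 0 for v in sc.values()):
                surviving[(mu.position, mu.mut)] = sc

    # (ii) unify: per position keep the most disruptive surviving substitution
    best_sub: dict[ResidueKey, tuple[str, dict[str, float]]] = {}
    for (pos, aa), sc in sorted(surviving.items(),
                                key=lambda kv: (kv[0][0], kv[0][1])):
        total = sum(sc.values())
        cur = best_sub.get(pos)
        if cur is None or total > sum(cur[1].values()):
            best_sub[pos] = (aa, sc)

    merged: dict[tuple, VariantDesign] = {}
    for d in designs:
        muts = []
        for mu in d.mutations:
            if (mu.position, mu.mut) not in surviving:
                continue  # rule (i): not disruptive toward every contacted model
            aa, sc = best_sub[mu.position]  # rule (ii): unify substitution
            muts.append(Mutation(mu.position, mu.wt, aa,
                                 tuple(sorted(sc.items()))))
        if not muts:
            continue
        muts = tuple(muts)
        sig = tuple((m.position, m.mut) for m in sorted(muts, key=lambda m: m.position))
        if sig in merged:
            continue
        covered = frozenset(mid for mu in muts for mid in mu.scores)
        total = sum(v for mu in muts for v in mu.scores.values())
        stab = stability_delta(antigen, muts, scorer)
        if stab > 0:
            continue  # unification may have changed the substitutions
        spread = mean_pairwise_ca_distance(antigen, [m.position for m in muts])
        merged[sig] = VariantDesign(mutations=muts, covered_models=covered,
                                    total_disruption=float(total),
                                    stability_delta=float(stab), spread=float(spread))
    final = sorted(merged.values(),
                   key=lambda d: (-d.total_disruption, d.mutation_label()))
    width = max(2, len(str(len(final))))
    return [replace(d, id=f"{id_prefix}{i + 1:0{width}d}")
            for i, d in enumerate(final)]


def write_designs_tsv(designs: Sequence[VariantDesign], path: str | Path) -> None:
    """TSV of designs; byte-identical across reruns for fixed inputs."""
    with open(path, "w") as fh:
        fh.write("design_id\tmutations\tspread_A\tstability_delta\t"
                 "total_disruption\tcovered_model_ids\n")
        for d in designs:
            fh.write(f"{d.id}\t{d.mutation_label()}\t{d.spread:.3f}\t"
                     f"{d.stability_delta:.4f}\t{d.total_disruption:.4f}\t"
                     f"{','.join(sorted(d.covered_models))}\n")
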