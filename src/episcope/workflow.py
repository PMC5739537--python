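"""End-to-end pipeline: surface -> candidates -> designs -> panel."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .design import (ContactStabilityScorer, DesignParams, SolvationStabilityScorer,
                     StabilityScorer, SubstitutionTable, VariantDesign,
                     allowed_substitutions, candidate_mutations,
                     merge_and_annotate, pareto_designs)
from .docking import DockingEnsemble
from .panel import Panel, select_panel
from .potentials import PairPotential, default_potential
from .structures import (AccessibilityMap, ResidueKey, Structure,
                         relative_accessibility, surface_residues)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything produced by one design run."""

    surface: set[ResidueKey]
    substitutions: SubstitutionTable
    designs: list[VariantDesign]
    panel: Panel
    accessibility: AccessibilityMap | None = None
    warnings: list[str] = field(default_factory=list)


def design_panel(antigen: Structure, ensemble: DockingEnsemble,
                 msa=None, substitutions: SubstitutionTable | None = None,
                 params: DesignParams | None = None,
                 potential: PairPotential | None = None,
                 stability: StabilityScorer | None = None,
                 surface: set[ResidueKey] | None = None) -> PipelineResult:
    """Run the full variant-design pipeline against one docking ensemble.

    Either an aligned homolog MSA or a prebuilt substitution table must be
    supplied.  The default stability scorer is the exposure-aware contact
    scorer evaluated with the default pair potential.
    """
    params = params or DesignParams()
    potential = potential or default_potential()
    acc = None
    if surface is None:
        acc = relative_accessibility(antigen)
        surface = surface_residues(acc, params.surface_threshold)
    if substitutions is None:
        if msa is None:
            raise ValueError("supply an MSA or a substitution table")
        substitutions = allowed_substitutions(msa, antigen,
                                              params.min_homolog_count)
    if stability is None:
        stability = SolvationStabilityScorer(potential=potential)
    warnings: list[str] = []
    raw: list[VariantDesign] = []
    for m in ensemble:
        cands = candidate_mutations(m, surface, substitutions, potential,
                                    params.contact_cutoff)
        if not cands:
            warnings.append(f"{m.id}: no disruptive candidate mutations")
            continue
        designs = pareto_designs(m, cands, params, antigen, stability)
        if not designs:
            warnings.append(f"{m.id}: no feasible design "
                            f"(spread/stability filters)")
        raw.extend(designs)
    if not raw:
        raise ValueError("no feasible designs for any docking model")
    merged = merge_and_annotate(raw, ensemble, potential, stability,
                                params.contact_cutoff)
    if not merged:
        raise ValueError("all designs eliminated by the cross-model "
                         "disruptiveness filter")
    panel = select_panel(merged, ensemble, seed=params.rng_seed)
    for w in warnings:
        log.info(w)
    return PipelineResult(surface=surface, substitutions=substitutions,
                          designs=merged, panel=panel, accessibility=acc,
                          warnings=warnings)
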