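# episcope

Computationally-driven antibody epitope localization.

## The problem

Newly isolated antibodies usually come with a sequence but no structural
knowledge of *where* they bind their antigen. Structure determination is slow
and expensive; purely computational epitope prediction is not yet reliable on
its own. `episcope` implements the middle road: treat an ensemble of
antibody–antigen docking poses as a set of competing hypotheses, then design a
small panel of multi-mutation antigen variants such that **every** docking
hypothesis is disrupted by at least one variant. Expressing the panel and
testing antibody binding then localizes the epitope: a variant that ablates
binding pins the epitope to its mutated residues and to the docking models
consistent with them.

The package is aimed at structural bioinformaticians and antibody engineers
who already have (or can generate) docking poses and want to turn them into a
minimal, interpretable mutagenesis experiment — including multiplexed panels
that interrogate several antibodies against one antigen at once (in-silico
epitope binning).

## The method

Given an antigen structure, a docking ensemble, and a homolog alignment:

1. **Footprints.** Each pose's footprint is the set of antigen residues with a
   heavy atom within 5 Å of the antibody.
2. **Candidate mutations** are restricted to footprint ∩ surface positions
   (relative solvent accessibility > 7%, Shrake–Rupley), to substitutions
   observed in homologs, and to substitutions with positive predicted binding
   disruption Δ = Σ<sub>ab contacts</sub> [e(mut, ab) − e(wt, ab)] under a
   residue-contact potential e (positive = disruptive).
3. **Per-model designs.** For each pose, all k-subsets of candidate positions
   (k = 3 by default) are enumerated and filtered on spatial coherence (mean
   pairwise Cα distance ≤ 12 Å) and predicted stability (ΔΔG ≤ 0 under a
   pluggable scorer); the Pareto frontier over (maximize disruption, minimize
   stability penalty) is kept.
4. **Merge.** A mutation must be disruptive toward every pose whose footprint
   contains it; identical positions are unified to the most disruptive
   substitution; coverage is recomputed.
5. **Panel selection.** Designs are clustered by the Hausdorff distance

   h(A,B) = max{ max<sub>a∈A</sub> min<sub>b∈B</sub> d(a,b),
                 max<sub>b∈B</sub> min<sub>a∈A</sub> d(a,b) }

   between the Cα point sets of their mutated positions, using PAM K-medoids.
   K grows from 1 until some one-design-per-cluster combination covers all
   coverable docking models; the covering combination with the largest summed
   disruptiveness is the panel.
6. **Evaluation.** Localization succeeds when a panel design carries a
   mutation inside the epitope (curated list or 5 Å interface of a reference
   complex). Docking models consistent with experimentally disruptive variants
   bound the residual epitope search space. A size-matched random-mutagenesis
   baseline quantifies what docking information buys.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

Everything below runs offline on a synthetic scenario: a 60-residue
pseudo-antigen, 20 docking poses (one flagged as the true binding mode, its
footprint being the ground-truth epitope), and a synthetic homolog alignment.

```bash
episcope simulate --seed 3 --out sc
episcope design --ag sc/antigen.pdb --docks sc/poses \
                --msa sc/homologs.fasta --seed 3 --out run
```

```
designs=27 panel=7 K=7 uncovered=0
```

27 merged variant designs survive the filters; clustering settles at K = 7,
giving a 7-variant panel that covers all 20 docking models (`uncovered=0`).
The panel TSV lists each variant's mutations and the poses it disrupts:

```
design_id  mutations        spread_A  stability_delta  total_disruption  covered_model_ids
Ag01       P2Q;L3D;F15K     11.590    -44.1000         36.1000           pose_000,pose_001,pose_006,...
Ag06       L3D;W6E;V19D     8.321     -44.9000         26.2000           pose_000,pose_001,pose_004,...
```

`Ag01` mutates positions 2, 3 and 15 (e.g. Pro2→Gln), spreads its mutations
over 11.6 Å, is predicted at least as stable as wild type (negative delta),
and disrupts nine poses including `pose_000` — the true one. Scoring the
panel against the known epitope:

```bash
episcope evaluate --panel run_panel.tsv --epitope sc/epitope.txt
```

```json
{
  "epitope_provenance": "curated-list",
  "epitope_size": 8,
  "hit_designs": ["Ag01", "Ag06"],
  "success": true
}
```

Two of the seven variants carry mutations inside the 8-residue epitope —
in an experiment, those are the variants that would lose antibody binding,
localizing the epitope. `episcope bin` runs the same machinery for several
antibodies at once and emits dock-overlap and design-distance matrices plus a
pooled panel; `episcope stats` summarises a retrospective benchmark table.

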