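# Methods

This note documents the models, parameters and numerical choices behind
`episcope`, and what the synthetic test bed does and does not demonstrate.

## Inputs and geometric conventions

All structures are reduced to heavy atoms; waters and hetero groups are
dropped (selenomethionine counts as methionine), alternate locations resolve
to the highest occupancy, and author (PDB) residue numbering is preserved
verbatim so mutation labels such as `M154E` match mutagenesis convention.
Every distance criterion is a heavy-atom Euclidean distance in Å:

- **Footprint / interface cutoff: 5 Å.** A pose's footprint is the set of
  antigen residues with any heavy atom within 5 Å of any antibody heavy atom;
  the same rule defines the binding-interface epitope of a reference complex.
  One cutoff serves both roles for consistency; it is configurable.
- **Surface: relative solvent accessibility strictly greater than 7%.**
  SASA uses Shrake–Rupley sphere sampling, probe 1.4 Å, 960 deterministic
  golden-spiral points per atom, van der Waals radii C 1.70 / N 1.55 /
  O 1.52 / S 1.80 / P 1.80 / Se 1.90 Å. RSA divides by the theoretical
  Gly-X-Gly maxima (Tien et al. 2013). Point count and reference table are
  configurable; RSA is rotation-invariant only to sampling resolution
  (measured ≤ 0.012 at 960 points, ≤ 0.005 at 3840).
- **f_nat** of a pose against a reference complex is the fraction of the
  reference's interface residue pairs (5 Å rule) present in the pose.

## Scoring

**Binding disruption.** For a candidate substitution wt→mut at an antigen
position in a pose's footprint, Δ = Σ over contacting antibody residues of
e(mut, ab) − e(wt, ab), where e is a symmetric 20×20 residue-contact
potential with lower = more favourable. Scores are sign-normalised so
positive = disruptive; only Δ > 0 candidates are retained, and after merging
a mutation must have Δ > 0 toward *every* pose whose footprint contains it.

The default potential is a quasichemical-style construction
e(a,b) = −0.5·(h_a + h_b) + 0.6·q_a·q_b from the Kyte–Doolittle hydropathy
scale h and unit side-chain charges q (His 0.5). Contact statistical
potentials are dominated by exactly such an additive hydrophobicity
component, and the charge product adds electrostatic complementarity. Any
complete 20×20 whitespace-delimited matrix with a one-letter header can be
loaded in its place (`load_potential`), and both the binding and the
stability scorer accept an arbitrary potential.

**Stability.** The default scorer is a solvent-reference contact model.
Each residue is assigned a fixed coordination number Z = 12; with c protein
contacts (residues within 5 Å), the remaining Z − c contacts are solvent
contacts whose energy is the transfer penalty s(a) = 0.5·h_a. A design's
stability delta is

    ΔΔG = Σ_contacts [e(mut, nb) − e(wt, nb)] + (Z − c)·[s(mut) − s(wt)]

summed over its mutations, plus a hard steric penalty (+∞) when two mutated
positions' Cβ proxies come within 2.5 Å. Buried positions (c ≈ Z) reduce to
a plain contact-potential delta; exposed positions are dominated by
solvation, so a surface hydrophobic→polar substitution — precisely the kind
that disrupts an interface — is correctly scored as benign or stabilising.
This matters: a naive reuse of the interface contact potential for stability
penalises every disruptive surface substitution (the same hydrophobicity
term appears with opposite roles) and empirically leaves *zero* feasible
designs on the synthetic test bed. The plain contact+clash variant is still
available (`ContactStabilityScorer`) for buried-site use or comparison.
Designs must satisfy ΔΔG ≤ 0 ("no worse than wild type").

**Homolog filter.** Substitutions are restricted to amino acids observed at
the aligned column in at least `min_homolog_count` (default 1) homolog rows
of a user-supplied alignment whose first row is the antigen sequence. This
delegates viability judgement to evolution at the cost of shrinking the
design space.

## Design and panel selection

Per pose, one mutation per candidate position (the most disruptive allowed
substitution), all k-subsets enumerated (k = 3 default, 1–4 supported; when
fewer candidate positions exist, all are used), filtered on mean pairwise Cα
spread ≤ 12 Å and ΔΔG ≤ 0, Pareto frontier over (max disruption, min ΔΔG),
truncated to `pareto_cap` = 50 designs by descending disruption then
lexicographic position order. Exhaustive enumeration is exact and cheap at
k ≤ 4; no ILP machinery is needed.

Merged designs are clustered by the Hausdorff distance between the Cα point
sets of their mutated positions, with PAM K-medoids: seeded random
initialisation, steepest single-swap descent, 10 restarts, best objective
kept, ties broken toward the lexicographically smallest medoid tuple. K
starts at 1 and grows until some one-design-per-cluster combination covers
every *coverable* model (models no design can disrupt are excluded from the
requirement and reported); among covering combinations the largest summed
disruptiveness wins, ties going to the smallest design-id tuple. If the
product of cluster sizes exceeds 10⁶ the search falls back to greedy
max-coverage with a logged warning. Everything is deterministic for a fixed
seed; panel TSV/JSON output is byte-identical across reruns.

The incremental-K clustered search is a heuristic, not an exact set-cover
solver: when two designs essential to the optimal cover are geometrically
close they can share a cluster at every K, and the selected panel is then
larger than the true minimum (about one instance in five on small random
test beds). The panel always covers every coverable model.

For several antibodies against one antigen, per-antibody ensembles are
pooled (model ids prefixed with the antibody label) and the identical
pipeline runs on the pooled ensemble; dock-overlap matrices (fraction of one
antibody's footprints matching another's at Jaccard ≥ 0.25 — a reporting
proxy, configurable) and average-Hausdorff design-distance matrices support
in-silico epitope binning.

## Evaluation

Localization succeeds when at least one panel design mutates a residue of
the epitope — a curated residue list when available, else the 5 Å interface
of a reference complex; both are reported when both exist. Models consistent
with experimentally disruptive designs are those whose footprint contains a
mutated position of such a design; the union of their footprints over the
surface measures the residual search space.

The random baseline draws, per repetition, a pool of random k-position
surface sets with mean Cα spread < 12 Å (rejection sampling, uniform over
feasible sets), clusters them with the same Hausdorff/K-medoids machinery
into as many clusters as the docking-guided panel has variants, takes the
medoids as the selected plan, and scores epitope overlap. Positions only are
randomised: amino-acid identity cannot affect the position-overlap success
metric. The mean over repetitions is reported with a Wilson binomial
interval.

`summarize_retrospective` computes column means/SDs, success counts and
rates, Kendall's τ (tau-b, tie-corrected) between decoy and design counts
per structure source, and Pearson's r between antigen size and design count
(whole-chain residue count primary; the surface-count pairing is also
emitted). Degenerate (constant) columns are flagged rather than scored. The
packaged 33-complex benchmark CSV ships with the code as a regression
fixture for these statistics.

## Synthetic test bed

`make_scenario` builds a convex pseudo-antigen: Cα positions on a golden-
spiral spherical lattice (≈6 Å spacing), five pseudo-atoms per residue
(N, Cα, C, O, Cβ), random sequence under the seed. Convexity makes every
residue surface, which keeps the geometry of footprints and spread realistic
while removing burial effects. Pseudo-antibodies are rigid ~50-atom clouds:
one contact atom 4.3 Å radially above each patch residue's Cβ (inside the
5 Å cutoff for exactly that residue) plus padding atoms 8–12 Å out. All
pseudo-paratope atoms belong to tyrosine pseudo-residues — tyrosine
dominates real paratope contacts, and a fixed identity keeps the paratope
compositionally neutral so the scenarios exercise the antigen-side
algorithms rather than accidental paratope chemistry. The synthetic homolog
alignment substitutes each column of each homolog with probability
`sub_rate` (default 0.3 at depth 8) and is patched so ≥ 80% of positions
offer at least one substitution. When a true pose is included, the
ground-truth epitope is its footprint, which makes end-to-end success a
construction property: covering the true model implies a disruptive
mutation inside its footprint.

What passing these tests shows: the geometry (SASA, contacts, Hausdorff,
spread), the filtering and merge logic, the covering search, and the
evaluation layer behave exactly as specified, deterministically, at
realistic problem shapes. What they do not show: performance on real
antigens — real surfaces are non-convex with partial burial, real paratopes
are chemically diverse, real docking ensembles carry correlated errors, and
real stability effects are not captured by any contact potential. The
retrospective benchmark table is a transcription used to validate the
statistics layer, not a re-run of docking or design on those complexes.

## Problem sizes and runtimes

The canonical synthetic condition is 60 residues, 20 poses, footprint 8,
k = 3, MSA depth 8; 50 seeded scenarios run in ~1 minute. The baseline uses
200 repetitions with a pool of 150 random sets per repetition (the pool is
the unit that scales runtime; the selection statistics are stable at this
size). Oracle-equivalence checks run brute-force set cover on ≤ 12 designs
× ≤ 8 models and exhaustive Pareto enumeration on ≤ 10 positions.

## Known limitations

- The contact potential and stability scorer are deliberately coarse; they
  rank substitutions sensibly but their absolute scales are arbitrary units.
- The panel search inherits the clustering heuristic's occasional
  over-sizing (above).
- The dock-overlap matrix measure (Jaccard ≥ 0.25 footprint match) is a
  labelled proxy; other definitions of "overlap" are plausible.
- Antigens are treated as single rigid chains; no conformational change,
  glycosylation or multi-chain epitopes.
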